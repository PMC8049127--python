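# Methods

## The rank-weighted similarity

A patient stay is an ordered list of categorical codes; position encodes
clinical priority (diagnoses) or execution order (procedures), 1-based at
every interface. For two profiles A and B, each code *c* present in both
lists contributes

* diagnosis weighting: `M_c = ln(1 + 1/max(pos_A(c), pos_B(c)))` — the
  weight is set by the *worse* of the two priorities, so a code that is
  primary in one list but incidental in the other counts little;
* procedure weighting: `M_c = ln(1 + 1/(|pos_A(c) − pos_B(c)| + 1))` — for
  sequence-ordered lists what matters is how far apart the matched steps
  occurred, not how early.

`S(A, B)` is the sum over shared codes (natural logarithm throughout).
Each term lies in (0, ln 2], so `S ≤ min(L_A, L_B)·ln 2`. A code repeated
within one list is matched once, at its earliest position — consistent
with the grouping step below, which deduplicates sections to their
earliest occurrence because earlier positions carry more weight.
Contributions are summed in sorted-code order so that `S(A, B)` and
`S(B, A)` are equal bit-for-bit, not merely to rounding.

Grouping raw codes into coarser sections (e.g. CCS-style ranges such as
`990-995.`) is supported via a code→group table; matching may be done on
raw codes or on grouped sections. Unmapped codes are kept verbatim by
default (policies: keep / drop / error) so that an incomplete grouping
table never silently shrinks profiles.

### Distances

Cohort similarities are normalized by the maximum *off-diagonal* pairwise
similarity and converted to `D = 1 − S/max(S)`. Normalizing by the best
pair (rather than by self-similarity) lets the most similar pair attain
distance 0, so distances span [0, 1]; self-distance is 0 by convention.
The normalization is per analyzed cohort, since networks are built per
cohort. A cohort in which no pair shares any code has no defined distance
scale and is rejected (`DegenerateCohortError`).

Because two random profiles rarely share codes — and shared codes tend to
sit at uninformative positions — pairwise distances pile up near 1: a
left-skewed distribution with its mode in the upper quartile. This shape
is the motivating regime for the ratio-penalized network objective.

## Network construction (STAD-R)

Given `D_X`, all n(n−1)/2 node pairs are ranked ascending by distance,
ties broken lexicographically by node pair, making the whole construction
deterministic. Kruskal's algorithm over that very ranking yields a unique
minimum spanning tree, the zero-added-edges seed. Non-tree candidates are
then admitted as a prefix of the ranking; a prefix of k added edges is
scored by

`objective(k) = ρ(D_X, D_U(k)) · R(k)`

where `D_U(k)` is the matrix of unweighted shortest-path (hop) lengths in
the graph, `ρ` the Pearson correlation over the upper-triangle pairs, and
`R = Σ(1−d)/Σ(1+d)` summed over *all* edges in the network (tree edges
included), with `d` the edge's original distance. `R ∈ [0, 1]` and is
computed from original distances, never hop counts. When either distance
vector is constant (a complete graph makes all hops 1; a constant `D_X`
has no structure), `ρ := 0` by convention, so degenerate inputs return the
MST rather than an undefined objective. Hop distances enter `ρ` as raw
integers: Pearson correlation is invariant to positive affine rescaling,
so normalizing them would change nothing.

The first (sparsest) argmax wins under ties. The plain-correlation
objective (`objective="correlation"`) is retained for comparison; on
left-skewed inputs its optimum is markedly denser, which is precisely the
behavior the ratio is designed to suppress.

### Search strategy

Every candidate prefix count is a valid iterate; how many to evaluate is a
cost choice:

* `exhaustive` — every prefix 0..K. Used by default up to K = 3,000
  candidate pairs (n ≈ 78): each evaluation is an all-pairs BFS, and the
  full scan stays in seconds there.
* `coarse` — all prefixes up to 32, a 64-point geometric grid up to K, and
  then repeated bracketed subdivision around the running best down to
  single-prefix resolution. Deterministic, ~150–250 evaluations regardless
  of K. Used by default above 3,000 candidates; a 300-patient cohort
  (~45,000 candidate pairs) runs in about two seconds.

The objective along the prefix axis is smooth at grid scale (ρ rises and
saturates, R decays monotonically), so the coarse search lands on the same
optimum region the exhaustive scan finds; exhaustive-versus-oracle
equivalence is pinned by tests at small n, where the oracle enumerates
every prefix. The trace records exactly which prefixes were evaluated,
with ρ, R, the objective and the chosen optimum per row, keeping the
search auditable.

## Annotation

Louvain modularity communities (resolution 1.0, seed 0 by default) and a
force-directed layout (Fruchterman–Reingold with a fixed seed; the
algorithm name is recorded in the artifact metadata) are attached as
post-hoc node attributes. They never alter the graph: a network serialized
with and without annotations has identical edges. Node-link JSON is
written with sorted keys and no timestamps, so identical inputs and seeds
produce byte-identical artifacts.

## Projection quality

Two complementary measures compare any projection to `D_X`:

* **Global**: Spearman rank correlation over all pairwise distances
  (average ranks under ties; the zero-variance convention above applies).
* **Local**: for each node, the fraction of its k nearest neighbors in
  `D_X` that remain among its k nearest in the projection, averaged over
  nodes. Default k = 14, a typical community size in ICU diagnosis
  cohorts; configurable. Neighbor ranking uses a stable sort, so ties
  resolve to the lower node index — material for hop matrices, where ties
  abound. The per-node-average (rather than pooled-count) form is used.

A projection may be the abstract graph itself (hop distances) or any 2-D
embedding (Euclidean distances between coordinates); both measures depend
only on ranks and neighbor sets, hence are invariant under rotation,
translation, uniform scaling, and any strictly monotone distance
transform.

## Synthetic cohorts

Real ICU diagnosis tables are credential-restricted, so the package ships
a generator that emulates their statistical shape rather than their
content:

* list lengths: rounded Normal(13, 5), truncated to ≥ 1 — matching the
  published cohort moments (mean 13, sd 5);
* k planted patient groups (default 3), each with its own pool of
  characteristic codes (default 30 per group), plus a shared background
  pool (default 200); each list slot draws background with probability
  0.3, codes drawn without replacement;
* with probability 0.8 the first (primary) position is forced to hold a
  cluster-pool code, mimicking cohorts defined by a shared leading
  diagnosis.

Pool sizes are the generator's free parameters; 30/200 makes same-group
pairs share a handful of codes while cross-group pairs share almost none,
which reproduces the left-skewed distance shape (mode in the upper
quartile) that motivates the ratio objective. The generator does *not*
model real comorbidity structure, ICD frequency spectra, code hierarchies
or demographics — so passing recovery tests demonstrate that the pipeline
detects planted co-occurrence structure of realistic sparsity, not that it
reproduces clinical findings.

### Cluster recovery

`recover_clusters` runs the full pipeline — similarity, network, Louvain —
and returns community labels for comparison with the planted ground truth
(adjusted Rand index). Modularity at its default resolution resolves
fine-grained communities of roughly 10–20 patients nested inside the
macro-groups (on sparse 300-node networks it finds 15–18 of them — the
familiar resolution limit; incidentally the same community scale seen in
real cohorts). A recovery experiment knows the number of planted groups,
so the resolution is selected from a fixed ladder
(1.0 … 0.05) as the highest resolution whose community count comes
closest to k — the network analogue of cutting a dendrogram at k
clusters. Under the default study conditions (n = 300, three groups) the
median ARI over ten seeds is ≈ 0.96.

## Numerical and degenerate-input choices

* Zero-variance correlation (Pearson or Spearman) → 0 with a warning.
* Constant distance matrices → the MST is returned with the warning above.
* All tie-breaks (edge ranking, argmax, neighbor ranking, community
  relabeling) are deterministic; no module except the seeded Louvain and
  layout steps uses randomness at all, and those are reproducible given
  their seeds.
* Distances are persisted at full double precision; rounding happens only
  in display.

## Known limitations

* The exhaustive/coarse switch trades exactness of the prefix argmax for
  run time above ~3,000 candidate pairs; the trace makes the evaluated
  prefixes explicit if finer search is wanted (`mode="exhaustive"`).
* Hop distances saturate quickly in small-diameter graphs, so ρ is a
  coarse signal on very dense networks; this is inherent to the method.
* Quality scores on real cohort data (restricted access) are not
  reproduced; the synthetic surrogates validate code paths and qualitative
  behavior only.
* The similarity treats codes as atomic tokens: no ontology-aware
  (hierarchy ancestor) or co-occurrence-based similarity is attempted.
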