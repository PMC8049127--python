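"""Rank-weighted similarity between ordered code lists, and distances.

Two profiles are similar when they share codes, and more so when the shared
codes sit early in the lists.  Each shared code c contributes

* diagnosis (priority-ordered) lists:  M = ln(1 + 1/max(pos_A(c), pos_B(c)))
* procedure (sequence-ordered) lists:  M = ln(1 + 1/(|pos_A(c) - pos_B(c)| + 1))

with 1-based positions, and the profile similarity S is the sum of the
contributions over the shared codes.  Every contribution lies in (0, ln 2],
so S <= min(L_A, L_B) * ln 2.

For network construction, similarities over a cohort are normalized by the
maximum *pairwise* (off-diagonal) similarity and converted to distances
D = 1 - S / max(S), which span [0, 1]: the most similar pair in the cohort
sits at distance 0 and pairs sharing no codes at distance 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DegenerateCohortError
from .profiles import PatientProfile

Weighting = Literal["diagnosis", "procedure"]

#: Upper bound of a single match contribution (both codes at position 1 /
#: at identical positions).
MAX_CONTRIBUTION = math.log(2.0)


def _check_positions(pos_a: int, pos_b: int) -> None:
    if pos_a < 1 or pos_b < 1:
        raise ValueError(f"positions are 1-based; got ({pos_a}, {pos_b})")


def diagnosis_contribution(pos_a: int, pos_b: int) -> float:
    """ln(1 + 1/max(pos_a, pos_b)): weight decays with the *worse* priority.

    Symmetric in its arguments and strictly decreasing in max(pos_a, pos_b);
    maximal (ln 2) when both codes are the primary diagnosis.
    """
    _check_positions(pos_a, pos_b)
    return math.log1p(1.0 / max(pos_a, pos_b))


def procedure_contribution(pos_a: int, pos_b: int) -> float:
    """ln(1 + 1/(|pos_a - pos_b| + 1)): weight decays with positional offset.

    Procedure lists encode the order of execution rather than priority, so
    what matters is how far apart the matched steps occurred, not how early.
    Maximal (ln 2) iff the positions coincide.
    """
    _check_positions(pos_a, pos_b)
    return math.log1p(1.0 / (abs(pos_a - pos_b) + 1))


_CONTRIBUTIONS: dict[str, Callable[[int, int], float]] = {
    "diagnosis": diagnosis_contribution,
    "procedure": procedure_contribution,
}


def match_contribution(weighting: Weighting) -> Callable[[int, int], float]:
    try:
        return _CONTRIBUTIONS[weighting]
    except KeyError:
        raise ConfigurationError(
            f"weighting must be one of {sorted(_CONTRIBUTIONS)}, got {weighting!r}"
        ) from None


def profile_similarity(
    a: PatientProfile, b: PatientProfile, weighting: Weighting = "diagnosis"
) -> float:
    """Sum of match contributions over codes present in both lists.

    A code occurring more than once is matched once, at its earliest
    position in each list.  Zero when the lists are disjoint.
    """
    contrib = match_contribution(weighting)
    pos_a: dict[str, int] = {}
    for i, code in enumerate(a.codes, start=1):
        pos_a.setdefault(code, i)
    pos_b: dict[str, int] = {}
    for i, code in enumerate(b.codes, start=1):
        pos_b.setdefault(code, i)
    # summing in sorted-code order makes S(a, b) == S(b, a) bit-exactly
    return sum(
        contrib(pos_a[code], pos_b[code])
        for code in sorted(pos_a.keys() & pos_b.keys())
    )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarities S[i, j] >= 0 over a cohort.

    The diagonal stores self-similarity; it is excluded from distance
    normalization.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray
    normalization_constant: float = 1.0

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy 'condensed' order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def pairwise_similarity(
    profiles: Sequence[PatientProfile], weighting: Weighting = "diagnosis"
) -> SimilarityMatrix:
    """All-pairs profile similarity for a cohort of >= 2 profiles."""
    n = len(profiles)
    if n < 2:
        raise DataError(f"need at least 2 profiles, got {n}")
    contrib = match_contribution(weighting)
    positions = []
    for p in profiles:
        pos: dict[str, int] = {}
        for i, code in enumerate(p.codes, start=1):
            pos.setdefault(code, i)
        positions.append(pos)

    values = np.zeros((n, n))
    for i in range(n):
        pi = positions[i]
        for j in range(i, n):
            pj = positions[j]
            s = sum(
                contrib(pi[code], pj[code])
                for code in sorted(pi.keys() & pj.keys())
            )
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(tuple(p.stay_id for p in profiles), values)


def to_distance(similarity: SimilarityMatrix) -> DistanceMatrix:
    """D = 1 - S/max(S) with max(S) taken over off-diagonal entries.

    Normalizing by the best *pairwise* similarity in the cohort (rather than
    by self-similarity) lets the most similar pair attain distance 0, so the
    distances span [0, 1].  Self-distance is 0 by convention.

    Raises
    ------
    DegenerateCohortError
        If no pair of profiles shares a code (all off-diagonal S are 0).
    """
    s = similarity.values
    n = len(similarity.ids)
    off = ~np.eye(n, dtype=bool)
    max_s = float(s[off].max()) if n > 1 else 0.0
    if max_s <= 0.0:
        raise DegenerateCohortError(
            "no pair of profiles shares any code; distances are undefined"
        )
    d = 1.0 - s / max_s
    np.clip(d, 0.0, 1.0, out=d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(similarity.ids, d, normalization_constant=max_s)


def profiles_to_distance(
    profiles: Sequence[PatientProfile], weighting: Weighting = "diagnosis"
) -> DistanceMatrix:
    """Convenience composition: pairwise similarity then normalization."""
    return to_distance(pairwise_similarity(profiles, weighting))


def write_distance_matrix(
    dist: DistanceMatrix, path: str | Path, long_format: bool = False
) -> None:
    """TSV export: square with id header row/column, or (id_a, id_b, value)."""
    if long_format:
        iu = np.triu_indices(dist.n, k=1)
        pd.DataFrame(
            {
                "id_a": [dist.ids[i] for i in iu[0]],
                "id_b": [dist.ids[j] for j in iu[1]],
                "value": dist.values[iu],
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(
            dist.values, index=list(dist.ids), columns=list(dist.ids)
        ).to_csv(path, sep="\t", index_label="id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square TSV written by :func:`write_distance_matrix`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in frame.columns)
    values = frame.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise DataError("distance matrix file is not square")
    if not np.allclose(values, values.T):
        raise DataError("distance matrix file is not symmetric")
    return DistanceMatrix(ids, values)
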