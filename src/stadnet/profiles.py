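"""Cohorts of ordered diagnosis/procedure code lists.

A patient stay is represented as an ordered list of categorical codes
(ICD-9 tokens in the motivating use case).  Position in the list is
meaningful: for diagnoses it encodes clinical priority (position 1 is the
most important pathology), for procedures it encodes the sequence in which
they were performed.  Positions are 1-based everywhere at the interface
level.

The module reads MIMIC-shaped long tables (one row per stay/rank/code),
coarsens raw codes into higher-level sections via a grouping table, selects
subpopulations sharing a code, and aggregates position distributions for
bar-chart style summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError

#: Default column names: the MIMIC-III DIAGNOSES_ICD / PROCEDURES_ICD dialect.
DEFAULT_COLUMNS: dict[str, str] = {
    "subject": "SUBJECT_ID",
    "stay": "HADM_ID",
    "rank": "SEQ_NUM",
    "code": "ICD9_CODE",
}

UNMAPPED_POLICIES = ("keep", "drop", "error")


@dataclass(frozen=True)
class PatientProfile:
    """One patient stay: an ordered, non-empty list of codes.

    ``codes[i]`` sits at 1-based position ``i + 1``.  After grouping and
    deduplication all codes within one profile are distinct.
    """

    stay_id: str
    codes: tuple[str, ...]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.codes) == 0:
            raise DataError(f"profile {self.stay_id!r} has no codes")

    def __len__(self) -> int:
        return len(self.codes)

    def position_of(self, code: str) -> int | None:
        """1-based position of the first occurrence of ``code``, or None."""
        try:
            return self.codes.index(code) + 1
        except ValueError:
            return None

    def __contains__(self, code: object) -> bool:
        return code in self.codes


def read_profiles(
    source: str | Path | pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
) -> list[PatientProfile]:
    """Read a long-format (stay, rank, code) table into ordered profiles.

    Parameters
    ----------
    source
        CSV path or an already-loaded DataFrame with one row per coded event.
    column_map
        Overrides for the logical column names ``stay``, ``rank``, ``code``
        and (optional) ``subject``.  Defaults to the MIMIC dialect
        (HADM_ID, SEQ_NUM, ICD9_CODE, SUBJECT_ID).

    Codes are sorted ascending by rank within each stay and renumbered to
    contiguous 1..L positions preserving order; raw rank values (which may
    have gaps) are discarded.  Rows with missing rank or code are dropped.

    Raises
    ------
    ConfigurationError
        If a required column is absent.
    DataError
        If one stay carries two different codes at the same rank.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    if isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source, dtype={cols["code"]: str})

    for logical in ("stay", "rank", "code"):
        if cols[logical] not in table.columns:
            raise ConfigurationError(
                f"required column {cols[logical]!r} (role: {logical}) "
                f"not found; available: {list(table.columns)}"
            )
    has_subject = cols["subject"] in table.columns

    table = table.dropna(subset=[cols["rank"], cols["code"]])
    if table.empty:
        return []

    table = table.assign(
        _rank=pd.to_numeric(table[cols["rank"]]),
        _code=table[cols["code"]].astype(str),
    )

    profiles: list[PatientProfile] = []
    for stay, grp in table.groupby(cols["stay"], sort=False):
        dup = grp.groupby("_rank")["_code"].nunique()
        if (dup > 1).any():
            bad = dup.index[dup > 1].tolist()
            raise DataError(
                f"stay {stay!r} has conflicting codes at rank(s) {bad}"
            )
        grp = grp.drop_duplicates("_rank").sort_values("_rank", kind="stable")
        subject = str(grp[cols["subject"]].iloc[0]) if has_subject else None
        profiles.append(
            PatientProfile(
                stay_id=str(stay),
                codes=tuple(grp["_code"]),
                subject_id=subject,
            )
        )
    return profiles


def profiles_to_table(
    profiles: Iterable[PatientProfile],
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format table (inverse of :func:`read_profiles`)."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    rows = [
        {
            cols["subject"]: p.subject_id if p.subject_id is not None else p.stay_id,
            cols["stay"]: p.stay_id,
            cols["rank"]: pos,
            cols["code"]: code,
        }
        for p in profiles
        for pos, code in enumerate(p.codes, start=1)
    ]
    return pd.DataFrame(rows, columns=[cols[k] for k in ("subject", "stay", "rank", "code")])


def write_profiles(
    profiles: Iterable[PatientProfile],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    profiles_to_table(profiles, column_map).to_csv(path, index=False)


def read_grouping(source: str | Path | pd.DataFrame) -> dict[str, str]:
    """Read a code→group table (CSV columns ``code``, ``group``[, ``label``])."""
    table = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str
    )
    for col in ("code", "group"):
        if col not in table.columns:
            raise ConfigurationError(f"grouping table lacks column {col!r}")
    dup = table["code"].duplicated()
    if dup.any():
        conflicting = (
            table.groupby("code")["group"].nunique().pipe(lambda s: s[s > 1])
        )
        if not conflicting.empty:
            raise DataError(
                f"grouping is not a function: codes {conflicting.index.tolist()} "
                "map to multiple groups"
            )
    return dict(zip(table["code"].astype(str), table["group"].astype(str)))


def apply_grouping(
    profiles: Iterable[PatientProfile],
    rules: Mapping[str, str],
    unmapped_policy: str = "keep",
) -> list[PatientProfile]:
    """Replace each code by its group, collapsing repeats to the first position.

    Sections repeated within one profile are kept only at their earliest
    (most relevant) position and later positions are closed up, so downstream
    similarity weights each section once, at its highest priority.

    ``unmapped_policy`` controls codes absent from ``rules``: ``keep`` them
    verbatim (default), ``drop`` them (a profile emptied this way is removed
    from the cohort), or ``error``.
    """
    if unmapped_policy not in UNMAPPED_POLICIES:
        raise ConfigurationError(
            f"unmapped_policy must be one of {UNMAPPED_POLICIES}, "
            f"got {unmapped_policy!r}"
        )

    out: list[PatientProfile] = []
    unmapped: dict[str, None] = {}  # insertion-ordered set
    for p in profiles:
        grouped: list[str] = []
        seen: set[str] = set()
        for code in p.codes:
            if code in rules:
                token = rules[code]
            elif unmapped_policy == "keep":
                token = code
            elif unmapped_policy == "drop":
                continue
            else:
                unmapped[code] = None
                continue
            if token not in seen:
                seen.add(token)
                grouped.append(token)
        if grouped:
            out.append(replace(p, codes=tuple(grouped)))
    if unmapped:
        raise DataError(f"unmapped codes under policy='error': {sorted(unmapped)}")
    return out


def select_subpopulation(
    profiles: Iterable[PatientProfile], target_code: str
) -> list[PatientProfile]:
    """Profiles containing ``target_code`` at any position (positions kept)."""
    return [p for p in profiles if target_code in p]


@dataclass(frozen=True)
class PositionDistribution:
    """Counts of profiles carrying each code at each 1-based position."""

    table: pd.DataFrame = field(repr=False)  # columns: code, position, count

    def count(self, code: str, position: int) -> int:
        t = self.table
        hit = t[(t["code"] == code) & (t["position"] == position)]
        return 0 if hit.empty else int(hit["count"].iloc[0])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def position_distribution(
    profiles: Sequence[PatientProfile],
) -> PositionDistribution:
    """How codes spread across list positions over a cohort.

    For every (code, position) observed, the number of profiles with that
    code at that position.  The total count at position p equals the number
    of profiles of length >= p, so stacked bars shorten with position.
    """
    counts: dict[tuple[str, int], int] = {}
    for p in profiles:
        for pos, code in enumerate(p.codes, start=1):
            counts[(code, pos)] = counts.get((code, pos), 0) + 1
    table = pd.DataFrame(
        [(c, pos, n) for (c, pos), n in counts.items()],
        columns=["code", "position", "count"],
    ).sort_values(["code", "position"], kind="stable", ignore_index=True)
    return PositionDistribution(table)
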