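"""Thermostability group statistics and sequence-determinant checks.

The thirteen study proteins separate into a high-melting group
(Tm ~ 96 degC) and a low-melting group (Tm ~ 88 degC).  Two alignment
positions in Sac7d numbering act as determinants of the split: a threonine
at position 17 (vs isoleucine) destabilises, as does a valine at position
30 (vs isoleucine).  Group membership is data (transcribed study
assignments), not inferred; a largest-gap splitter is provided only as a
non-authoritative convenience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sequence_analysis import ProteinRecord, global_align

__all__ = [
    "StabilityRecord",
    "GroupStats",
    "DeterminantReport",
    "tm_group_stats",
    "delta_tm",
    "split_by_tm_gap",
    "residue_at_reference_position",
    "determinant_check",
]


@dataclass(frozen=True)
class StabilityRecord:
    """A protein's melting behaviour: Tm (degC), aggregation flag, group label."""

    name: str
    tm_c: float
    aggregates: bool = False
    group: str = "unassigned"  # {high, low, unassigned}

    def __post_init__(self) -> None:
        if not 0 < self.tm_c < 150:
            raise ValueError(f"{self.name}: Tm {self.tm_c} degC outside (0, 150)")
        if self.group not in ("high", "low", "unassigned"):
            raise ValueError(f"{self.name}: unknown group {self.group!r}")


@dataclass(frozen=True)
class GroupStats:
    """Mean and sample SD of melting temperatures in one group."""

    members: tuple[str, ...]
    mean: float
    sd: float
    n: int


def tm_group_stats(records: list[StabilityRecord], group: str) -> GroupStats:
    """Arithmetic mean and sample SD (n-1 denominator) of a Tm group."""
    members = [r for r in records if r.group == group]
    if not members:
        raise ValueError(f"no records in group {group!r}")
    tms = np.array([r.tm_c for r in members])
    sd = float(np.std(tms, ddof=1)) if len(members) > 1 else 0.0
    return GroupStats(
        members=tuple(r.name for r in members),
        mean=float(np.mean(tms)),
        sd=sd,
        n=len(members),
    )


def delta_tm(records: list[StabilityRecord], a: str, b: str) -> float:
    """Signed melting-temperature difference Tm(a) - Tm(b), degC."""
    by_name = {r.name: r for r in records}
    for name in (a, b):
        if name not in by_name:
            raise KeyError(f"unknown protein {name!r}")
    return by_name[a].tm_c - by_name[b].tm_c


def split_by_tm_gap(records: list[StabilityRecord]) -> dict[str, list[str]]:
    """Convenience two-way split at the largest gap in sorted Tm.

    Non-authoritative: study group membership is carried as data on the
    records themselves.
    """
    if len(records) < 2:
        raise ValueError("need at least two records to split")
    ordered = sorted(records, key=lambda r: r.tm_c)
    gaps = np.diff([r.tm_c for r in ordered])
    cut = int(np.argmax(gaps)) + 1
    return {
        "low": [r.name for r in ordered[:cut]],
        "high": [r.name for r in ordered[cut:]],
    }


def residue_at_reference_position(
    reference: ProteinRecord, query: ProteinRecord, position: int
) -> str | None:
    """Residue of ``query`` aligned to 1-based ``position`` of ``reference``.

    Uses pairwise global alignment; returns None (with a warning) when the
    reference position aligns to a gap in the query.
    """
    aln = global_align(reference.sequence, query.sequence)
    ref_idx = 0
    for ra, rq in zip(aln.a, aln.b):
        if ra != "-":
            ref_idx += 1
            if ref_idx == position:
                if rq == "-":
                    warnings.warn(
                        f"{query.name}: reference position {position} aligns to a gap",
                        stacklevel=2,
                    )
                    return None
                return rq
    warnings.warn(
        f"{query.name}: reference has no position {position}", stacklevel=2
    )
    return None


@dataclass(frozen=True)
class DeterminantReport:
    """Outcome of the position-17/30 thermostability-determinant rule."""

    rows: tuple[dict, ...]
    n_consistent: int
    n_violations: int
    excluded: tuple[str, ...]

    def violations(self) -> list[str]:
        return [r["name"] for r in self.rows if r["status"] == "violation"]


def determinant_check(
    records: list[StabilityRecord],
    sequences: list[ProteinRecord],
    positions: tuple[int, int] = (17, 30),
    reference_name: str = "Sac7d",
) -> DeterminantReport:
    """Check the stability-determinant rule at Sac7d positions 17 and 30.

    Rule: non-aggregating low-Tm proteins carry at least one destabilising
    residue (T at 17 or V at 30); high-Tm proteins carry neither.
    Aggregating proteins unfold irreversibly, so their Tm is not comparable
    and they are excluded from the rule.  Sequence positions are mapped to
    the reference (Sac7d) numbering by pairwise alignment.
    """
    seq_by_name = {s.name: s for s in sequences}
    if reference_name not in seq_by_name:
        raise KeyError(f"reference sequence {reference_name!r} not provided")
    ref = seq_by_name[reference_name]
    p17, p30 = positions
    rows: list[dict] = []
    excluded: list[str] = []
    n_consistent = n_violations = 0
    for rec in records:
        if rec.name not in seq_by_name:
            warnings.warn(f"no sequence for {rec.name}; skipped", stacklevel=2)
            continue
        seq = seq_by_name[rec.name]
        r17 = residue_at_reference_position(ref, seq, p17)
        r30 = residue_at_reference_position(ref, seq, p30)
        row = {
            "name": rec.name,
            "group": rec.group,
            "aggregates": rec.aggregates,
            f"res{p17}": r17,
            f"res{p30}": r30,
        }
        if rec.aggregates or rec.group == "unassigned":
            row["status"] = "excluded"
            excluded.append(rec.name)
        else:
            destabilising = (r17 == "T") or (r30 == "V")
            ok = destabilising if rec.group == "low" else not destabilising
            row["status"] = "consistent" if ok else "violation"
            if ok:
                n_consistent += 1
            else:
                n_violations += 1
        rows.append(row)
    return DeterminantReport(
        rows=tuple(rows),
        n_consistent=n_consistent,
        n_violations=n_violations,
        excluded=tuple(excluded),
    )
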