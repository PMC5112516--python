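"""Sequence analytics for the Sul7d family.

Covers the construct and composition arithmetic used alongside the binding
work: assembly of the RGS-His6 expression construct, pairwise percent
identity and similarity under eight standard residue classes, net charge
versus pH by Henderson-Hasselbalch summation, average molecular mass, and
ordering of paralogs by basicity (isoelectric point).

Sul7d proteins are small (60-66 residues in the known family) and highly
basic; paralogs from one organism are traditionally suffixed a, b, c ... in
order of increasing basicity, which :func:`basicity_order` reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.optimize import brentq

__all__ = [
    "STANDARD_RESIDUES",
    "DEFAULT_SIMILARITY_SCHEME",
    "DEFAULT_PKA_TABLE",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "TAG_AFTER_MET",
    "TAG_AFTER_LAST_LYS",
    "ProteinRecord",
    "SimilarityScheme",
    "PairScore",
    "PkaTable",
    "GlobalAlignment",
    "TaggingError",
    "apply_expression_tag",
    "global_align",
    "pair_score",
    "net_charge",
    "average_mass",
    "isoelectric_point",
    "basicity_order",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: expression-construct insertions: RGS-His6 detection/purification region
#: after the initiator Met, and a C-terminal extension after the last Lys
TAG_AFTER_MET = "RGSHHHHHHGS"
TAG_AFTER_LAST_LYS = "LN"

#: average (isotope-weighted) residue masses, Da; peptide mass adds one water
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01528


class TaggingError(ValueError):
    """The sequence violates a rule of the expression-tag construction."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with study annotations.

    The alphabet is the 20 standard residues; '-' is additionally tolerated
    so records read from aligned FASTA can carry their gaps.
    """

    name: str
    sequence: str
    accession: str = ""
    tagged: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_RESIDUES) - {"-"}
        if bad:
            raise ValueError(
                f"{self.name}: non-standard residues {sorted(bad)} in sequence"
            )

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityScheme:
    """A named partition of the 20 standard residues into similarity classes."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        all_res = "".join(self.groups.values())
        if len(all_res) != len(set(all_res)):
            raise ValueError("similarity classes overlap")
        if set(all_res) != set(STANDARD_RESIDUES):
            missing = set(STANDARD_RESIDUES) - set(all_res)
            raise ValueError(f"similarity classes do not cover residues {sorted(missing)}")

    def group_of(self, residue: str) -> str:
        for name, members in self.groups.items():
            if residue in members:
                return name
        raise KeyError(f"residue {residue!r} outside the similarity scheme")

    def same_group(self, a: str, b: str) -> bool:
        return self.group_of(a) == self.group_of(b)


#: the eight standard side-chain classes used for similarity scoring
DEFAULT_SIMILARITY_SCHEME = SimilarityScheme(
    groups={
        "aliphatic": "GAVLI",
        "aromatic": "FYW",
        "sulphur": "CM",
        "hydroxylic": "ST",
        "basic": "KRH",
        "acidic": "DE",
        "amidic": "NQ",
        "proline": "P",
    }
)


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values for net-charge calculation."""

    side_chains: dict[str, float]
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for label, pka in {**self.side_chains, "n_term": self.n_term, "c_term": self.c_term}.items():
            if not 0 < pka < 14:
                raise ValueError(f"pKa for {label} out of range: {pka}")


#: EMBOSS-style pKa set (a standard published choice; overridable everywhere)
DEFAULT_PKA_TABLE = PkaTable(
    side_chains={"K": 10.8, "R": 12.5, "H": 6.5, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    n_term=8.6,
    c_term=3.6,
)

_BASIC = "KRH"
_ACIDIC = "DECY"


@dataclass(frozen=True)
class GlobalAlignment:
    """A pairwise global alignment as two equal-length gapped strings."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned strings must have equal length")

    def __len__(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class PairScore:
    """Percent identity and similarity of one aligned sequence pair."""

    identity_pct: float
    similarity_pct: float
    aligned_positions: int
    gap_positions: int

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= self.similarity_pct <= 100 + 1e-9:
            raise ValueError(
                f"require 0 <= identity ({self.identity_pct}) <= "
                f"similarity ({self.similarity_pct}) <= 100"
            )


def apply_expression_tag(record: ProteinRecord) -> ProteinRecord:
    """Build the expression construct used for all study proteins.

    Inserts ``RGSHHHHHHGS`` immediately after the initiator methionine and
    ``LN`` immediately after the last lysine (any residues downstream of
    that lysine are preserved).  The construct is 13 residues longer than
    the input.  Raises :class:`TaggingError` if the sequence lacks an
    initial M or any K, or already carries the tag.
    """
    seq = record.sequence
    if not seq.startswith("M"):
        raise TaggingError(f"{record.name}: sequence must start with methionine")
    if record.tagged or seq.startswith("M" + TAG_AFTER_MET):
        raise TaggingError(f"{record.name}: sequence already carries the expression tag")
    last_k = seq.rfind("K")
    if last_k < 1:
        raise TaggingError(f"{record.name}: no lysine after the initiator methionine")
    tagged_seq = (
        "M" + TAG_AFTER_MET + seq[1:last_k + 1] + TAG_AFTER_LAST_LYS + seq[last_k + 1:]
    )
    assert len(tagged_seq) == len(seq) + 13
    return ProteinRecord(
        name=record.name, sequence=tagged_seq, accession=record.accession, tagged=True
    )


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> GlobalAlignment:
    """Optimal Needleman-Wunsch global alignment of two sequences.

    The default scoring (match 1, mismatch 0, affine gaps -10/-0.5 on the
    same scale) is tuned for the short, highly similar Sul7d sequences,
    where it recovers the homologous columns a multiple aligner would.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    return GlobalAlignment(a=str(aln[0]), b=str(aln[1]), score=float(aln.score))


def pair_score(
    alignment: GlobalAlignment,
    scheme: SimilarityScheme = DEFAULT_SIMILARITY_SCHEME,
    denominator: str = "shorter_sequence",
) -> PairScore:
    """Percent identity / similarity of an aligned pair.

    Identity counts columns with identical residues; similarity counts
    columns whose residues fall in the same class of ``scheme`` (identical
    pairs included, since the classes partition the alphabet).  The
    ``denominator`` convention is 'shorter_sequence' (length of the shorter
    ungapped input) or 'alignment_length' (columns with at least one
    residue); published percent-identity tools differ on this, so both are
    exposed.
    """
    identical = similar = aligned = gaps = 0
    for ra, rb in zip(alignment.a, alignment.b):
        if ra == "-" or rb == "-":
            gaps += 1
            continue
        aligned += 1
        if ra == rb:
            identical += 1
            similar += 1
        elif scheme.same_group(ra, rb):
            similar += 1
    if denominator == "shorter_sequence":
        denom = min(
            len(alignment.a.replace("-", "")), len(alignment.b.replace("-", ""))
        )
    elif denominator == "alignment_length":
        denom = aligned + gaps
    else:
        raise ValueError(
            "denominator must be 'shorter_sequence' or 'alignment_length', "
            f"got {denominator!r}"
        )
    return PairScore(
        identity_pct=100.0 * identical / denom,
        similarity_pct=100.0 * similar / denom,
        aligned_positions=aligned,
        gap_positions=gaps,
    )


def net_charge(
    record: ProteinRecord | str,
    pH: float = 7.4,
    table: PkaTable = DEFAULT_PKA_TABLE,
) -> float:
    """Net charge (elementary charges) by Henderson-Hasselbalch summation.

    Basic sites (K, R, H side chains and the N-terminus) each contribute
    ``+1 / (1 + 10**(pH - pKa))``; acidic sites (D, E, C, Y side chains and
    the C-terminus) contribute ``-1 / (1 + 10**(pKa - pH))``.  Strictly
    decreasing in pH.
    """
    if not 0 <= pH <= 14:
        raise ValueError(f"pH must be within [0, 14], got {pH}")
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    charge = 1.0 / (1.0 + 10 ** (pH - table.n_term))
    charge -= 1.0 / (1.0 + 10 ** (table.c_term - pH))
    for res in seq:
        if res in _BASIC:
            charge += 1.0 / (1.0 + 10 ** (pH - table.side_chains[res]))
        elif res in _ACIDIC:
            charge -= 1.0 / (1.0 + 10 ** (table.side_chains[res] - pH))
    return charge


def average_mass(record: ProteinRecord | str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    try:
        total = sum(AVERAGE_RESIDUE_MASS[res] for res in seq)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return total + WATER_MASS


def isoelectric_point(
    record: ProteinRecord | str, table: PkaTable = DEFAULT_PKA_TABLE
) -> float:
    """pH at which the net charge vanishes (bisection on :func:`net_charge`).

    Unique because the charge is strictly decreasing in pH and the termini
    guarantee one positive and one negative site.
    """
    return float(brentq(lambda ph: net_charge(record, ph, table), 0.0, 14.0, xtol=1e-9))


def basicity_order(
    records: list[ProteinRecord], table: PkaTable = DEFAULT_PKA_TABLE
) -> list[ProteinRecord]:
    """Records sorted by ascending isoelectric point (ties by name).

    This is the family's naming convention: paralogs of one organism get
    lowercase suffixes in order of increasing basicity.
    """
    if not records:
        raise ValueError("need at least one record")
    return sorted(records, key=lambda r: (isoelectric_point(r, table), r.name))
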