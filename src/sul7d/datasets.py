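"""Packaged study data: the printed per-protein table and sequence fixtures.

Only the Sac7d sequence (UniProt P13123) is packaged verbatim; the other
twelve study sequences are not redistributable here, so
:func:`load_study_sequences` builds SYNTHETIC stand-ins from the Sac7d
backbone carrying exactly the residue differences the study documents
(positions 2, 14, 17, 20, 25, 30 in Sac7d numbering, the QDL 11-13 motif of
the Metallosphaera proteins, and Aho7c's missing penultimate lysine).
These synthetic sequences support the determinant and pipeline analyses;
they do not reproduce the real proteins' masses, charges or full pairwise
divergence.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sequence_analysis import ProteinRecord
from .stability_analysis import StabilityRecord

__all__ = [
    "SAC7D_SEQUENCE",
    "load_study_table",
    "load_stability_records",
    "load_sac7d",
    "load_study_sequences",
]

#: Sac7d, UniProt P13123 (66 residues; 1-based numbering used throughout)
SAC7D_SEQUENCE = "MVKVKFKYKGEEKEVDTSKIKKVWRVGKMVSFTYDDNGKTGRGAVSEKDAPKELLDMLARAEREKK"


def _data_path(name: str):
    return resources.files("sul7d.data").joinpath(name)


def load_study_table() -> pd.DataFrame:
    """The printed per-protein table (MW, yield, K_D, n, Tm, grouping) as a DataFrame."""
    with resources.as_file(_data_path("study_table.csv")) as path:
        return pd.read_csv(path, comment="#")


def load_stability_records() -> list[StabilityRecord]:
    """Melting-temperature records with the study's group assignments."""
    df = load_study_table()
    return [
        StabilityRecord(
            name=row["name"],
            tm_c=float(row["tm_c"]),
            aggregates=bool(row["aggregates"]),
            group=str(row["tm_group"]),
        )
        for _, row in df.iterrows()
    ]


def load_sac7d() -> ProteinRecord:
    """The real Sac7d sequence (UniProt P13123) from the packaged FASTA."""
    from .cli_io import read_fasta

    with resources.as_file(_data_path("sac7d.fasta")) as path:
        return read_fasta(path)[0]


# Synthetic stand-in substitutions on the Sac7d backbone, 1-based positions.
# Each entry encodes only residue differences the study states explicitly
# (stability determinants 17/30, position-2/14 relationships among the
# Sulfolobus paralogs, the Metallosphaera QDL 11-13 motif plus V4I/I20V/R25K,
# Aho7c's missing penultimate lysine); remaining backbone positions are
# Sac7d's and NOT the real proteins' residues.
_SYNTHETIC_SUBSTITUTIONS: dict[str, dict[int, str]] = {
    "Sac7e": {37: "Q", 50: "S"},
    "Mse7": {4: "I", 11: "Q", 12: "D", 13: "L", 20: "V", 25: "K"},
    "Mcu7": {4: "I", 11: "Q", 12: "D", 13: "L", 20: "V", 25: "K", 59: "S"},
    "Aho7a": {17: "I", 30: "I", 39: "R"},
    "Aho7b": {17: "I", 30: "I", 35: "E"},
    "Aho7c": {17: "I", 30: "I", 65: "A"},
    "Sto7": {17: "I", 30: "I", 46: "T"},
    "Sis7a": {17: "I", 30: "I"},
    "Sis7b": {30: "I"},
    "Ssh7a": {2: "A", 17: "I", 30: "I"},
    "Ssh7b": {2: "T", 14: "Q", 30: "I"},
    "Sso7d": {2: "A", 14: "Q", 17: "I", 30: "I"},
}


def _mutate(sequence: str, substitutions: dict[int, str]) -> str:
    seq = list(sequence)
    for pos, aa in substitutions.items():
        seq[pos - 1] = aa
    return "".join(seq)


def load_study_sequences() -> list[ProteinRecord]:
    """The 13-protein study set: real Sac7d plus 12 synthetic stand-ins.

    The synthetic records carry the documented determinant residues only
    (see module docstring); order matches the printed table.
    """
    sac7d = load_sac7d()
    records = {"Sac7d": sac7d}
    for name, subs in _SYNTHETIC_SUBSTITUTIONS.items():
        records[name] = ProteinRecord(name=name, sequence=_mutate(sac7d.sequence, subs))
    order = load_study_table()["name"].tolist()
    return [records[name] for name in order]
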