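"""Isoform domain decomposition and windowed hydropathy profiles.

Intermediate-filament proteins split into head, rod and tail domains; the 3'
splice isoforms studied here share the head+rod (exons 1-6 plus part of 7)
and differ only in the tail, so each record carries the species-specific
combined head+rod length (374 aa mouse, 377 human, 375 rat for this gene
set) and the tail is everything after it.

Hydropathy profiles are sliding-window arithmetic means of per-residue scale
values (Kyte-Doolittle by default, window 9, full windows only, value at the
window centre); values above zero indicate hydrophobicity, below zero
hydrophilicity.  Alternative scales may be supplied as a residue -> value
mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "KYTE_DOOLITTLE",
    "ProteinRecord",
    "HydropathyProfile",
    "split_domains",
    "hydropathy_profile",
    "load_proteins",
]

#: Kyte & Doolittle per-residue hydropathy values
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SCALES = {"kyte_doolittle": KYTE_DOOLITTLE}

ISOFORMS = ("alpha", "delta_epsilon", "kappa")


@dataclass
class ProteinRecord:
    accession: str
    species: str
    isoform: str
    sequence: str
    head_rod_length: int

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.head_rod_length > len(self.sequence):
            raise ValueError(
                f"{self.accession}: head+rod length {self.head_rod_length} "
                f"exceeds sequence length {len(self.sequence)}"
            )
        if self.head_rod_length < 0:
            raise ValueError("head+rod length must be non-negative")

    @property
    def tail_length(self) -> int:
        return len(self.sequence) - self.head_rod_length


def split_domains(rec: ProteinRecord) -> tuple[str, str]:
    """(head+rod, tail) split at the record's head+rod length."""
    n = rec.head_rod_length
    return rec.sequence[:n], rec.sequence[n:]


@dataclass
class HydropathyProfile:
    values: np.ndarray
    scale: str
    window: int
    # 1-based residue position of the first window centre
    first_center: int

    def __len__(self) -> int:
        return len(self.values)

    @property
    def centers(self) -> np.ndarray:
        """1-based centre positions."""
        return np.arange(self.first_center,
                         self.first_center + len(self.values))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"center": self.centers, "value": self.values}
        ).to_csv(path, sep="\t", index=False)


def hydropathy_profile(seq: str, scale="kyte_doolittle",
                       window: int = 9) -> HydropathyProfile:
    """Sliding-window mean hydropathy (full windows only, centre-indexed)."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd number")
    if isinstance(scale, str):
        scale_name = scale
        try:
            table = SCALES[scale]
        except KeyError:
            raise ValueError(f"unknown scale {scale!r}; supply a dict "
                             "of per-residue values") from None
    else:
        scale_name, table = "custom", dict(scale)
    seq = seq.upper()
    if len(seq) < window:
        logger.warning("sequence of length %d shorter than window %d; "
                       "empty profile", len(seq), window)
        return HydropathyProfile(np.empty(0), scale_name, window,
                                 window // 2 + 1)
    try:
        vals = np.array([table[r] for r in seq], dtype=float)
    except KeyError as e:
        raise ValueError(f"residue {e.args[0]!r} not in the {scale_name} "
                         "scale") from None
    prof = np.convolve(vals, np.ones(window) / window, mode="valid")
    return HydropathyProfile(prof, scale_name, window, window // 2 + 1)


def load_proteins(fasta_path, metadata) -> list[ProteinRecord]:
    """Attach species/isoform/head+rod metadata to FASTA records.

    ``metadata`` is a TSV path or DataFrame with columns ``accession``,
    ``species``, ``isoform``, ``head_rod_length``.  Every FASTA id must map
    to a metadata row with a head+rod length.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t")
    required = {"accession", "species", "isoform", "head_rod_length"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata is missing columns {sorted(missing)}")
    meta = metadata.set_index("accession")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = rec.id
        if acc not in meta.index:
            raise ValueError(f"FASTA id {acc!r} has no metadata row")
        row = meta.loc[acc]
        if pd.isna(row["head_rod_length"]):
            raise ValueError(f"{acc}: head_rod_length is missing")
        records.append(ProteinRecord(
            accession=acc,
            species=str(row["species"]),
            isoform=str(row["isoform"]),
            sequence=str(rec.seq),
            head_rod_length=int(row["head_rod_length"]),
        ))
    return records
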