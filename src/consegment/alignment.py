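"""Reference-anchored alignment columns and conservation-code encoding.

A multi-species alignment (MAF) is projected onto the reference species:
columns in which the reference carries a gap are dropped, so every retained
column sits at a definite reference coordinate.  Each column is then encoded
as a *conservation code* — the number of distinct symbols among the aligned
characters (a gap counts as its own symbol) minus one — and, for the
three-species case, classified into one of ten canonical match/mismatch/gap
patterns (``AAA`` .. ``A--``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion",
    "AlignmentColumn",
    "CodeSequence",
    "read_maf_subset",
    "encode_column",
    "classify_pattern",
    "encode_region",
    "PATTERN_LABELS",
    "read_bed",
    "write_bed",
    "write_codes_tsv",
    "read_codes_tsv",
]

#: the ten admissible three-species column patterns (reference, then others)
PATTERN_LABELS = (
    "AAA", "AAB", "ABA", "ABB", "ABC",
    "AA-", "A-A", "AB-", "A-B", "A--",
)

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open genomic interval, 0-based internally.

    Browser-style coordinates (1-based inclusive, as printed by UCSC) are
    converted on input via :meth:`from_browser`.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_browser(cls, chrom: str, start1: int, end1: int,
                     strand: str = "+") -> "GenomicRegion":
        """Build from 1-based inclusive browser coordinates."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_browser(self) -> tuple[str, int, int]:
        return self.chrom, self.start + 1, self.end


class AlignmentColumn(NamedTuple):
    ref_base: str
    other_bases: tuple[str, ...]
    ref_position: int


@dataclass
class CodeSequence:
    """Ordered conservation codes over a reference region."""

    codes: np.ndarray
    region: GenomicRegion | None = None
    n_symbols: int = 3

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if self.region is not None and len(self.codes) != len(self.region):
            raise ValueError(
                f"{len(self.codes)} codes for a region of length "
                f"{len(self.region)}"
            )
        if len(self.codes) and (
            self.codes.min() < 0 or self.codes.max() >= self.n_symbols
        ):
            raise ValueError("codes out of range")

    def __len__(self) -> int:
        return len(self.codes)


def _species_key(src: str) -> str:
    """MAF 'src' fields look like 'hg19.chr17'; the assembly is the prefix."""
    return src.split(".", 1)[0]


def read_maf_subset(
    path, species: Sequence[str]
) -> list[AlignmentColumn]:
    """Project a MAF alignment onto the first (reference) species.

    Parameters
    ----------
    path
        MAF file (UCSC multiz dialect).
    species
        Ordered assembly names, reference first (e.g. ``["hg19", "mm9",
        "rn4"]``).  Species absent from a block contribute ``'-'`` at every
        column of that block.

    Returns
    -------
    list of AlignmentColumn in reference-coordinate order.  Columns where the
    reference carries a gap are dropped.
    """
    if len(species) < 2:
        raise ValueError("need a reference and at least one other species")
    ref = species[0]
    columns: list[AlignmentColumn] = []
    last_ref_start = -1
    n_count = 0
    for bi, block in enumerate(AlignIO.parse(path, "maf")):
        rows = {}
        for rec in block:
            key = _species_key(rec.id)
            if key in species and key not in rows:
                rows[key] = rec
        if ref not in rows:
            raise ValueError(
                f"block {bi} is missing the reference species {ref!r}"
            )
        ref_rec = rows[ref]
        ref_start = int(ref_rec.annotations["start"])
        if ref_start < last_ref_start:
            raise ValueError(
                f"block {bi} starts before the previous block; "
                "MAF blocks must be sorted by reference coordinate"
            )
        last_ref_start = ref_start
        texts = [str(ref_rec.seq).upper()]
        width = len(texts[0])
        for sp in species[1:]:
            if sp in rows:
                t = str(rows[sp].seq).upper()
                if len(t) != width:
                    raise ValueError(
                        f"block {bi}: row for {sp} has width {len(t)}, "
                        f"expected {width}"
                    )
                texts.append(t)
            else:
                texts.append("-" * width)
        pos = ref_start
        for j in range(width):
            rb = texts[0][j]
            if rb == "-":
                continue
            if rb not in _VALID_BASES:
                raise ValueError(
                    f"block {bi}: invalid reference base {rb!r}"
                )
            if rb == "N":
                n_count += 1
            others = tuple(t[j] for t in texts[1:])
            columns.append(AlignmentColumn(rb, others, pos))
            pos += 1
    if n_count:
        logger.warning("alignment contains %d reference 'N' bases", n_count)
    return columns


def encode_column(col: AlignmentColumn) -> int:
    """Conservation code: distinct symbols (gap = a symbol) minus one.

    All characters at the column are pooled; ``N`` is treated as a distinct
    fifth symbol; case is ignored.
    """
    symbols = {col.ref_base.upper()}
    for b in col.other_bases:
        symbols.add(b.upper())
    return len(symbols) - 1


def classify_pattern(col: AlignmentColumn) -> str:
    """Canonical column pattern: 'A' for the reference base, then novel bases
    'B', 'C', ... in species order; gaps rendered literally as '-'."""
    mapping = {col.ref_base.upper(): "A"}
    label = ["A"]
    next_letter = ord("B")
    for b in col.other_bases:
        b = b.upper()
        if b == "-":
            label.append("-")
            continue
        if b not in mapping:
            mapping[b] = chr(next_letter)
            next_letter += 1
        label.append(mapping[b])
    return "".join(label)


def encode_region(
    columns: Iterable[AlignmentColumn],
    region: GenomicRegion | None = None,
    n_symbols: int | None = None,
) -> CodeSequence:
    """Vectorise :func:`encode_column` over a column list."""
    cols = list(columns)
    codes = np.fromiter(
        (encode_column(c) for c in cols), dtype=np.int8, count=len(cols)
    )
    if n_symbols is None:
        n_symbols = (len(cols[0].other_bases) + 1) if cols else 3
    return CodeSequence(codes, region=region, n_symbols=n_symbols)


# ---------------------------------------------------------------------------
# plain-text interchange: BED intervals and code TSV


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read chrom/start/end triples from a BED file (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(path, intervals, names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            row = [chrom, str(start), str(end)]
            if names is not None:
                row.append(str(names[i]))
                if scores is not None:
                    row.append(str(scores[i]))
            fh.write("\t".join(row) + "\n")


def write_codes_tsv(path, codeseq: CodeSequence) -> None:
    """Two-column TSV: reference position (0-based), code."""
    start = codeseq.region.start if codeseq.region is not None else 0
    with open(path, "w") as fh:
        fh.write("position\tcode\n")
        for i, c in enumerate(codeseq.codes):
            fh.write(f"{start + i}\t{int(c)}\n")


def read_codes_tsv(path, region: GenomicRegion | None = None) -> CodeSequence:
    codes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("position"):
            raise ValueError("expected a 'position\\tcode' header")
        for line in fh:
            if line.strip():
                codes.append(int(line.split("\t")[1]))
    return CodeSequence(np.array(codes, dtype=np.int8), region=region)
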