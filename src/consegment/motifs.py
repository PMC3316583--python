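"""Degenerate-pattern scanning for splicing-regulatory DNA elements and
PROSITE-style protein phosphorylation motifs, with cross-species
conservation filtering.

The DNA registry covers the short regulatory elements relevant to 3'
isoform choice: G-triplet runs and CA tandem repeats (splicing
enhancers/silencers), the Nova-family YCAY element, the PTB-bound
polypyrimidine motifs CUCUCU and UCUUC (scanned as DNA, U -> T), and the
AAUAAA polyadenylation signal.  Protein patterns cover the kinase acceptor
motifs [ST]XX[DE] (CKII), [ST]X[RK] (PKC) and [RK]XX[ST] (cAMP/cGMP-dependent
kinase), with flanking-residue annotation (an acidic residue N-terminal of a
CKII acceptor raises the phosphorylation rate; a basic one lowers it).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotifHit",
    "ProteinPattern",
    "scan_iupac",
    "find_g_runs",
    "find_tandem_repeats",
    "conserved_hits",
    "scan_protein_pattern",
    "annotate_flanks",
    "FlankAnnotation",
    "hit_density",
    "scan_dna_registry",
    "reverse_complement",
    "DNA_MOTIFS",
    "PROTEIN_PATTERNS",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: sense-strand DNA equivalents of the splicing-regulatory motif registry
DNA_MOTIFS = {
    "YCAY": "YCAY",
    "PTB_CUCUCU": "CTCTCT",
    "PTB_UCUUC": "TCTTC",
    "polyA_AAUAAA": "AATAAA",
}


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int           # 0-based
    length: int
    matched: str
    motif: str
    strand: str = "sense"
    conserved_in: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in {motif!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?=({''.join(parts)}))")


def scan_iupac(seq: str, motif: str, seq_id: str = "seq",
               antisense: bool = False, name: str | None = None
               ) -> list[MotifHit]:
    """All (overlapping) matches of an IUPAC motif on the sense strand;
    with ``antisense=True`` the reverse complement is also scanned, hits
    reported in sense-strand coordinates."""
    seq = seq.upper().replace("U", "T")
    name = name or motif
    rx = _iupac_regex(motif)
    hits = [
        MotifHit(seq_id, m.start(), len(m.group(1)), m.group(1), name)
        for m in rx.finditer(seq)
    ]
    if antisense:
        rc = reverse_complement(seq)
        L = len(seq)
        for m in rx.finditer(rc):
            w = len(m.group(1))
            start = L - m.start() - w
            hits.append(MotifHit(seq_id, start, w, seq[start:start + w],
                                 name, strand="antisense"))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def find_g_runs(seq: str, min_run: int = 3, seq_id: str = "seq"
                ) -> list[MotifHit]:
    """Maximal runs of consecutive G of length >= min_run, reported once."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seq = seq.upper().replace("U", "T")
    return [
        MotifHit(seq_id, m.start(), m.end() - m.start(), m.group(),
                 f"G_run>={min_run}")
        for m in re.finditer(f"G{{{min_run},}}", seq)
    ]


def find_tandem_repeats(seq: str, unit: str = "CA", min_units: int = 3,
                        seq_id: str = "seq") -> list[MotifHit]:
    """Maximal perfect tandem runs of ``unit`` with >= min_units copies."""
    if len(unit) < 1:
        raise ValueError("unit must be non-empty")
    unit = unit.upper().replace("U", "T")
    seq = seq.upper().replace("U", "T")
    rx = re.compile(f"(?:{re.escape(unit)}){{{min_units},}}")
    return [
        MotifHit(seq_id, m.start(), m.end() - m.start(), m.group(),
                 f"{unit}_repeat>={min_units}")
        for m in rx.finditer(seq)
    ]


def scan_dna_registry(seq: str, seq_id: str = "seq",
                      g_run_min: int = 3, ca_min_units: int = 3
                      ) -> list[MotifHit]:
    """Scan the full splicing-regulatory registry on one sequence."""
    hits = find_g_runs(seq, g_run_min, seq_id)
    hits += find_tandem_repeats(seq, "CA", ca_min_units, seq_id)
    for name, motif in DNA_MOTIFS.items():
        hits += scan_iupac(seq, motif, seq_id, name=name)
    return sorted(hits, key=lambda h: (h.start, h.motif))


def hit_density(hits, length: int, window: int = 50) -> np.ndarray:
    """Sliding count of hit starts per window (the registry's stand-in for
    'clusters'); entry i covers starts in [i, i+window)."""
    starts = np.zeros(length, dtype=float)
    for h in hits:
        if 0 <= h.start < length:
            starts[h.start] += 1
    if length < window:
        return np.array([starts.sum()])
    return np.convolve(starts, np.ones(window), mode="valid")


def conserved_hits(columns, scanner, seq_id: str = "ref") -> list[MotifHit]:
    """Cross-species conservation filter for reference-coordinate hits.

    ``scanner`` maps a sequence string to a hit list (e.g.
    ``lambda s: scan_iupac(s, "YCAY")``).  The reference sequence of the
    columns is scanned; a hit is conserved iff, for every other species, the
    gapless subsequence over the hit's columns is itself fully matched by the
    scanner (a hit spanning the entire subsequence).  Any gap shortens the
    subsequence and breaks conservation.

    Returned hits carry ``conserved_in`` = 1 (reference) + number of other
    species matching; only hits conserved in all species are returned.
    """
    cols = list(columns)
    ref_seq = "".join(c.ref_base for c in cols)
    n_other = len(cols[0].other_bases) if cols else 0
    hits = scanner(ref_seq)
    out = []
    for h in hits:
        window = cols[h.start:h.end]
        n_cons = 1
        for si in range(n_other):
            sub = "".join(c.other_bases[si] for c in window
                          if c.other_bases[si] != "-")
            if len(sub) != h.length:
                continue
            sub_hits = scanner(sub)
            if any(sh.start == 0 and sh.length == len(sub)
                   for sh in sub_hits):
                n_cons += 1
        if n_cons == 1 + n_other:
            out.append(MotifHit(seq_id, h.start, h.length, h.matched,
                                h.motif, h.strand, conserved_in=n_cons))
    return out


# ---------------------------------------------------------------------------
# protein patterns


@dataclass(frozen=True)
class ProteinPattern:
    """Ordered residue sets; ``None`` elements (X) match any residue.

    ``acceptor_index`` marks the phospho-acceptor S/T within the pattern.
    """

    name: str
    elements: tuple
    acceptor_index: int = 0

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern must be non-empty")

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def from_string(cls, name: str, pattern: str,
                    acceptor_index: int = 0) -> "ProteinPattern":
        """Parse bracket notation, e.g. ``[ST]XX[DE]``."""
        elements = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                j = pattern.index("]", i)
                residues = frozenset(pattern[i + 1:j].upper())
                if not residues <= AMINO_ACIDS:
                    raise ValueError(f"bad residue set in {pattern!r}")
                elements.append(residues)
                i = j + 1
            elif ch.upper() == "X":
                elements.append(None)
                i += 1
            else:
                if ch.upper() not in AMINO_ACIDS:
                    raise ValueError(f"bad residue {ch!r} in {pattern!r}")
                elements.append(frozenset(ch.upper()))
                i += 1
        return cls(name, tuple(elements), acceptor_index)

    def matches_at(self, seq: str, pos: int) -> bool:
        if pos + len(self) > len(seq):
            return False
        for off, el in enumerate(self.elements):
            if el is not None and seq[pos + off] not in el:
                return False
        return True


#: kinase acceptor-site registry
PROTEIN_PATTERNS = {
    "CKII": ProteinPattern.from_string("CKII", "[ST]XX[DE]",
                                       acceptor_index=0),
    "PKC": ProteinPattern.from_string("PKC", "[ST]X[RK]", acceptor_index=0),
    "cAMP_cGMP_PK": ProteinPattern.from_string("cAMP_cGMP_PK", "[RK]XX[ST]",
                                               acceptor_index=3),
}


def scan_protein_pattern(seq: str, pattern: ProteinPattern,
                         seq_id: str = "protein") -> list[MotifHit]:
    """All (overlapping) exact matches of a PROSITE-style pattern."""
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in sequence")
    hits = []
    for pos in range(len(seq) - len(pattern) + 1):
        if pattern.matches_at(seq, pos):
            hits.append(MotifHit(seq_id, pos, len(pattern),
                                 seq[pos:pos + len(pattern)], pattern.name))
    return hits


@dataclass(frozen=True)
class FlankAnnotation:
    n_terminal_residue: str | None
    n_terminal_class: str | None   # 'acidic' | 'basic' | 'other' | None
    acceptor_position: int         # 0-based position of the acceptor residue
    plus_five_residue: str | None  # residue at acceptor + 5, if present


_ACIDIC = set("DE")
_BASIC = set("KRH")


def annotate_flanks(seq: str, hit: MotifHit,
                    pattern: ProteinPattern | None = None) -> FlankAnnotation:
    """Classify the residue immediately N-terminal of a phospho-site match
    as acidic/basic/other, and report the residue at +5 from the acceptor."""
    seq = seq.upper()
    if hit.start < 0 or hit.end > len(seq):
        raise ValueError("hit lies outside the sequence")
    if pattern is None:
        pattern = PROTEIN_PATTERNS.get(hit.motif)
    acc_off = pattern.acceptor_index if pattern is not None else 0
    acceptor = hit.start + acc_off
    if hit.start == 0:
        n_res, n_class = None, None
    else:
        n_res = seq[hit.start - 1]
        n_class = ("acidic" if n_res in _ACIDIC
                   else "basic" if n_res in _BASIC else "other")
    p5 = acceptor + 5
    plus5 = seq[p5] if p5 < len(seq) else None
    return FlankAnnotation(n_res, n_class, acceptor, plus5)
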