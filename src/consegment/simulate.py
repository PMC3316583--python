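"""Synthetic data with the exact generative structure the model assumes.

The generator mirrors the inference model: Bernoulli(rho) boundaries,
segment labels i.i.d. from ``pi``, per-segment code proportions drawn from
the class Dirichlet, codes i.i.d. within each segment.  On top of the code
sequence it can emit a three-species reference-anchored alignment whose
columns re-encode to exactly the simulated codes, a coding annotation tied
to one class, and DNA sequences with planted motifs — all with known ground
truth and full seed determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import (
    AlignmentColumn,
    CodeSequence,
    GenomicRegion,
    PATTERN_LABELS,
    encode_region,
)
from .model import ClassParams, Segmentation

__all__ = [
    "SyntheticTruth",
    "simulate_codes",
    "emit_alignment",
    "annotate_coding",
    "plant_motifs",
    "random_dna",
    "gfap_like_params",
    "scenario_params",
    "simulate_scenario",
    "write_maf",
    "GFAP_LIKE",
    "WELL_SEPARATED",
    "SCENARIOS",
]

#: default scenario: a desk-scale stand-in for the real 110 kb region —
#: four conservation classes whose code-0 (fully conserved) proportions span
#: coding-like (0.95) to weakly constrained (0.35), mean segment length 200.
GFAP_LIKE = dict(
    length=20_000,
    k=4,
    pi=(0.1, 0.3, 0.4, 0.2),
    class_means=(
        (0.35, 0.45, 0.20),
        (0.95, 0.045, 0.005),
        (0.60, 0.32, 0.08),
        (0.45, 0.40, 0.15),
    ),
    concentration=60.0,
    rho=0.005,
    coding_class=2,
)


#: well-separated scenario: evenly spaced conservation levels (code-0
#: proportions 0.95/0.75/0.50/0.25, the coding-like class second so the
#: coding annotation is class 2 in both scenarios); the remaining mass
#: splits 3:1 between codes 1 and 2.
WELL_SEPARATED = dict(
    length=20_000,
    k=4,
    pi=(0.1, 0.3, 0.4, 0.2),
    class_means=(
        (0.25, 0.5625, 0.1875),
        (0.95, 0.0375, 0.0125),
        (0.75, 0.1875, 0.0625),
        (0.50, 0.3750, 0.1250),
    ),
    concentration=60.0,
    rho=0.005,
    coding_class=2,
)

SCENARIOS = {"gfap_like": GFAP_LIKE, "well_separated": WELL_SEPARATED}


def scenario_params(name: str = "gfap_like") -> ClassParams:
    try:
        sc = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    alphas = np.array(sc["class_means"]) * sc["concentration"]
    return ClassParams(alphas, np.array(sc["pi"]), sc["rho"])


def gfap_like_params() -> ClassParams:
    return scenario_params("gfap_like")


def simulate_scenario(name: str = "gfap_like", seed: int = 0,
                      length: int | None = None) -> SyntheticTruth:
    """Simulate a named scenario and attach its coding annotation."""
    sc = SCENARIOS[name]  # validated in scenario_params
    p = scenario_params(name)
    truth = simulate_codes(
        length=length if length is not None else sc["length"],
        k=sc["k"], pi=p.pi, alphas=p.alpha, rho=p.rho, seed=seed,
    )
    annotate_coding(truth, coding_class=sc["coding_class"])
    return truth


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation."""

    segmentation: Segmentation
    params: ClassParams
    seed: int
    codes: CodeSequence
    columns: list | None = None
    coding_intervals: list | None = None
    coding_class: int | None = None

    @property
    def position_labels(self) -> np.ndarray:
        return self.segmentation.position_labels()

    @property
    def n_changepoints(self) -> int:
        return len(self.segmentation.changepoints)


def simulate_codes(
    length: int | None = None,
    k: int | None = None,
    pi=None,
    alphas=None,
    rho: float | None = None,
    seed: int = 0,
    n_codes: int = 3,
) -> SyntheticTruth:
    """Draw a code sequence from the generative model.

    Defaults are the "gfap-like" scenario (:data:`GFAP_LIKE`).
    """
    base = gfap_like_params()
    if length is None:
        length = GFAP_LIKE["length"]
    if pi is None:
        pi = base.pi if k in (None, base.k) else np.full(k, 1.0 / k)
    pi = np.asarray(pi, dtype=float)
    if alphas is None:
        if k in (None, base.k):
            alphas = base.alpha
        else:
            from .model import _default_init
            alphas = _default_init(k, n_codes,
                                   concentration=GFAP_LIKE["concentration"])
    alphas = np.atleast_2d(np.asarray(alphas, dtype=float))
    rho = float(rho if rho is not None else base.rho)
    if k is None:
        k = len(pi)
    if len(pi) != k or alphas.shape[0] != k:
        raise ValueError("pi/alphas inconsistent with k")
    params = ClassParams(alphas, pi, rho)  # validates simplex/positivity
    if alphas.shape[1] != n_codes:
        raise ValueError(f"alphas must have {n_codes} columns")
    if length < 1:
        raise ValueError("length must be >= 1")

    rng = np.random.default_rng(seed)
    is_cp = rng.random(length - 1) < rho
    changepoints = np.flatnonzero(is_cp) + 1
    n_seg = len(changepoints) + 1
    labels = rng.choice(k, size=n_seg, p=pi) + 1
    starts = np.concatenate(([0], changepoints))
    ends = np.concatenate((changepoints, [length]))
    codes = np.empty(length, dtype=np.int8)
    for a, b, g in zip(starts, ends, labels):
        theta = rng.dirichlet(alphas[g - 1])
        codes[a:b] = rng.choice(n_codes, size=b - a, p=theta)
    seg = Segmentation(changepoints, labels, length)
    return SyntheticTruth(
        segmentation=seg,
        params=params,
        seed=seed,
        codes=CodeSequence(codes, n_symbols=n_codes),
    )


# ---------------------------------------------------------------------------
# alignment emission

_BASES = "ACGT"

#: patterns admissible for each conservation code (distinct symbols - 1)
PATTERNS_BY_CODE = {
    0: ("AAA",),
    1: ("AAB", "ABA", "ABB", "AA-", "A-A", "A--"),
    2: ("ABC", "AB-", "A-B"),
}

DEFAULT_PATTERN_MIX = {
    0: {"AAA": 1.0},
    1: {"AAB": 0.30, "ABA": 0.30, "ABB": 0.20,
        "AA-": 0.08, "A-A": 0.08, "A--": 0.04},
    2: {"ABC": 0.60, "AB-": 0.20, "A-B": 0.20},
}


def _pattern_code(pattern: str) -> int:
    return len(set(pattern)) - 1


def _column_from_pattern(pattern: str, pos: int, rng) -> AlignmentColumn:
    choice: dict[str, str] = {}
    pool = list(_BASES)
    rng.shuffle(pool)
    it = iter(pool)
    chars = []
    for ch in pattern:
        if ch == "-":
            chars.append("-")
        else:
            if ch not in choice:
                choice[ch] = next(it)
            chars.append(choice[ch])
    return AlignmentColumn(chars[0], tuple(chars[1:]), pos)


#: gap-bearing patterns per code, keyed by which other-species rows are gaps
_GAP_PATTERNS = {
    1: {(True, False): "A-A", (False, True): "AA-", (True, True): "A--"},
    2: {(True, False): "A-B", (False, True): "AB-"},
}


def emit_alignment(codes, pattern_mix=None, seed: int = 0,
                   start: int = 0,
                   gap_run_length: float | None = None
                   ) -> list[AlignmentColumn]:
    """Emit three-species columns whose conservation code equals the input
    code at every position; base identities are drawn uniformly subject to
    the pattern.

    ``gap_run_length``: when set, a drawn gap pattern is extended over
    following columns with geometric mean run length ``gap_run_length``
    (same species gapped, pattern re-chosen per column to stay consistent
    with its code).  The model itself assumes i.i.d. columns; this option
    exists to probe robustness to gap-run autocorrelation.
    """
    if isinstance(codes, CodeSequence):
        codes = codes.codes
    codes = np.asarray(codes)
    mix = pattern_mix if pattern_mix is not None else DEFAULT_PATTERN_MIX
    tables = {}
    for code, probs in mix.items():
        pats = list(probs)
        for p in pats:
            if p not in PATTERN_LABELS:
                raise ValueError(f"unknown pattern {p!r}")
            if _pattern_code(p) != code:
                raise ValueError(
                    f"pattern {p!r} is incompatible with code {code}"
                )
        w = np.array([probs[p] for p in pats], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"empty pattern mix for code {code}")
        tables[code] = (pats, w / w.sum())
    rng = np.random.default_rng(seed)
    cols = []
    gap_mask = None  # which other-species rows are in an ongoing gap run
    for i, c in enumerate(codes):
        c = int(c)
        if c not in tables:
            raise ValueError(f"no pattern mix for code {c}")
        pattern = None
        if gap_mask is not None:
            pattern = _GAP_PATTERNS.get(c, {}).get(gap_mask)
            if pattern is None or rng.random() < 1.0 / gap_run_length:
                gap_mask = None
                pattern = None
        if pattern is None:
            pats, w = tables[c]
            pattern = pats[rng.choice(len(pats), p=w)]
            if gap_run_length is not None and "-" in pattern:
                gap_mask = tuple(ch == "-" for ch in pattern[1:])
        cols.append(_column_from_pattern(pattern, start + i, rng))
    return cols


def annotate_coding(truth: SyntheticTruth, coding_class: int = 2,
                    chrom: str = "chrS") -> list[tuple[str, int, int]]:
    """BED-style intervals = maximal runs of positions in the coding class."""
    lab = truth.position_labels
    mask = lab == coding_class
    out = []
    i = 0
    N = len(mask)
    while i < N:
        if mask[i]:
            j = i
            while j < N and mask[j]:
                j += 1
            out.append((chrom, i, j))
            i = j
        else:
            i += 1
    truth.coding_intervals = out
    truth.coding_class = coding_class
    return out


# ---------------------------------------------------------------------------
# motif planting


def random_dna(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_BASES), size=length))


def plant_motifs(length: int, instances, seed: int = 0):
    """Uniform-background DNA with motif instances written at fixed positions.

    ``instances``: iterable of (position, text).  Returns (sequence, planted)
    where planted is the list of (position, text) actually written.

    Raises on overlap or out-of-bounds placements.
    """
    seq = list(random_dna(length, seed))
    occupied = np.zeros(length, dtype=bool)
    planted = []
    for pos, text in instances:
        if pos < 0 or pos + len(text) > length:
            raise ValueError(f"motif {text!r} at {pos} does not fit")
        if occupied[pos:pos + len(text)].any():
            raise ValueError(f"motif {text!r} at {pos} overlaps another")
        occupied[pos:pos + len(text)] = True
        seq[pos:pos + len(text)] = list(text.upper().replace("U", "T"))
        planted.append((pos, text))
    return "".join(seq), planted


# ---------------------------------------------------------------------------
# MAF emission (minimal 3-row dialect, single block)


def write_maf(path, columns, species=("hg19", "mm9", "rn4"),
              chrom: str = "chrS", block_size: int = 10_000) -> None:
    """Write reference-anchored columns as MAF blocks.

    The reference row is gapless by construction; other species may carry
    gaps, and their start/size fields count non-gap characters.
    """
    n_other = len(columns[0].other_bases) if columns else len(species) - 1
    if n_other != len(species) - 1:
        raise ValueError("species list does not match column arity")
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        other_consumed = [0] * n_other
        for off in range(0, len(columns), block_size):
            chunk = columns[off:off + block_size]
            ref_text = "".join(c.ref_base for c in chunk)
            ref_start = chunk[0].ref_position
            fh.write("\na score=0.0\n")
            total = 10 ** 9
            fh.write(
                f"s {species[0]}.{chrom} {ref_start} {len(ref_text)} + "
                f"{total} {ref_text}\n"
            )
            for si in range(n_other):
                text = "".join(c.other_bases[si] for c in chunk)
                size = len(text) - text.count("-")
                fh.write(
                    f"s {species[si + 1]}.{chrom} {other_consumed[si]} "
                    f"{size} + {total} {text}\n"
                )
                other_consumed[si] += size
        fh.write("\n")
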