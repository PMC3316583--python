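"""Profile thresholding: class assignment, pattern composition, the coding
classifier and conserved-feature interval extraction.

A position is *unambiguously assigned* to a class when its posterior profile
value strictly exceeds a threshold of at least 0.5 (so at most one class can
qualify).  Treating the profile of the conservation class that tracks
protein-coding sequence as a classifier against a coding annotation yields
standard confusion counts: sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), with UTRs counted as non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GenomicRegion, PATTERN_LABELS
from .model import ProfileMatrix

__all__ = [
    "ConfusionCounts",
    "PatternCompositionTable",
    "FeatureInterval",
    "assign_unambiguous",
    "pattern_composition",
    "classifier_confusion",
    "sensitivity_specificity",
    "extract_features",
    "intervals_to_mask",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


def assign_unambiguous(profiles, threshold: float = 0.5) -> np.ndarray:
    """Per-position class assignment: class g (1-based) where
    profile(i, g) > threshold strictly, else 0 (unassigned).

    ``threshold`` must be in [0.5, 1) so at most one class can exceed it.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must be in [0.5, 1) for unambiguous "
                         "assignment")
    values = profiles.values if isinstance(profiles, ProfileMatrix) \
        else np.asarray(profiles, dtype=float)
    best = values.argmax(axis=1)
    assigned = values[np.arange(len(values)), best] > threshold
    return np.where(assigned, best + 1, 0)


@dataclass
class PatternCompositionTable:
    """Counts and proportions of the 10 column patterns per class, over
    unambiguously assigned positions only."""

    counts: pd.DataFrame       # index: class, columns: pattern labels
    proportions: pd.DataFrame

    def to_tsv(self, path) -> None:
        merged = pd.concat(
            {"count": self.counts, "proportion": self.proportions}, axis=1
        )
        merged.to_csv(path, sep="\t")


def pattern_composition(assignments, labels) -> PatternCompositionTable:
    assignments = np.asarray(assignments)
    labels = np.asarray(labels, dtype=object)
    if len(assignments) != len(labels):
        raise ValueError("assignments and labels must be the same length")
    k = int(assignments.max(initial=0))
    classes = list(range(1, max(k, 1) + 1))
    counts = pd.DataFrame(0, index=pd.Index(classes, name="class"),
                          columns=list(PATTERN_LABELS), dtype=int)
    for g in classes:
        sel = labels[assignments == g]
        if len(sel):
            vc = pd.Series(sel).value_counts()
            for pat, n in vc.items():
                if pat not in counts.columns:
                    raise ValueError(f"unknown pattern label {pat!r}")
                counts.loc[g, pat] = int(n)
    totals = counts.sum(axis=1)
    props = counts.div(totals.replace(0, 1), axis=0)
    return PatternCompositionTable(counts, props.astype(float))


def intervals_to_mask(intervals, n_positions: int, offset: int = 0,
                      strict: bool = True) -> np.ndarray:
    """Boolean per-position mask from (chrom, start, end) or (start, end)
    intervals, shifted by ``offset`` (the region start)."""
    mask = np.zeros(n_positions, dtype=bool)
    for iv in intervals:
        start, end = (iv[1], iv[2]) if len(iv) == 3 else (iv[0], iv[1])
        a, b = start - offset, end - offset
        if strict and (a < 0 or b > n_positions):
            raise ValueError(
                f"annotation interval [{start}, {end}) lies outside the "
                f"profiled region"
            )
        mask[max(a, 0):min(b, n_positions)] = True
    return mask


def classifier_confusion(group_profile, coding, threshold: float = 0.5,
                         offset: int = 0) -> ConfusionCounts:
    """Confusion counts of the profile-threshold coding classifier.

    ``coding`` is either a boolean mask or a list of annotation intervals on
    the same region as the profile.  A position calls coding when its profile
    value is strictly greater than the threshold.
    """
    p = np.asarray(group_profile, dtype=float)
    if isinstance(coding, np.ndarray) and coding.dtype == bool:
        mask = coding
        if len(mask) != len(p):
            raise ValueError("mask length does not match the profile")
    else:
        mask = intervals_to_mask(coding, len(p), offset=offset)
    call = p > threshold
    return ConfusionCounts(
        TP=int(np.sum(mask & call)),
        FN=int(np.sum(mask & ~call)),
        TN=int(np.sum(~mask & ~call)),
        FP=int(np.sum(~mask & call)),
    )


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    if c.TP + c.FN == 0:
        raise ValueError("no annotated coding positions in scope "
                         "(TP+FN is zero)")
    if c.TN + c.FP == 0:
        raise ValueError("no non-coding positions in scope (TN+FP is zero)")
    return c.TP / (c.TP + c.FN), c.TN / (c.TN + c.FP)


@dataclass
class FeatureInterval:
    """A maximal run of high-profile positions (a conserved feature)."""

    region: GenomicRegion
    class_index: int
    mean_value: float
    max_value: float
    label: str

    @property
    def score(self) -> int:
        """BED score convention: mean profile value x 1000."""
        return int(round(self.mean_value * 1000))


def _feature_label(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return letters[i] if i < 26 else f"F{i + 1}"


def extract_features(group_profile, threshold: float = 0.5,
                     min_length: int = 10, merge_gap: int = 5,
                     class_index: int = 1,
                     chrom: str = "chrN", start: int = 0
                     ) -> list[FeatureInterval]:
    """Maximal runs of positions with profile > threshold; runs separated by
    at most ``merge_gap`` positions are merged, and merged runs shorter than
    ``min_length`` are dropped.

    The reported mean is over the above-threshold positions of the interval,
    so mean >= threshold even across merged gaps.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(group_profile, dtype=float)
    above = p > threshold
    runs = []
    i = 0
    while i < len(p):
        if above[i]:
            j = i
            while j < len(p) and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    out = []
    for a, b in merged:
        if b - a < min_length:
            continue
        vals = p[a:b][above[a:b]]
        out.append(FeatureInterval(
            region=GenomicRegion(chrom, start + a, start + b),
            class_index=class_index,
            mean_value=float(vals.mean()),
            max_value=float(vals.max()),
            label=_feature_label(len(out)),
        ))
    return out
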