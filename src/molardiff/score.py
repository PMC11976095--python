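"""Ordinal difficulty scoring for mandibular third molar extraction.

Each of the four anatomical features carries an ordinal score; their sum
(range 4-14) maps a case onto one of four difficulty classes:

=====  ====================  ===========
class  name                  total score
=====  ====================  ===========
D1     Easy                  4-6
D2     Slightly difficult    7-8
D3     Moderately difficult  9-10
D4     Very difficult        11-14
=====  ====================  ===========

The published class table tops out at 13, but the feature maxima
(4 + 3 + 3 + 4) sum to 14, so D4 is extended to cover 14 and the printed
upper bound is kept as :attr:`DifficultyClass.printed_hi`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "FeatureVector",
    "DifficultyClass",
    "CLASSES",
    "CLASS_BY_LABEL",
    "total_score",
    "classify_score",
    "enumerate_combinations",
]

#: (field name, human-readable feature, max score) in canonical order.
FEATURE_RANGES = (
    ("angulation_score", "angulation", 4),
    ("root_count_score", "root count", 3),
    ("curvature_score", "root curvature", 3),
    ("canal_score", "canal relation", 4),
)

MIN_TOTAL = 4
MAX_TOTAL = 14


@dataclass(frozen=True, order=True)
class FeatureVector:
    """The four ordinal scores resolved for one report."""

    angulation_score: int
    root_count_score: int
    curvature_score: int
    canal_score: int

    def __post_init__(self) -> None:
        for field, name, hi in FEATURE_RANGES:
            v = getattr(self, field)
            if not isinstance(v, int) or isinstance(v, bool) or not 1 <= v <= hi:
                raise ValueError(
                    f"{name} score must be an integer in [1, {hi}], got {v!r}"
                )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.angulation_score,
            self.root_count_score,
            self.curvature_score,
            self.canal_score,
        )


@dataclass(frozen=True)
class DifficultyClass:
    """One of the four extraction-difficulty classes with its score range."""

    label: str
    name: str
    lo: int
    hi: int
    #: published upper bound where it differs from the effective one
    printed_hi: int

    @property
    def score_range(self) -> tuple[int, int]:
        return (self.lo, self.hi)

    @property
    def index(self) -> int:
        return CLASS_LABELS.index(self.label)

    def __contains__(self, total: int) -> bool:
        return self.lo <= total <= self.hi


CLASSES: tuple[DifficultyClass, ...] = (
    DifficultyClass("D1", "Easy", 4, 6, 6),
    DifficultyClass("D2", "Slightly difficult", 7, 8, 8),
    DifficultyClass("D3", "Moderately difficult", 9, 10, 10),
    DifficultyClass("D4", "Very difficult", 11, 14, 13),
)

CLASS_LABELS = tuple(c.label for c in CLASSES)
CLASS_BY_LABEL = {c.label: c for c in CLASSES}


def total_score(fv: FeatureVector) -> int:
    """Sum of the four ordinal feature scores (always in [4, 14])."""
    if not isinstance(fv, FeatureVector):
        fv = FeatureVector(*fv)
    return sum(fv.as_tuple())


def classify_score(total: int) -> DifficultyClass:
    """Map a total score onto the unique difficulty class containing it."""
    if not isinstance(total, int) or isinstance(total, bool):
        raise ValueError(f"total score must be an integer, got {total!r}")
    if not MIN_TOTAL <= total <= MAX_TOTAL:
        raise ValueError(
            f"total score must lie in [{MIN_TOTAL}, {MAX_TOTAL}], got {total}"
        )
    for cls in CLASSES:
        if total in cls:
            return cls
    raise AssertionError("class ranges do not partition the score domain")


def classify_vector(fv: FeatureVector) -> DifficultyClass:
    """Convenience: class of a feature vector's total score."""
    return classify_score(total_score(fv))


def enumerate_combinations() -> list[tuple[FeatureVector, int, DifficultyClass]]:
    """All 4*3*3*4 = 144 feature vectors with totals and classes.

    Brute-force oracle table used in tests and for stratified sampling.
    """
    table = []
    for combo in _iter_combos():
        fv = FeatureVector(*combo)
        t = total_score(fv)
        table.append((fv, t, classify_score(t)))
    return table


def _iter_combos() -> Iterator[tuple[int, int, int, int]]:
    ranges = [range(1, hi + 1) for _, _, hi in FEATURE_RANGES]
    yield from itertools.product(*ranges)
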