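"""Evaluation: confusion matrices, precision/recall/F1, error taxonomy.

Class order is fixed to D1 < D2 < D3 < D4 everywhere. "Total" rows are
unweighted macro averages over the four classes (micro variants are also
emitted). Zero-division (an empty row or column) yields 0, not NaN.

Pipeline mistakes are split three ways, mutually exclusive per report
and assigned in priority order:

1. **tokenizer error** — sentence/token segmentation broke a synonym
   phrase that is present in the normalized text, preventing its match;
2. **concept error** — extraction resolved a wrong category, or missed
   a feature that the gold case does mention;
3. **classification error** — the feature vector was extracted
   correctly but the classifier predicted the wrong class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extract import ExtractionResult, Status
from .lexicon import FEATURE_IDS, FeatureLexicon
from .preprocess import Document
from .score import CLASS_LABELS, DifficultyClass
from .synthdata import GoldCase

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ErrorBreakdown",
    "EvaluatedCase",
    "confusion",
    "metrics",
    "categorize_errors",
    "plot_confusion",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 count grid; rows are true classes D1..D4, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (4, 4) or (c < 0).any():
            raise ValueError("confusion matrix must be a non-negative 4x4 grid")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{c}" for c in CLASS_LABELS],
            columns=[f"pred_{c}" for c in CLASS_LABELS],
        )


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    totals: dict[str, float]  # macro averages
    micro: dict[str, float]
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "totals": self.totals,
            "micro": self.micro,
            "accuracy": self.accuracy,
        }


@dataclass
class ErrorBreakdown:
    concept_errors: int = 0
    classification_errors: int = 0
    tokenizer_errors: int = 0

    @property
    def total(self) -> int:
        return self.concept_errors + self.classification_errors + self.tokenizer_errors

    def to_dict(self) -> dict:
        return {
            "concept_errors": self.concept_errors,
            "classification_errors": self.classification_errors,
            "tokenizer_errors": self.tokenizer_errors,
            "total": self.total,
        }


@dataclass
class EvaluatedCase:
    """One report with its full pipeline trace, ready for error triage."""

    case: GoldCase
    document: Document
    extraction: ExtractionResult
    predicted: DifficultyClass | None  # None when the report was excluded


def _class_index(label_or_class) -> int:
    return CLASS_LABELS.index(getattr(label_or_class, "label", label_or_class))


def confusion(
    gold: Sequence[DifficultyClass | str], pred: Sequence[DifficultyClass | str]
) -> ConfusionMatrix:
    if len(gold) != len(pred):
        raise ValueError(
            f"gold ({len(gold)}) and pred ({len(pred)}) differ in length"
        )
    if not gold:
        raise ValueError("need at least one evaluated case")
    counts = np.zeros((4, 4), dtype=int)
    for g, p in zip(gold, pred):
        counts[_class_index(g), _class_index(p)] += 1
    return ConfusionMatrix(counts)


def _prf(tp: float, col_sum: float, row_sum: float) -> tuple[float, float, float]:
    precision = tp / col_sum if col_sum else 0.0
    recall = tp / row_sum if row_sum else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and macro-averaged precision/recall/F1 plus accuracy."""
    c = cm.counts
    per_class: dict[str, dict[str, float]] = {}
    for i, label in enumerate(CLASS_LABELS):
        p, r, f = _prf(c[i, i], c[:, i].sum(), c[i, :].sum())
        per_class[label] = {"precision": p, "recall": r, "f1": f}
    totals = {
        m: float(np.mean([per_class[lab][m] for lab in CLASS_LABELS]))
        for m in ("precision", "recall", "f1")
    }
    # micro: every metric collapses to accuracy in single-label multiclass
    micro_val = cm.accuracy
    micro = {"precision": micro_val, "recall": micro_val, "f1": micro_val}
    return MetricsReport(
        per_class=per_class, totals=totals, micro=micro, accuracy=cm.accuracy
    )


def _phrase_broken_by_segmentation(
    doc: Document, lex: FeatureLexicon, feature_id: str, gold_label: str
) -> bool:
    """Is a gold synonym present as a token sequence although no phrase
    match fired? Then a sentence break or intervening punctuation split
    the phrase — a segmentation artifact, not a concept failure."""
    from .preprocess import tokenize

    all_tokens = [t for s in doc.sentences for t in s.tokens]
    for phrase in lex.synonyms_for(feature_id, gold_label):
        ptoks = list(tokenize(phrase))
        n = len(ptoks)
        if not n:
            continue
        for i in range(len(all_tokens) - n + 1):
            if all_tokens[i : i + n] == ptoks:
                return True
    return False


def categorize_errors(
    evaluated: Sequence[EvaluatedCase], lex: FeatureLexicon
) -> ErrorBreakdown:
    """Triage erroneous reports into the three-way taxonomy."""
    out = ErrorBreakdown()
    for ec in evaluated:
        gold = ec.case
        extracted = ec.extraction.features
        expected_missing = set(gold.omitted_features)
        wrong_features = []
        for fid in FEATURE_IDS:
            if fid in expected_missing:
                continue  # omitted by construction; exclusion is correct
            resolved = ec.extraction.resolved.get(fid)
            if resolved is None or resolved[0] != gold.gold_categories[fid]:
                wrong_features.append(fid)
        extraction_ok = not wrong_features
        prediction_ok = (
            ec.predicted is not None
            and ec.predicted.label == gold.gold_class.label
        )
        excluded_as_expected = (
            ec.predicted is None
            and extraction_ok
            and ec.extraction.status is not Status.COMPLETE
            and bool(expected_missing)
        )
        if (extraction_ok and prediction_ok) or excluded_as_expected:
            continue
        if not extraction_ok:
            # only features whose gold category produced no mention at all
            # can be segmentation casualties; a negated or mis-resolved
            # mention means the concepts were seen but handled wrongly
            mentioned = {
                (m.feature_id, m.category_label) for m in ec.extraction.mentions
            }
            broke = any(
                (fid, gold.gold_categories[fid]) not in mentioned
                and _phrase_broken_by_segmentation(
                    ec.document, lex, fid, gold.gold_categories[fid]
                )
                for fid in wrong_features
            )
            if broke:
                out.tokenizer_errors += 1
            else:
                out.concept_errors += 1
        else:
            out.classification_errors += 1
    return out


def plot_confusion(cm: ConfusionMatrix, path: str | Path, title: str = "") -> Path:
    """Render the confusion matrix as a PNG heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(4), CLASS_LABELS)
    ax.set_yticks(range(4), CLASS_LABELS)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    if title:
        ax.set_title(title)
    for i in range(4):
        for j in range(4):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
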