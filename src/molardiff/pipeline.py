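"""End-to-end orchestration of the report-difficulty pipeline.

Stages: generate (or load) a corpus -> preprocess -> rule-based
extraction (INCOMPLETE reports excluded, with a count, mirroring the
exclusion of incomplete reports from the emulated study) -> ordinal
scoring of the extracted features -> neural classifier trained on the
train split -> prediction on both splits -> confusion matrices, metrics
and the error breakdown per split.

The classifier is trained on (extracted feature vector, rule-assigned
class) pairs — the network learns the scoring rule from the extraction
output, so extraction mistakes propagate into training exactly as they
would have in the emulated study. Evaluation always compares
predictions against the *gold* classes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import classifier as clf_mod
from .classifier import ClassifierConfig, TrainedModel
from .evaluate import (
    ConfusionMatrix,
    ErrorBreakdown,
    EvaluatedCase,
    MetricsReport,
    categorize_errors,
    confusion,
    metrics,
)
from .extract import Status, extract_report
from .lexicon import FeatureLexicon, build_default_lexicon
from .preprocess import preprocess
from .score import classify_score, total_score
from .synthdata import GeneratorConfig, GoldCase, generate_corpus

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "SplitResult", "run_pipeline"]


@dataclass
class SplitResult:
    name: str
    n_cases: int
    n_excluded: int
    confusion_matrix: ConfusionMatrix
    metrics: MetricsReport
    errors: ErrorBreakdown
    evaluated: list[EvaluatedCase] = field(repr=False, default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    def to_dict(self) -> dict:
        return {
            "split": self.name,
            "n_cases": self.n_cases,
            "n_excluded": self.n_excluded,
            "confusion_matrix": self.confusion_matrix.counts.tolist(),
            "metrics": self.metrics.to_dict(),
            "errors": self.errors.to_dict(),
        }


@dataclass
class PipelineResult:
    cases: list[GoldCase]
    model: TrainedModel
    train: SplitResult
    validation: SplitResult
    timings: dict[str, float]

    def metrics_json(self, include_timings: bool = False) -> str:
        # timings are excluded by default so the file is byte-identical
        # across runs with the same seed
        payload = {
            "train": self.train.to_dict(),
            "validation": self.validation.to_dict(),
        }
        if include_timings:
            payload["timings_s"] = {
                k: round(v, 3) for k, v in self.timings.items()
            }
        return json.dumps(payload, indent=2, sort_keys=True)


def _evaluate_split(
    name: str,
    evaluated: list[EvaluatedCase],
    lex: FeatureLexicon,
) -> SplitResult:
    scored = [ec for ec in evaluated if ec.predicted is not None]
    n_excluded = len(evaluated) - len(scored)
    cm = confusion(
        [ec.case.gold_class for ec in scored],
        [ec.predicted for ec in scored],
    )
    return SplitResult(
        name=name,
        n_cases=len(evaluated),
        n_excluded=n_excluded,
        confusion_matrix=cm,
        metrics=metrics(cm),
        errors=categorize_errors(evaluated, lex),
        evaluated=evaluated,
    )


def run_pipeline(
    gen_cfg: GeneratorConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    lex: FeatureLexicon | None = None,
    cases: Sequence[GoldCase] | None = None,
) -> PipelineResult:
    """Run the full pipeline; pass ``cases`` to reuse an existing corpus."""
    gen_cfg = gen_cfg or GeneratorConfig()
    clf_cfg = clf_cfg or ClassifierConfig(seed=gen_cfg.seed)
    lex = lex or build_default_lexicon()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if cases is None:
        cases = generate_corpus(gen_cfg, lex)
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    traces: list[tuple[GoldCase, object, object]] = []
    n_excluded = 0
    for case in cases:
        doc = preprocess(case.text, report_id=case.report_id)
        extraction = extract_report(doc, lex)
        if extraction.status is not Status.COMPLETE:
            n_excluded += 1
        traces.append((case, doc, extraction))
    timings["extract"] = time.perf_counter() - t0
    logger.info("excluded %d incomplete/conflicting reports", n_excluded)

    # scoring stage: rule class from extracted features, for training labels
    train_X, train_y = [], []
    for case, _doc, extraction in traces:
        if case.split == "train" and extraction.status is Status.COMPLETE:
            train_X.append(extraction.features)
            train_y.append(classify_score(total_score(extraction.features)))

    t0 = time.perf_counter()
    model = clf_mod.train(train_X, train_y, clf_cfg)
    timings["train"] = time.perf_counter() - t0
    logger.info(
        "classifier trained for %d epochs (early stop: %s)",
        model.n_epochs,
        model.stopped_early,
    )

    t0 = time.perf_counter()
    evaluated = {"train": [], "validation": []}
    for case, doc, extraction in traces:
        if extraction.status is Status.COMPLETE:
            predicted, _probs = model.predict(extraction.features)
        else:
            predicted = None
        evaluated[case.split].append(
            EvaluatedCase(
                case=case, document=doc, extraction=extraction, predicted=predicted
            )
        )
    train_res = _evaluate_split("train", evaluated["train"], lex)
    val_res = _evaluate_split("validation", evaluated["validation"], lex)
    timings["evaluate"] = time.perf_counter() - t0

    return PipelineResult(
        cases=list(cases),
        model=model,
        train=train_res,
        validation=val_res,
        timings=timings,
    )
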