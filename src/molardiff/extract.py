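"""Rule-based concept extraction from segmented report text.

For each sentence, lexicon synonym phrases are matched greedy
longest-first at word boundaries; once a span is consumed by a match, no
shorter overlapping synonym can fire inside it (so "no contact" is never
read as "contact"). A mention is flagged negated when a negation cue
("no", "not", "without", "denies") occurs within the three tokens
preceding it — unless the cue is part of the matched phrase itself,
which longest-match already guarantees for synonyms like "no contact".

Per report, each feature resolves to one category: negated mentions are
dropped; disagreements across sentences resolve to the last mentioning
sentence (radiology impressions conventionally conclude a report); two
categories of one feature in the same sentence are a genuine
contradiction and yield CONFLICT. A feature with no surviving mention
makes the report INCOMPLETE — such reports are excluded downstream,
mirroring the exclusion of incomplete reports from the study data.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import FEATURE_IDS, FeatureLexicon, phrase_priority
from .preprocess import Document, Sentence
from .score import FeatureVector

__all__ = [
    "NEGATION_CUES",
    "Status",
    "ConceptMention",
    "ExtractionResult",
    "match_concepts",
    "resolve_features",
    "extract_report",
    "extraction_table",
    "write_results_jsonl",
]

NEGATION_CUES = frozenset({"no", "not", "without", "denies"})
NEGATION_WINDOW = 3  # tokens


class Status(str, enum.Enum):
    COMPLETE = "COMPLETE"
    INCOMPLETE = "INCOMPLETE"
    CONFLICT = "CONFLICT"


@dataclass(frozen=True)
class ConceptMention:
    """One lexicon synonym matched in one sentence."""

    feature_id: str
    category_label: str
    matched_phrase: str
    sentence_index: int
    char_span: tuple[int, int]  # within the sentence, 0-based half-open
    negated: bool
    score: int


@dataclass
class ExtractionResult:
    """Per-report feature resolution outcome."""

    report_id: str
    status: Status
    features: FeatureVector | None = None
    missing_features: list[str] = field(default_factory=list)
    conflicting_features: list[str] = field(default_factory=list)
    mentions: list[ConceptMention] = field(default_factory=list)
    #: feature_id -> (category_label, score) for every feature that resolved
    resolved: dict[str, tuple[str, int]] = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "report_id": self.report_id,
            "status": self.status.value,
            "features": list(self.features.as_tuple()) if self.features else None,
            "resolved": {k: list(v) for k, v in self.resolved.items()},
            "missing_features": self.missing_features,
            "conflicting_features": self.conflicting_features,
            "mentions": [
                {
                    "feature_id": m.feature_id,
                    "category_label": m.category_label,
                    "matched_phrase": m.matched_phrase,
                    "sentence_index": m.sentence_index,
                    "char_span": list(m.char_span),
                    "negated": m.negated,
                    "score": m.score,
                }
                for m in self.mentions
            ],
        }


def _phrase_table(lex: FeatureLexicon) -> list[tuple[str, str, str, int, re.Pattern]]:
    """(phrase, feature, category, score, compiled pattern), longest first."""
    rows = []
    for concept in lex.concepts:
        score = lex.score_of(concept.feature_id, concept.category_label)
        for phrase in concept.synonyms:
            pat = re.compile(
                r"(?<![a-z0-9])" + re.escape(phrase) + r"(?![a-z0-9])"
            )
            rows.append(
                (phrase, concept.feature_id, concept.category_label, score, pat)
            )
    rows.sort(key=lambda r: (-phrase_priority(r[0]), r[0]))
    return rows


def _is_negated(sentence: Sentence, match_start: int) -> bool:
    """True when a negation cue sits within 3 tokens before the match."""
    preceding = [
        tok
        for tok, (s, e) in zip(sentence.tokens, sentence.token_spans)
        if e <= match_start
    ]
    return any(tok in NEGATION_CUES for tok in preceding[-NEGATION_WINDOW:])


def match_concepts(doc: Document, lex: FeatureLexicon) -> list[ConceptMention]:
    """Greedy longest-match-first synonym scan over every sentence."""
    table = _phrase_table(lex)
    mentions: list[ConceptMention] = []
    for sent in doc.sentences:
        consumed: list[tuple[int, int]] = []
        found: list[ConceptMention] = []
        for phrase, fid, label, score, pat in table:
            for m in pat.finditer(sent.text):
                s, e = m.span()
                if any(s < ce and cs < e for cs, ce in consumed):
                    continue  # span already eaten by a longer match
                consumed.append((s, e))
                found.append(
                    ConceptMention(
                        feature_id=fid,
                        category_label=label,
                        matched_phrase=sent.text[s:e],
                        sentence_index=sent.index,
                        char_span=(s, e),
                        negated=_is_negated(sent, s),
                        score=score,
                    )
                )
        found.sort(key=lambda m: m.char_span[0])
        mentions.extend(found)
    return mentions


def resolve_features(
    mentions: Sequence[ConceptMention], report_id: str = ""
) -> ExtractionResult:
    """Resolve one category per feature from a report's mentions."""
    result = ExtractionResult(report_id=report_id, status=Status.COMPLETE)
    result.mentions = list(mentions)
    for fid in FEATURE_IDS:
        surviving = [
            m for m in mentions if m.feature_id == fid and not m.negated
        ]
        if not surviving:
            result.missing_features.append(fid)
            continue
        by_sentence: dict[int, set[str]] = {}
        for m in surviving:
            by_sentence.setdefault(m.sentence_index, set()).add(m.category_label)
        if any(len(cats) > 1 for cats in by_sentence.values()):
            result.conflicting_features.append(fid)
            continue
        last = max(surviving, key=lambda m: (m.sentence_index, m.char_span[0]))
        result.resolved[fid] = (last.category_label, last.score)

    if result.missing_features:
        result.status = Status.INCOMPLETE
    elif result.conflicting_features:
        result.status = Status.CONFLICT
    else:
        result.status = Status.COMPLETE
        result.features = FeatureVector(
            *(result.resolved[fid][1] for fid in FEATURE_IDS)
        )
    return result


def extract_report(doc: Document, lex: FeatureLexicon) -> ExtractionResult:
    """match_concepts + resolve_features for one document."""
    return resolve_features(match_concepts(doc, lex), report_id=doc.report_id)


def extraction_table(results: Iterable[ExtractionResult]) -> pd.DataFrame:
    """Flat feature table: report_id, the four scores, status."""
    rows = []
    for r in results:
        rec = {"report_id": r.report_id, "status": r.status.value}
        for fid in FEATURE_IDS:
            rec[fid.lower()] = r.resolved.get(fid, (None, None))[1]
        rows.append(rec)
    return pd.DataFrame(rows)


def write_results_jsonl(
    results: Iterable[ExtractionResult], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in results:
            fh.write(json.dumps(r.to_record()) + "\n")
    return path
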