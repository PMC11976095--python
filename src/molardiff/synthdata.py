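"""Seeded synthetic CBCT-report corpus with gold labels.

Real mandibular third molar CBCT reports are private clinical documents,
so this module emulates them: each synthetic report states the tooth's
angulation, root count, root curvature and mandibular-canal relationship
— one sentence per feature, phrased with a randomly chosen lexicon
synonym and sentence template — interleaved with distractor sentences
(demographics, incidental findings) that contain no lexicon phrase.

Gold labels are exact by construction: categories are drawn per feature,
the gold score vector and difficulty class follow deterministically from
the scoring rules. Optional noise degrades the text:

* ``typo_rate`` — per-token character perturbations; tokens inside a
  feature synonym phrase may be corrupted at most once per report, so
  noise can break one feature's extractability but never all of them.
* ``omission_rate`` — per-feature chance that the feature sentence is
  dropped entirely, producing a gold-INCOMPLETE report (emulating the
  real corpus's excluded incomplete reports).

Everything is driven by one ``numpy`` generator seeded from the config,
so identical configs yield byte-identical corpora.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .lexicon import FEATURE_IDS, FeatureLexicon, build_default_lexicon
from .score import CLASS_BY_LABEL, DifficultyClass, FeatureVector, classify_score, total_score

__all__ = [
    "GeneratorConfig",
    "GoldCase",
    "sample_case",
    "render_report",
    "generate_corpus",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "export_reports_txt",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus-generation settings; defaults mirror the emulated study
    (738 reports split 556 train / 182 validation)."""

    n_reports: int = 738
    train_count: int = 556
    val_count: int = 182
    seed: int = 0
    #: feature_id -> probabilities over its categories in score order;
    #: None means uniform
    feature_distribution: Mapping[str, Sequence[float]] | None = None
    distractor_sentences_range: tuple[int, int] = (2, 5)
    typo_rate: float = 0.0
    omission_rate: float = 0.0
    paraphrase: bool = True

    def __post_init__(self) -> None:
        if self.train_count + self.val_count != self.n_reports:
            raise ValueError(
                f"train_count + val_count must equal n_reports "
                f"({self.train_count} + {self.val_count} != {self.n_reports})"
            )
        for name in ("typo_rate", "omission_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.distractor_sentences_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid distractor_sentences_range")
        if self.feature_distribution is not None:
            for fid, probs in self.feature_distribution.items():
                if fid not in FEATURE_IDS:
                    raise ValueError(f"unknown feature {fid!r} in distribution")
                p = np.asarray(list(probs), dtype=float)
                if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise ValueError(f"probabilities for {fid} must sum to 1")


@dataclass
class GoldCase:
    report_id: str
    gold_categories: dict[str, str]
    gold_vector: FeatureVector
    gold_class: DifficultyClass
    text: str = ""
    split: str = ""
    omitted_features: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "report_id": self.report_id,
            "text": self.text,
            "gold_categories": self.gold_categories,
            "gold_vector": list(self.gold_vector.as_tuple()),
            "gold_class": self.gold_class.label,
            "split": self.split,
            "omitted_features": self.omitted_features,
        }

    @classmethod
    def from_record(cls, rec: Mapping) -> "GoldCase":
        return cls(
            report_id=rec["report_id"],
            gold_categories=dict(rec["gold_categories"]),
            gold_vector=FeatureVector(*rec["gold_vector"]),
            gold_class=CLASS_BY_LABEL[rec["gold_class"]],
            text=rec["text"],
            split=rec.get("split", ""),
            omitted_features=list(rec.get("omitted_features", [])),
        )


# -- sentence templates ------------------------------------------------------
# {syn} is replaced by a lexicon synonym. Templates must not place a negation
# cue right before the phrase and must not themselves contain lexicon phrases.

_FEATURE_TEMPLATES: dict[str, tuple[str, ...]] = {
    "ANGULATION": (
        "the impacted third molar is {syn}.",
        "the lower third molar demonstrates {syn}.",
        "tooth 38 presents as {syn} on panoramic reconstruction.",
        "assessment of the long axis shows {syn}.",
    ),
    "ROOT_COUNT": (
        "the tooth has {syn}.",
        "root morphology reveals {syn}.",
        "{syn} are identified on cross-sectional views.",
        "examination of the root complex shows {syn}.",
    ),
    "ROOT_CURVATURE": (
        "the tooth exhibits {syn}.",
        "{syn} are seen on the sagittal sections.",
        "root form evaluation demonstrates {syn}.",
        "apical morphology is consistent with {syn}.",
    ),
    "CANAL_RELATION": (
        "relationship to the inferior alveolar nerve: {syn}.",
        "the root apices demonstrate {syn}.",
        "canal evaluation shows {syn}.",
        "with respect to the nerve canal there is {syn}.",
    ),
}

_DISTRACTORS: tuple[str, ...] = (
    "the patient is a {age} year old {sex}.",
    "cbct examination was performed for pre-surgical assessment.",
    "bone density in the region is within normal limits.",
    "the maxillary sinus floor appears intact.",
    "mild distal caries is present on the adjacent second molar.",
    "the periodontal ligament space of neighboring teeth appears normal.",
    "no periapical radiolucency is detected around the adjacent teeth.",
    "the cortical plates are preserved buccally and lingually.",
    "overlying soft tissues are unremarkable.",
    "the follicular space is within normal range.",
    "image quality is adequate for diagnostic evaluation.",
    "the patient reported intermittent pain in the retromolar region.",
    "the crown of the tooth is fully formed.",
    "the surrounding trabecular bone pattern is regular.",
    "the temporomandibular joints are not included in the field of view.",
    "clinical correlation is recommended.",
)

_SEXES = ("male", "female")


def sample_case(rng: np.random.Generator, cfg: GeneratorConfig) -> GoldCase:
    """Draw gold categories per feature; text is rendered separately."""
    lex = _DEFAULT_LEX
    categories: dict[str, str] = {}
    scores: list[int] = []
    for fid in FEATURE_IDS:
        labels = lex.schema[fid].labels
        if cfg.feature_distribution and fid in cfg.feature_distribution:
            probs = np.asarray(list(cfg.feature_distribution[fid]), dtype=float)
        else:
            probs = np.full(len(labels), 1.0 / len(labels))
        label = labels[int(rng.choice(len(labels), p=probs))]
        categories[fid] = label
        scores.append(lex.schema[fid].score_of(label))
    fv = FeatureVector(*scores)
    return GoldCase(
        report_id="",
        gold_categories=categories,
        gold_vector=fv,
        gold_class=classify_score(total_score(fv)),
    )


def _perturb_token(tok: str, rng: np.random.Generator) -> str:
    """One character-level typo: swap, drop, duplicate or substitute."""
    if len(tok) < 2:
        return tok + "q"
    i = int(rng.integers(0, len(tok) - 1))
    op = int(rng.integers(0, 4))
    if op == 0:  # swap adjacent
        return tok[:i] + tok[i + 1] + tok[i] + tok[i + 2:]
    if op == 1:  # drop
        return tok[:i] + tok[i + 1:]
    if op == 2:  # duplicate
        return tok[: i + 1] + tok[i] + tok[i + 1:]
    return tok[:i] + "abcdefghijklmnopqrstuvwxyz"[int(rng.integers(0, 26))] + tok[i + 1:]


def _apply_typos(
    sentence: str,
    protected: str | None,
    rng: np.random.Generator,
    typo_rate: float,
    synonym_typo_budget: list[int],
) -> str:
    """Per-token typos; tokens inside the protected synonym phrase draw on
    a report-level budget of one corruption."""
    if typo_rate <= 0:
        return sentence
    phrase_start = sentence.find(protected) if protected else -1
    phrase_end = phrase_start + len(protected) if phrase_start >= 0 else -1
    out: list[str] = []
    pos = 0
    for tok in sentence.split(" "):
        tok_start, tok_end = pos, pos + len(tok)
        pos = tok_end + 1
        if rng.random() < typo_rate and tok:
            in_phrase = phrase_start >= 0 and tok_start < phrase_end and tok_end > phrase_start
            if in_phrase:
                if synonym_typo_budget[0] > 0:
                    synonym_typo_budget[0] -= 1
                    tok = _perturb_token(tok, rng)
            else:
                tok = _perturb_token(tok, rng)
        out.append(tok)
    return " ".join(out)


def render_report(
    case: GoldCase,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    lex: FeatureLexicon,
) -> str:
    """Render a case to report text: one sentence per (non-omitted)
    feature plus interleaved distractors, with optional typo noise."""
    feature_sentences: list[tuple[str, str]] = []  # (sentence, synonym)
    omitted: list[str] = []
    for fid in FEATURE_IDS:
        if cfg.omission_rate > 0 and rng.random() < cfg.omission_rate:
            omitted.append(fid)
            continue
        synonyms = lex.synonyms_for(fid, case.gold_categories[fid])
        syn = synonyms[int(rng.integers(0, len(synonyms)))] if cfg.paraphrase else synonyms[0]
        templates = _FEATURE_TEMPLATES[fid]
        tmpl = templates[int(rng.integers(0, len(templates)))] if cfg.paraphrase else templates[0]
        feature_sentences.append((tmpl.format(syn=syn), syn))

    lo, hi = cfg.distractor_sentences_range
    n_distract = int(rng.integers(lo, hi + 1))
    distractors = []
    for j in rng.choice(len(_DISTRACTORS), size=n_distract, replace=False):
        d = _DISTRACTORS[int(j)].format(
            age=int(rng.integers(18, 70)), sex=_SEXES[int(rng.integers(0, 2))]
        )
        distractors.append((d, None))

    sentences = feature_sentences + distractors
    order = rng.permutation(len(sentences))
    budget = [1]  # at most one synonym-phrase token corrupted per report
    rendered = [
        _apply_typos(sentences[i][0], sentences[i][1], rng, cfg.typo_rate, budget)
        for i in order
    ]
    case.omitted_features = omitted
    return " ".join(rendered)


def generate_corpus(
    cfg: GeneratorConfig | None = None,
    lex: FeatureLexicon | None = None,
) -> list[GoldCase]:
    """Generate the full corpus with stratified train/validation splits."""
    cfg = cfg or GeneratorConfig()
    lex = lex or _DEFAULT_LEX
    rng = np.random.default_rng(cfg.seed)
    cases: list[GoldCase] = []
    for i in range(cfg.n_reports):
        case = sample_case(rng, cfg)
        case.report_id = f"R{i:04d}"
        case.text = render_report(case, rng, cfg, lex)
        cases.append(case)

    labels = [c.gold_class.label for c in cases]
    idx = np.arange(cfg.n_reports)
    try:
        train_idx, val_idx = train_test_split(
            idx,
            train_size=cfg.train_count,
            test_size=cfg.val_count,
            random_state=cfg.seed,
            stratify=labels,
        )
    except ValueError:
        logger.warning(
            "a difficulty class is too rare for stratification; "
            "falling back to a random split"
        )
        train_idx, val_idx = train_test_split(
            idx,
            train_size=cfg.train_count,
            test_size=cfg.val_count,
            random_state=cfg.seed,
        )
    train_set = set(int(i) for i in train_idx)
    for i, case in enumerate(cases):
        case.split = "train" if i in train_set else "validation"
    return cases


def write_corpus_jsonl(cases: Sequence[GoldCase], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for c in cases:
            fh.write(json.dumps(c.to_record(), sort_keys=True) + "\n")
    return path


def read_corpus_jsonl(path: str | Path) -> list[GoldCase]:
    cases = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                cases.append(GoldCase.from_record(json.loads(line)))
    return cases


def export_reports_txt(cases: Sequence[GoldCase], out_dir: str | Path) -> Path:
    """One plain-text file per report, for shell-level demos."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for c in cases:
        (out_dir / f"{c.report_id}.txt").write_text(c.text + "\n", encoding="utf-8")
    return out_dir


_DEFAULT_LEX = build_default_lexicon()
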