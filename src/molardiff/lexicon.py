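"""Feature schema and synonym ("concept") dictionaries.

Four anatomical features drive the difficulty score of an impacted
mandibular third molar, each with an ordinal categorical scale:

* ``ANGULATION`` — Mesioangular (1), Horizontal (2), Vertical (3),
  Distoangular (4)
* ``ROOT_COUNT`` — Single fused root (1), Two roots (2), Three or more
  roots (3)
* ``ROOT_CURVATURE`` — Incomplete roots (1), Straight roots (2),
  Dilacerated roots (3)
* ``CANAL_RELATION`` — No contact (1), Approximation (2), Contact (3),
  Inside (4)

A *concept* is the set of report-language phrases that denote one
category of one feature. The default synonym inventory shipped here is a
clinically plausible stand-in written for this package (the source
scoring system's own concept tables are not published); it is
configuration, not algorithm, and can be replaced wholesale via
:func:`load_lexicon`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "FEATURE_IDS",
    "FeatureSchema",
    "Concept",
    "FeatureLexicon",
    "LexiconError",
    "LexiconParseError",
    "LexiconValidationError",
    "build_default_lexicon",
    "load_lexicon",
    "save_lexicon",
]

FEATURE_IDS = ("ANGULATION", "ROOT_COUNT", "ROOT_CURVATURE", "CANAL_RELATION")

#: Categories and scores exactly as printed in the published scales.
DEFAULT_SCHEMA: dict[str, tuple[tuple[str, int], ...]] = {
    "ANGULATION": (
        ("Mesioangular", 1),
        ("Horizontal", 2),
        ("Vertical", 3),
        ("Distoangular", 4),
    ),
    "ROOT_COUNT": (
        ("Single fused root", 1),
        ("Two roots", 2),
        ("Three or more roots", 3),
    ),
    "ROOT_CURVATURE": (
        ("Incomplete roots", 1),
        ("Straight roots", 2),
        ("Dilacerated roots", 3),
    ),
    "CANAL_RELATION": (
        ("No contact", 1),
        ("Approximation", 2),
        ("Contact", 3),
        ("Inside", 4),
    ),
}

#: Required category count per feature (schema invariant).
SCHEMA_SIZES = {
    "ANGULATION": 4,
    "ROOT_COUNT": 3,
    "ROOT_CURVATURE": 3,
    "CANAL_RELATION": 4,
}


class LexiconError(ValueError):
    """Base class for lexicon configuration problems."""


class LexiconParseError(LexiconError):
    """The config file could not be parsed or has the wrong shape."""


class LexiconValidationError(LexiconError):
    """The parsed lexicon violates a schema or concept invariant."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered categorical scale of one feature."""

    feature_id: str
    categories: tuple[tuple[str, int], ...]  # (label, score), score-ordered

    def score_of(self, label: str) -> int:
        for lab, score in self.categories:
            if lab == label:
                return score
        raise KeyError(f"{self.feature_id} has no category {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.categories)

    @property
    def max_score(self) -> int:
        return max(score for _, score in self.categories)


@dataclass(frozen=True)
class Concept:
    """Synonym phrases denoting one category of one feature."""

    feature_id: str
    category_label: str
    synonyms: tuple[str, ...]
    priority: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise LexiconValidationError(
                f"concept ({self.feature_id}, {self.category_label}) "
                "has no synonyms"
            )
        for s in self.synonyms:
            if not s.strip():
                raise LexiconValidationError(
                    f"concept ({self.feature_id}, {self.category_label}) "
                    "contains an empty synonym"
                )
            if s != s.lower():
                raise LexiconValidationError(
                    f"synonym {s!r} of ({self.feature_id}, "
                    f"{self.category_label}) is not lowercase"
                )
        if self.priority == 0:
            object.__setattr__(
                self, "priority", max(phrase_priority(s) for s in self.synonyms)
            )


def phrase_priority(phrase: str) -> int:
    """Longest-match rank of a synonym phrase: its token count."""
    return len(phrase.split())


@dataclass(frozen=True)
class FeatureLexicon:
    """Validated bundle of feature schemas and synonym concepts."""

    schema: Mapping[str, FeatureSchema]
    concepts: tuple[Concept, ...]
    version: str = "default-1"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup -----------------------------------------------------------

    def lookup(self, phrase: str) -> tuple[str, str, int]:
        """Resolve a synonym phrase to (feature_id, category_label, score)."""
        key = phrase.strip().lower()
        hit = self._phrase_index().get(key)
        if hit is None:
            raise KeyError(f"phrase {key!r} is not in the lexicon")
        feature_id, label = hit
        return feature_id, label, self.schema[feature_id].score_of(label)

    def _phrase_index(self) -> dict[str, tuple[str, str]]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {}
            for c in self.concepts:
                for s in c.synonyms:
                    idx[s] = (c.feature_id, c.category_label)
            object.__setattr__(self, "_idx", idx)
        return idx

    def concepts_for(self, feature_id: str) -> list[Concept]:
        return [c for c in self.concepts if c.feature_id == feature_id]

    def synonyms_for(self, feature_id: str, category_label: str) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.concepts:
            if c.feature_id == feature_id and c.category_label == category_label:
                out.extend(c.synonyms)
        return tuple(out)

    def score_of(self, feature_id: str, category_label: str) -> int:
        return self.schema[feature_id].score_of(category_label)

    def category_pairs(self) -> list[tuple[str, str]]:
        """All (feature_id, category_label) pairs, schema order."""
        return [
            (fid, lab)
            for fid in FEATURE_IDS
            for lab in self.schema[fid].labels
        ]

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if set(self.schema) != set(FEATURE_IDS):
            raise LexiconValidationError(
                f"schema must define exactly the features {FEATURE_IDS}, "
                f"got {sorted(self.schema)}"
            )
        for fid, expected_n in SCHEMA_SIZES.items():
            cats = self.schema[fid].categories
            scores = sorted(score for _, score in cats)
            if len(cats) != expected_n or scores != list(range(1, expected_n + 1)):
                raise LexiconValidationError(
                    f"{fid} must have exactly {expected_n} categories with "
                    f"contiguous scores 1..{expected_n}, got {cats}"
                )
        valid_pairs = set()
        for fid in FEATURE_IDS:
            valid_pairs.update((fid, lab) for lab in self.schema[fid].labels)

        # every concept points at a real category
        for c in self.concepts:
            if (c.feature_id, c.category_label) not in valid_pairs:
                raise LexiconValidationError(
                    f"concept references unknown category "
                    f"({c.feature_id}, {c.category_label})"
                )

        # coverage: every category has at least one synonym
        covered = {(c.feature_id, c.category_label) for c in self.concepts}
        missing = sorted(valid_pairs - covered)
        if missing:
            raise LexiconValidationError(
                f"categories without any synonym concept: {missing}"
            )

        # no synonym shared by two categories of the same feature
        seen: dict[tuple[str, str], str] = {}
        for c in self.concepts:
            for s in c.synonyms:
                key = (c.feature_id, s)
                if key in seen and seen[key] != c.category_label:
                    raise LexiconValidationError(
                        f"synonym {s!r} of feature {c.feature_id} is listed "
                        f"under both {seen[key]!r} and {c.category_label!r}"
                    )
                seen[key] = c.category_label

        # longest-match safety: a phrase embedded in another category's
        # longer phrase must rank strictly lower ("no contact" must never
        # be consumed as "contact")
        by_feature: dict[str, list[tuple[str, str]]] = {}
        for c in self.concepts:
            for s in c.synonyms:
                by_feature.setdefault(c.feature_id, []).append(
                    (s, c.category_label)
                )
        for fid, phrases in by_feature.items():
            for s1, lab1 in phrases:
                for s2, lab2 in phrases:
                    if lab1 == lab2 or s1 == s2:
                        continue
                    if s1 in s2 and phrase_priority(s1) >= phrase_priority(s2):
                        raise LexiconValidationError(
                            f"{fid}: phrase {s1!r} ({lab1}) is contained in "
                            f"{s2!r} ({lab2}) but does not rank below it"
                        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {"version": self.version}
        for fid in FEATURE_IDS:
            entries = []
            for lab, score in self.schema[fid].categories:
                entries.append(
                    {
                        "label": lab,
                        "score": score,
                        "synonyms": list(self.synonyms_for(fid, lab)),
                    }
                )
            out[fid] = entries
        return out


def _lexicon_from_dict(data: Mapping, source: str = "<dict>") -> FeatureLexicon:
    if not isinstance(data, Mapping):
        raise LexiconParseError(f"{source}: top level must be a mapping")
    version = str(data.get("version", "custom"))
    schema: dict[str, FeatureSchema] = {}
    concepts: list[Concept] = []
    for fid in FEATURE_IDS:
        entries = data.get(fid)
        if entries is None:
            raise LexiconParseError(f"{source}: missing feature key {fid!r}")
        cats: list[tuple[str, int]] = []
        for i, entry in enumerate(entries):
            try:
                label = str(entry["label"])
                score = int(entry["score"])
                synonyms = tuple(str(s).strip().lower() for s in entry["synonyms"])
            except (KeyError, TypeError, ValueError) as exc:
                raise LexiconParseError(
                    f"{source}: malformed entry {fid}[{i}]: {exc}"
                ) from exc
            cats.append((label, score))
            concepts.append(Concept(fid, label, synonyms))
        cats.sort(key=lambda c: c[1])
        schema[fid] = FeatureSchema(fid, tuple(cats))
    return FeatureLexicon(schema=schema, concepts=tuple(concepts), version=version)


def load_lexicon(path: str | Path) -> FeatureLexicon:
    """Load and validate a lexicon from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise LexiconParseError(f"{path}: cannot parse config: {exc}") from exc
    return _lexicon_from_dict(data, source=str(path))


def save_lexicon(lex: FeatureLexicon, path: str | Path) -> Path:
    """Serialize a lexicon to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    data = lex.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(data, sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )
    return path


# ---------------------------------------------------------------------------
# Default synonym inventory. Written for this package; clinically plausible
# report phrasings, not the (unpublished) original concept tables.
# ---------------------------------------------------------------------------

_DEFAULT_SYNONYMS: dict[tuple[str, str], tuple[str, ...]] = {
    ("ANGULATION", "Mesioangular"): (
        "mesioangular",
        "mesioangular impaction",
        "mesially tilted",
        "mesially inclined",
        "mesial angulation",
        "tilted mesially",
    ),
    ("ANGULATION", "Horizontal"): (
        "horizontal",
        "horizontally impacted",
        "horizontal impaction",
        "horizontal angulation",
        "lying horizontally",
    ),
    ("ANGULATION", "Vertical"): (
        "vertical",
        "vertically positioned",
        "vertical impaction",
        "vertical angulation",
        "upright position",
    ),
    ("ANGULATION", "Distoangular"): (
        "distoangular",
        "distoangular impaction",
        "distally tilted",
        "distally inclined",
        "distal angulation",
        "tilted distally",
    ),
    ("ROOT_COUNT", "Single fused root"): (
        "single fused root",
        "single root",
        "one root",
        "1 root",
        "fused root",
        "fused roots",
        "single conical root",
    ),
    ("ROOT_COUNT", "Two roots"): (
        "two roots",
        "2 roots",
        "two separate roots",
        "two-rooted",
        "bifid roots",
    ),
    ("ROOT_COUNT", "Three or more roots"): (
        "three or more roots",
        "three roots",
        "3 roots",
        "four roots",
        "4 roots",
        "three separate roots",
        "multiple roots",
    ),
    ("ROOT_CURVATURE", "Incomplete roots"): (
        "incomplete roots",
        "incomplete root formation",
        "incompletely formed roots",
        "immature roots",
        "open apices",
        "open root apices",
    ),
    ("ROOT_CURVATURE", "Straight roots"): (
        "straight roots",
        "straight root",
        "roots are straight",
        "straight root morphology",
        "no root curvature",
    ),
    ("ROOT_CURVATURE", "Dilacerated roots"): (
        "dilacerated roots",
        "dilacerated",
        "dilaceration",
        "root dilaceration",
        "severely curved roots",
        "hooked roots",
    ),
    ("CANAL_RELATION", "No contact"): (
        "no contact",
        "no contact with the mandibular canal",
        "not in contact",
        "away from the mandibular canal",
        "no communication with the canal",
        "clearly separated from the canal",
    ),
    ("CANAL_RELATION", "Approximation"): (
        "approximation",
        "approximating the mandibular canal",
        "close to the mandibular canal",
        "in close proximity to the canal",
        "near the mandibular canal",
        "approximation to the canal",
    ),
    ("CANAL_RELATION", "Contact"): (
        "contact",
        "contact with the mandibular canal",
        "in contact with the mandibular canal",
        "contacting the mandibular canal",
        "touching the mandibular canal",
        "contact with the inferior alveolar canal",
    ),
    ("CANAL_RELATION", "Inside"): (
        "inside",
        "inside the mandibular canal",
        "within the mandibular canal",
        "penetrating the mandibular canal",
        "root apex inside the mandibular canal",
        "passing through the canal",
    ),
}


def build_default_lexicon() -> FeatureLexicon:
    """The package's built-in lexicon: 14 categories, >=3 synonyms each."""
    schema = {
        fid: FeatureSchema(fid, cats) for fid, cats in DEFAULT_SCHEMA.items()
    }
    concepts = tuple(
        Concept(fid, label, synonyms)
        for (fid, label), synonyms in _DEFAULT_SYNONYMS.items()
    )
    return FeatureLexicon(schema=schema, concepts=concepts, version="default-1")
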