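"""Concept matching and per-report feature resolution: longest match,
negation, last-mention tie-break, conflict/incomplete contracts."""

import numpy as np
import pytest

from molardiff.extract import (
    Status,
    extract_report,
    match_concepts,
    resolve_features,
)
from molardiff.preprocess import preprocess
from molardiff.score import FeatureVector


def _mentions(text, lex):
    return match_concepts(preprocess(text), lex)


def test_no_contact_is_a_match_not_a_negation(lex):
    mentions = _mentions("the roots show no contact with the mandibular canal", lex)
    assert len(mentions) == 1
    m = mentions[0]
    assert (m.feature_id, m.category_label) == ("CANAL_RELATION", "No contact")
    assert m.negated is False
    # longest-match: no Contact mention may ever fire on that span
    assert not any(m.category_label == "Contact" for m in mentions)


def test_two_feature_sentence(lex):
    mentions = _mentions("tooth is mesioangular with two roots", lex)
    got = {(m.feature_id, m.category_label) for m in mentions}
    assert got == {("ANGULATION", "Mesioangular"), ("ROOT_COUNT", "Two roots")}


def test_sentence_without_lexicon_phrases(lex):
    assert _mentions("the patient reported intermittent pain", lex) == []


def test_negation_window_marks_mention(lex):
    mentions = _mentions("the roots are not dilacerated", lex)
    assert len(mentions) == 1
    assert mentions[0].negated is True
    result = resolve_features(mentions, "r1")
    assert result.status is Status.INCOMPLETE
    assert "ROOT_CURVATURE" in result.missing_features


def test_negation_cue_beyond_window_does_not_negate(lex):
    mentions = _mentions(
        "there is no sign of resorption, rather clearly dilacerated roots", lex
    )
    (m,) = [m for m in mentions if m.feature_id == "ROOT_CURVATURE"]
    assert m.negated is False


def test_numeric_root_phrases_resolve(lex):
    for text, label in [
        ("the tooth has 2 roots", "Two roots"),
        ("the tooth has 3 roots", "Three or more roots"),
        ("the tooth has two roots", "Two roots"),
    ]:
        (m,) = _mentions(text, lex)
        assert m.category_label == label


def test_last_sentence_wins_across_sentences(lex):
    text = (
        "initial view suggests the tooth is vertical. bone quality is fair. "
        "two roots are present. straight roots are noted. "
        "impression: the tooth is distoangular with no contact."
    )
    result = extract_report(preprocess(text, report_id="r2"), lex)
    assert result.status is Status.COMPLETE
    assert result.resolved["ANGULATION"] == ("Distoangular", 4)
    assert result.features == FeatureVector(4, 2, 2, 1)


def test_same_sentence_contradiction_is_conflict(lex):
    text = (
        "the tooth is vertical and also distoangular. two roots. "
        "straight roots. no contact."
    )
    result = extract_report(preprocess(text, report_id="r3"), lex)
    assert result.status is Status.CONFLICT
    assert result.conflicting_features == ["ANGULATION"]
    assert result.features is None


def test_missing_feature_yields_incomplete(lex):
    text = "the tooth is vertical. two roots. no contact."
    result = extract_report(preprocess(text, report_id="r4"), lex)
    assert result.status is Status.INCOMPLETE
    assert result.missing_features == ["ROOT_CURVATURE"]


def test_complete_extraction_round_trip_on_clean_corpus(lex, clean_corpus):
    _cfg, cases = clean_corpus
    for case in cases:
        result = extract_report(preprocess(case.text, case.report_id), lex)
        assert result.status is Status.COMPLETE
        assert result.features == case.gold_vector
        got = {fid: lab for fid, (lab, _s) in result.resolved.items()}
        assert got == case.gold_categories


def test_distractor_permutation_stability(lex):
    feature_sentences = [
        "the tooth is horizontal.",
        "two roots are seen.",
        "dilacerated roots are present.",
        "there is contact with the mandibular canal.",
    ]
    distractors = [
        "the patient is a 40 year old male.",
        "image quality is adequate.",
        "the sinus floor is intact.",
    ]
    rng = np.random.default_rng(0)
    reference = None
    for _ in range(10):
        sentences = feature_sentences + distractors
        rng.shuffle(sentences)
        result = extract_report(preprocess(" ".join(sentences)), lex)
        assert result.status is Status.COMPLETE
        if reference is None:
            reference = result.features
        assert result.features == reference == FeatureVector(2, 2, 3, 3)
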