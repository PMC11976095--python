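"""Metric identities, confusion-matrix conservation, error taxonomy."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from molardiff.evaluate import (
    ConfusionMatrix,
    EvaluatedCase,
    categorize_errors,
    confusion,
    metrics,
)
from molardiff.extract import Status, extract_report
from molardiff.preprocess import preprocess
from molardiff.score import CLASSES, CLASS_BY_LABEL, classify_score, total_score


def test_perfect_prediction_gives_diagonal():
    gold = [CLASSES[i % 4] for i in range(10)]
    cm = confusion(gold, gold)
    assert np.trace(cm.counts) == 10 == cm.total
    rep = metrics(cm)
    assert rep.accuracy == 1.0
    for label in ("D1", "D2", "D3", "D4"):
        assert rep.per_class[label] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    assert rep.totals == {"precision": 1.0, "recall": 1.0, "f1": 1.0}


def test_single_off_diagonal_cell():
    cm = confusion(["D1"], ["D4"])
    assert cm.counts[0, 3] == 1
    assert cm.counts.sum() == 1
    rep = metrics(cm)
    assert rep.accuracy == 0.0
    # empty rows/columns yield 0, never NaN
    assert rep.per_class["D2"] == {"precision": 0.0, "recall": 0.0, "f1": 0.0}


def test_toy_matrix_hand_arithmetic():
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 0] = 8
    counts[0, 1] = 2
    counts[1, 1] = 10
    rep = metrics(ConfusionMatrix(counts))
    assert rep.per_class["D1"]["recall"] == pytest.approx(0.8)
    assert rep.per_class["D2"]["precision"] == pytest.approx(10 / 12)
    assert rep.accuracy == pytest.approx(18 / 20)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion(["D1", "D2"], ["D1"])


def test_conservation_and_macro_identity_on_random_pairs():
    rng = np.random.default_rng(0)
    labels = [c.label for c in CLASSES]
    for _ in range(5):
        gold = [labels[i] for i in rng.integers(0, 4, size=200)]
        pred = [labels[i] for i in rng.integers(0, 4, size=200)]
        cm = confusion(gold, pred)
        assert cm.total == 200
        rep = metrics(cm)
        # micro accuracy equals the directly computed exact-match rate
        direct = np.mean([g == p for g, p in zip(gold, pred)])
        assert rep.accuracy == pytest.approx(direct)
        # macro totals equal unweighted means of per-class values
        for m in ("precision", "recall", "f1"):
            assert rep.totals[m] == pytest.approx(
                np.mean([rep.per_class[lab][m] for lab in labels])
            )
        # per-class f1 is the harmonic mean of its precision and recall
        for lab in labels:
            pc = rep.per_class[lab]
            if pc["precision"] + pc["recall"]:
                assert pc["f1"] == pytest.approx(
                    2 * pc["precision"] * pc["recall"]
                    / (pc["precision"] + pc["recall"])
                )
        # cross-check against the reference implementation
        p, r, f, _ = precision_recall_fscore_support(
            gold, pred, labels=labels, average="macro", zero_division=0
        )
        assert rep.totals["precision"] == pytest.approx(p)
        assert rep.totals["recall"] == pytest.approx(r)
        assert rep.totals["f1"] == pytest.approx(f)


def _evaluated(case, lex, predicted_label):
    doc = preprocess(case.text, case.report_id)
    res = extract_report(doc, lex)
    pred = CLASS_BY_LABEL[predicted_label] if predicted_label else None
    return EvaluatedCase(case=case, document=doc, extraction=res, predicted=pred)


def test_error_taxonomy(lex, clean_corpus):
    _cfg, cases = clean_corpus

    # all correct -> no errors
    correct = [_evaluated(c, lex, c.gold_class.label) for c in cases[:20]]
    assert categorize_errors(correct, lex).to_dict()["total"] == 0

    # correct features, wrong predicted class -> classification error
    flipped = []
    for c in cases[:10]:
        wrong = "D1" if c.gold_class.label != "D1" else "D2"
        flipped.append(_evaluated(c, lex, wrong))
    bd = categorize_errors(flipped, lex)
    assert bd.classification_errors == 10
    assert bd.concept_errors == 0 and bd.tokenizer_errors == 0

    # a gold synonym missing from the text entirely -> concept error
    import copy

    damaged = copy.deepcopy(cases[0])
    for syn in lex.synonyms_for("ROOT_CURVATURE",
                                damaged.gold_categories["ROOT_CURVATURE"]):
        damaged.text = damaged.text.replace(syn, "qqq")
    bd = categorize_errors([_evaluated(damaged, lex, None)], lex)
    assert bd.concept_errors == 1 and bd.tokenizer_errors == 0


def test_tokenizer_error_detected(lex, clean_corpus):
    """A sentence break injected inside a synonym phrase is triaged as a
    tokenizer error, not a concept error."""
    import copy

    _cfg, cases = clean_corpus
    case = copy.deepcopy(cases[1])
    fid = "ROOT_COUNT"
    label = case.gold_categories[fid]
    for syn in sorted(lex.synonyms_for(fid, label), key=len, reverse=True):
        if syn in case.text and " " in syn:
            head, tail = syn.split(" ", 1)
            case.text = case.text.replace(syn, f"{head}. {tail}")
            break
    else:
        pytest.skip("case lacks a multiword synonym occurrence")
    ec = _evaluated(case, lex, None)
    assert fid in ec.extraction.missing_features or (
        ec.extraction.resolved.get(fid, (None,))[0] != label
    )
    bd = categorize_errors([ec], lex)
    assert bd.tokenizer_errors == 1 and bd.concept_errors == 0


def test_excluded_as_constructed_is_not_an_error(lex):
    from molardiff.synthdata import GeneratorConfig, generate_corpus

    cfg = GeneratorConfig(n_reports=10, train_count=8, val_count=2, seed=9,
                          omission_rate=1.0)
    cases = generate_corpus(cfg, lex)
    evaluated = [_evaluated(c, lex, None) for c in cases]
    assert categorize_errors(evaluated, lex).to_dict()["total"] == 0
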