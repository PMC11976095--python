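"""Synthetic corpus generator: gold consistency, seeded determinism,
sampling frequencies, splits, omission and typo noise behavior."""

import numpy as np
import pytest

from molardiff.extract import Status, extract_report
from molardiff.preprocess import preprocess
from molardiff.score import classify_score, total_score
from molardiff.synthdata import (
    GeneratorConfig,
    generate_corpus,
    read_corpus_jsonl,
    sample_case,
    write_corpus_jsonl,
)


def test_gold_class_consistent_with_scoring(clean_corpus):
    _cfg, cases = clean_corpus
    for case in cases:
        assert case.gold_class is classify_score(total_score(case.gold_vector))


def test_default_config_mirrors_emulated_study():
    cfg = GeneratorConfig()
    assert (cfg.n_reports, cfg.train_count, cfg.val_count) == (738, 556, 182)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="train_count"):
        GeneratorConfig(n_reports=10, train_count=5, val_count=4)
    with pytest.raises(ValueError, match="typo_rate"):
        GeneratorConfig(typo_rate=1.5)
    with pytest.raises(ValueError, match="sum to 1"):
        GeneratorConfig(feature_distribution={"ANGULATION": [0.5, 0.5, 0.5, 0.5]})


def test_uniform_sampling_frequencies():
    rng = np.random.default_rng(17)
    cfg = GeneratorConfig(n_reports=2, train_count=1, val_count=1)
    n = 10_000
    counts = np.zeros(4)
    for _ in range(n):
        case = sample_case(rng, cfg)
        counts[case.gold_vector.angulation_score - 1] += 1
    se = np.sqrt(0.25 * 0.75 / n)
    assert np.all(np.abs(counts / n - 0.25) < 3 * se)


def test_point_mass_distribution_forces_d1():
    rng = np.random.default_rng(1)
    cfg = GeneratorConfig(
        n_reports=2,
        train_count=1,
        val_count=1,
        feature_distribution={
            "ANGULATION": [1, 0, 0, 0],
            "ROOT_COUNT": [1, 0, 0],
            "ROOT_CURVATURE": [1, 0, 0],
            "CANAL_RELATION": [1, 0, 0, 0],
        },
    )
    for _ in range(50):
        case = sample_case(rng, cfg)
        assert case.gold_class.label == "D1"
        assert total_score(case.gold_vector) == 4


def test_seeded_corpus_is_byte_identical(tmp_path, lex):
    cfg = GeneratorConfig(n_reports=40, train_count=30, val_count=10, seed=7,
                          typo_rate=0.02)
    p1 = write_corpus_jsonl(generate_corpus(cfg, lex), tmp_path / "a.jsonl")
    p2 = write_corpus_jsonl(generate_corpus(cfg, lex), tmp_path / "b.jsonl")
    assert p1.read_bytes() == p2.read_bytes()
    other = generate_corpus(
        GeneratorConfig(n_reports=40, train_count=30, val_count=10, seed=8,
                        typo_rate=0.02),
        lex,
    )
    assert len(other) == 40
    assert write_corpus_jsonl(other, tmp_path / "c.jsonl").read_bytes() != p1.read_bytes()


def test_jsonl_roundtrip(tmp_path, clean_corpus):
    _cfg, cases = clean_corpus
    path = write_corpus_jsonl(cases, tmp_path / "corpus.jsonl")
    loaded = read_corpus_jsonl(path)
    assert len(loaded) == len(cases)
    for a, b in zip(cases, loaded):
        assert a.to_record() == b.to_record()


def test_split_counts_and_stratification(clean_corpus):
    cfg, cases = clean_corpus
    assert sum(c.split == "train" for c in cases) == cfg.train_count
    assert sum(c.split == "validation" for c in cases) == cfg.val_count
    frac = cfg.train_count / cfg.n_reports
    from collections import Counter

    totals = Counter(c.gold_class.label for c in cases)
    in_train = Counter(c.gold_class.label for c in cases if c.split == "train")
    for label, n in totals.items():
        assert abs(in_train[label] - frac * n) <= 1


def test_clean_text_contains_every_gold_synonym(clean_corpus, lex):
    _cfg, cases = clean_corpus
    for case in cases[:30]:
        for fid, label in case.gold_categories.items():
            assert any(s in case.text for s in lex.synonyms_for(fid, label))


def test_forced_omission_makes_reports_incomplete(lex):
    cfg = GeneratorConfig(
        n_reports=10, train_count=8, val_count=2, seed=4, omission_rate=1.0
    )
    cases = generate_corpus(cfg, lex)
    for case in cases:
        assert set(case.omitted_features) == {
            "ANGULATION",
            "ROOT_COUNT",
            "ROOT_CURVATURE",
            "CANAL_RELATION",
        }
        res = extract_report(preprocess(case.text, case.report_id), lex)
        assert res.status is Status.INCOMPLETE


def test_typos_corrupt_at_most_one_synonym_phrase_per_report(lex):
    cfg = GeneratorConfig(
        n_reports=150, train_count=120, val_count=30, seed=6, typo_rate=0.25
    )
    cases = generate_corpus(cfg, lex)
    n_broken = []
    for case in cases:
        res = extract_report(preprocess(case.text, case.report_id), lex)
        wrong = sum(
            1
            for fid, label in case.gold_categories.items()
            if res.resolved.get(fid, (None,))[0] != label
        )
        n_broken.append(wrong)
    # heavy typo noise may break one feature, never more than one
    assert max(n_broken) <= 1
    assert any(n == 1 for n in n_broken)
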