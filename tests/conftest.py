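import pytest

from molardiff.classifier import ClassifierConfig, train
from molardiff.lexicon import build_default_lexicon
from molardiff.score import enumerate_combinations
from molardiff.synthdata import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def lex():
    return build_default_lexicon()


@pytest.fixture(scope="session")
def oracle_table():
    """All 144 (FeatureVector, total, DifficultyClass) combinations."""
    return enumerate_combinations()


@pytest.fixture(scope="session")
def clean_corpus(lex):
    """Noise-free 120-report corpus with a 90/30 split."""
    cfg = GeneratorConfig(n_reports=120, train_count=90, val_count=30, seed=11)
    return cfg, generate_corpus(cfg, lex)


@pytest.fixture(scope="session")
def oracle_model(oracle_table):
    """Classifier trained once on the full 144-combination table."""
    fvs = [fv for fv, _, _ in oracle_table]
    classes = [c for _, _, c in oracle_table]
    return train(fvs, classes, ClassifierConfig(seed=0))
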