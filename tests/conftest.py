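import numpy as np
import pytest

from epochsift.consensus import majority_vote
from epochsift.epoch_io import Epoch
from epochsift.features import extract_table
from epochsift.synthetic import (
    ARTEFACT_KINDS,
    DEFAULT_PANEL,
    GeneratorSpec,
    gen_clean_epoch,
    inject_artefact,
    simulate_raters,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gen_spec():
    return GeneratorSpec(seed=7)


@pytest.fixture
def clean_epoch(gen_spec):
    return gen_clean_epoch(gen_spec, np.random.default_rng(7))


def random_epochs(n, seed=11, fs=2000.0, n_samples=3000):
    """Plain white/coloured random epochs for oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if i % 2 == 0:
            x = rng.standard_normal(n_samples) * 20
        else:
            spec = GeneratorSpec(seed=seed + i)
            x = gen_clean_epoch(spec, rng).samples
        out.append(Epoch(samples=x, fs=fs))
    return out


@pytest.fixture(scope="session")
def labelled_set():
    """Small balanced train/test sets of clean and artefactual epochs."""
    spec = GeneratorSpec(seed=1)

    def make(seed, n_clean, n_art):
        r = np.random.default_rng(seed)
        eps, y = [], []
        for _ in range(n_clean):
            eps.append(gen_clean_epoch(spec, r))
            y.append(0)
        for i in range(n_art):
            kind = ARTEFACT_KINDS[i % len(ARTEFACT_KINDS)]
            eps.append(inject_artefact(gen_clean_epoch(spec, r), kind, r))
            y.append(1)
        return eps, np.array(y)

    tr_e, tr_y = make(1, 40, 40)
    te_e, te_y = make(2, 20, 20)
    return {
        "train_epochs": tr_e,
        "train_truth": tr_y,
        "test_epochs": te_e,
        "test_truth": te_y,
        "X_train": extract_table(tr_e),
        "X_test": extract_table(te_e),
    }


@pytest.fixture(scope="session")
def trained_model(labelled_set):
    from epochsift.classifier import ForestConfig, train

    matrix = simulate_raters(
        labelled_set["train_truth"], DEFAULT_PANEL, np.random.default_rng(3)
    )
    cons = majority_vote(matrix)
    return train(labelled_set["X_train"], cons, ForestConfig(seed=0))
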