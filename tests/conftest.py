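import pytest

from abhumanize.ab_sequence import Chain
from abhumanize.humanness_classifier import (
    calibrate_threshold,
    split_dataset,
    train_model,
)
from abhumanize.repertoire_sim import SimConfig, make_default_germlines, simulate_repertoire


@pytest.fixture(scope="session")
def germlines():
    return make_default_germlines()


@pytest.fixture(scope="session")
def heavy_repertoire():
    return simulate_repertoire(SimConfig(n_per_class=300, chain=Chain.HEAVY, seed=11))


@pytest.fixture(scope="session")
def heavy_split(heavy_repertoire):
    labels = [1 if s.species == "human" else 0 for s in heavy_repertoire]
    return split_dataset(heavy_repertoire, labels, seed=11)


def _train_calibrated(split, v_gene, n_estimators=40, seed=11):
    pos = [s for s, l in zip(split.train, split.train_labels) if l == 1 and s.v_gene == v_gene]
    neg = [s for s, l in zip(split.train, split.train_labels) if l == 0]
    model = train_model(pos, neg, n_estimators=n_estimators, seed=seed)
    calibrate_threshold(model, split.validation, split.validation_labels)
    return model


@pytest.fixture(scope="session")
def v1_model(heavy_split):
    return _train_calibrated(heavy_split, "V1")


@pytest.fixture(scope="session")
def v3_model(heavy_split):
    return _train_calibrated(heavy_split, "V3")


@pytest.fixture(scope="session")
def kappa_repertoire():
    return simulate_repertoire(SimConfig(n_per_class=150, chain=Chain.KAPPA, seed=12))


@pytest.fixture(scope="session")
def lambda_repertoire():
    return simulate_repertoire(SimConfig(n_per_class=150, chain=Chain.LAMBDA, seed=13))
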