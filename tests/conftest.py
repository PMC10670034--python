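"""Shared fixtures: a small generated dataset and a classifier trained on it.

Both are session-scoped — the trained model backs every test that needs a
real predictor (explanation focus, feature separation, patch-size trade-off).
"""

import numpy as np
import pytest

from xwclust import (ClassifierHandle, DatasetManifest, TrainConfig,
                     build_dataset, train_classifier)


@pytest.fixture(scope="session")
def dataset_small(tmp_path_factory) -> DatasetManifest:
    """160-image two-subtype dataset (yellow rectangle vs blue ellipse)."""
    root = tmp_path_factory.mktemp("ds_small")
    return build_dataset(root, n_total=160, seed=0, stratified=True)


@pytest.fixture(scope="session")
def trained_model(dataset_small) -> ClassifierHandle:
    """Small CNN trained to separate healthy from pathological."""
    return train_classifier(dataset_small, config=TrainConfig(seed=0))


@pytest.fixture(scope="session")
def pathological_test_rows(dataset_small):
    rows = dataset_small.split("test")
    return rows[rows["label"] == "pathological"].reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
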