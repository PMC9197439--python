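"""Shared fixtures: templates and a small synthetic patch corpus.

The patch corpus is generated once per session into a temp directory so
the training-based tests share the same study conditions: 200 training
and 100 test patches of 100 px (50 um at 0.5 mpp), balanced classes.
"""

import numpy as np
import pytest

from nar.synthetic import load_manifest, make_manifest
from nar.templates import (inception_v4_template, resnet50v2_template,
                           toy_cnn_template)


@pytest.fixture(scope="session")
def resnet240():
    return resnet50v2_template(240, 2)


@pytest.fixture(scope="session")
def inception240():
    return inception_v4_template(240, 2)


@pytest.fixture(scope="session")
def patch_corpus(tmp_path_factory):
    """(train_manifest, test_manifest) paths for the standard toy task."""
    root = tmp_path_factory.mktemp("patches")
    train = make_manifest(200, 0.5, 100, root / "train", seed=11)
    test = make_manifest(100, 0.5, 100, root / "test", seed=99)
    return train, test


@pytest.fixture(scope="session")
def toy_run(patch_corpus):
    """A trained toy model plus its held-out scores and labels."""
    from nar.runtime import TrainConfig, materialize, train

    train_m, test_m = patch_corpus
    side = 48
    xtr, ytr = load_manifest(train_m, side)
    xte, yte = load_manifest(test_m, side)
    model = materialize(toy_cnn_template(side), seed=0)
    model, history = train(model, (xtr, ytr), TrainConfig(epochs=5, seed=0))
    scores = model.predict_proba(xte)[:, 1]
    return {"model": model, "history": history, "side": side,
            "scores": np.asarray(scores), "labels": yte}
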