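import numpy as np
import pytest

from interviewsim.avatar import AvatarProfile, build_scenario_pack
from interviewsim.classifier import BoosterConfig, tune_and_train
from interviewsim.synthcorpus import (
    balanced_spec,
    default_rule_config,
    generate_corpus,
)


@pytest.fixture(scope="session")
def rules():
    return default_rule_config()


@pytest.fixture(scope="session")
def small_corpus():
    """A balanced 30-per-class corpus: quick to train on, still separable."""
    df = generate_corpus(balanced_spec(per_class=30, seed=11))
    return df["text"].tolist(), df["label"].tolist()


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A fast, CV-free model used by rule-layer and session tests."""
    texts, labels = small_corpus
    cfg = BoosterConfig(
        n_estimators=60, min_child_weight=2, learning_rate=0.3, random_seed=5
    )
    return tune_and_train(
        texts, labels, booster_cfg=cfg, seed=5, cv=False, rebalance=False
    )


@pytest.fixture()
def pack4():
    """A fresh 4-year-old abused avatar scenario pack."""
    profile = AvatarProfile("avatar_t4", age=4, gender="girl", abused=True)
    return build_scenario_pack(profile, seed=2)


@pytest.fixture()
def pack6():
    """A fresh 6-year-old non-abused avatar scenario pack."""
    profile = AvatarProfile("avatar_t6", age=6, gender="boy", abused=False)
    return build_scenario_pack(profile, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
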