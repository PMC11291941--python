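import logging

import pytest

from reserveml import features, proxy, rri, synthetic

logging.getLogger("reserveml").setLevel(logging.ERROR)

FAST_HYPER = dict(
    max_depth=3,
    learning_rate=0.08,
    n_estimators=300,
    subsample=0.9,
    colsample_bytree=0.9,
    reg_lambda=1.0,
)


@pytest.fixture(scope="session")
def building_cohort():
    """Default model-building cohort at study scale (n=1665)."""
    cfg = synthetic.GenerativeConfig(n_participants=1665, seed=20250901)
    cohort, latents = synthetic.simulate_model_building_cohort(cfg)
    return cfg, cohort, latents


@pytest.fixture(scope="session")
def criterion_scores(building_cohort):
    _, cohort, _ = building_cohort
    params = rri.fit_rri(cohort)
    scores = rri.score_rri(params, cohort)
    return params, scores


@pytest.fixture(scope="session")
def trained_full_proxy(building_cohort, criterion_scores):
    """A Full-tier surrogate trained on 75% of the session cohort."""
    _, cohort, _ = building_cohort
    _, scores = criterion_scores
    tier = features.tier_spec("full")
    train_ids, test_ids = proxy.split_train_test(cohort, proxy.SplitSpec(0.75, 7))
    X = features.assemble_feature_frame(cohort, tier)
    trained = proxy.fit_final(
        X.loc[train_ids], scores.rri.loc[train_ids].to_numpy(), tier, FAST_HYPER, seed=0
    )
    return trained, X, train_ids, test_ids
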