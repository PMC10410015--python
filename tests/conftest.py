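import numpy as np
import pytest

import physioage as pa


@pytest.fixture(scope="session")
def linear_panel():
    """Ten linear effects with amplitudes 1..10: the workhorse cohort."""
    effects = tuple(
        pa.EffectSpec(f"v{i:02d}", "linear", amplitude=float(a), noise_sd=0.3,
                      baseline_mean=10.0, baseline_sd=1.0)
        for i, a in enumerate(range(1, 11))
    )
    return effects


@pytest.fixture(scope="session")
def small_cohort(linear_panel):
    return pa.generate_cohort(pa.GeneratorConfig(n_individuals=2500, effects=linear_panel, seed=42))


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return pa.fit_age_model(
        small_cohort.cohort, {"n_estimators": 120}, objective="age_normalized", seed=0,
        evaluate_train=False,
    )


@pytest.fixture(scope="session")
def global_expl(small_model, small_cohort):
    return pa.explain_global(small_model, small_cohort.cohort, seed=0)


@pytest.fixture(scope="session")
def ctx_expl(small_model, small_cohort):
    return pa.explain_contextualized(small_model, small_cohort.cohort, min_group_size=50, seed=0)
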