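import numpy as np
import pytest

import mimecorrect as mc
from mimecorrect import synthetic


@pytest.fixture(scope="session")
def small_survey():
    """Reduced survey with defaults: n = 1,500, ~15% validation subsample."""
    return mc.generate_survey(
        mc.TruthParams(n_respondents=1500),
        design=mc.DesignParams(validation_fraction=0.15),
        seed=20240917,
    )


@pytest.fixture(scope="session")
def midsize_survey():
    """n = 10,000 survey for checks that need tight Monte-Carlo error."""
    return mc.generate_survey(mc.TruthParams(n_respondents=10000), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def weighted_params():
    """Superpopulation weighted prevalences implied by the default generator,
    from one large truth-only draw (the estimand of the weighted estimator)."""
    big = synthetic.generate_truth(mc.TruthParams(n_respondents=200000), seed=424242)
    w = synthetic.default_weight_model(big)
    return {
        name: float(np.sum(w * big[f"true_{name}"]) / np.sum(w))
        for name in ("overweight", "obesity", "hypertension", "hypercholesterolemia")
    }
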