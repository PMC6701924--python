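import numpy as np
import pytest

from smfretkin import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def wt_levels():
    return np.array([0.03, 0.61, 0.03])


@pytest.fixture(scope="session")
def wt_cohort(wt_levels):
    """100 WT-like E_FRET records (outlier-masked) with ground truth."""
    from smfretkin.preprocess import apply_outlier_policy

    rng = np.random.default_rng(20260)
    recs, truths = sd.simulate_efret_cohort(
        sd.wt_like_scheme(), wt_levels, 100, 0.10, rng
    )
    recs, _ = apply_outlier_policy(recs)
    assert len(recs) == len(truths)
    return recs, truths


@pytest.fixture(scope="session")
def wt_fit(wt_cohort):
    from smfretkin.ebhmm import eb_fit_population, wt_priors

    recs, _ = wt_cohort
    return eb_fit_population(recs, wt_priors(), n_restarts=3, seed=0)
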