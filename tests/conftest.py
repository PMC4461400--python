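import numpy as np
import pytest

import burstkit as bk


@pytest.fixture(scope="session")
def default_cohort() -> bk.Cohort:
    """The calibrated default cohort: 200 clones x 600 cells, seed 1."""
    return bk.generate_cohort(bk.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_moments(default_cohort):
    means = np.array([c.counts.mean() for c in default_cohort.counts])
    variances = np.array([c.counts.var(ddof=1) for c in default_cohort.counts])
    return {"mean": means, "variance": variances, "cv": np.sqrt(variances) / means}


@pytest.fixture(scope="session")
def fitted_cohort(default_cohort) -> bk.CohortFitResult:
    """MLE fits of every clone in the default cohort (shared: ~3 min)."""
    return bk.fit_cohort(
        default_cohort.counts,
        delta=1.0,
        lam=default_cohort.config.lam_fixed,
        seed=7,
        truth=default_cohort.truth,
    )
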