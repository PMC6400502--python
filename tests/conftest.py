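import numpy as np
import pandas as pd
import pytest

import cilp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Cross-sectional two-group cohort with planted loss-of-correlation pairs."""
    spec = cilp.CohortSpec(n_per_group=200, n_traits=24, n_planted_pairs=6)
    return cilp.simulate_cohort(spec, 101)


@pytest.fixture(scope="session")
def qtl_cohort():
    """Cohort with genotypes and planted correlation QTLs."""
    spec = cilp.CohortSpec(
        n_per_group=1000, n_traits=16, n_planted_pairs=4, n_snps=30, n_planted_qtls=4
    )
    return cilp.simulate_cohort(spec, 202)


@pytest.fixture
def trait_frame(rng):
    n = 60
    data = pd.DataFrame(
        rng.standard_normal((n, 5)),
        index=[f"s{i:03d}" for i in range(n)],
        columns=list("abcde"),
    )
    return cilp.TraitMatrix(data)


def naive_ols_pvalue(y, X):
    """Textbook OLS Wald-t p-value for the last column of X (test oracle)."""
    from scipy import stats

    XtX_i = np.linalg.inv(X.T @ X)
    beta = XtX_i @ (X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    se = np.sqrt(resid @ resid / df * XtX_i[-1, -1])
    return float(beta[-1]), float(2 * stats.t.sf(abs(beta[-1] / se), df))
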