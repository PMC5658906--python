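import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from edcmix.catalog import load_catalog  # noqa: E402
from edcmix.cohort import CohortConfig, simulate_covariates, simulate_exposures  # noqa: E402
from edcmix.preprocess import assemble_design  # noqa: E402


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A 250-participant cohort with assembled (outcome-free) design."""
    cfg = CohortConfig(n_participants=250, seed=7)
    cov = simulate_covariates(cfg)
    panel = simulate_exposures(cfg, catalog)
    matrix = assemble_design(panel, cov, catalog)
    return {"config": cfg, "covariates": cov, "panel": panel, "matrix": matrix}


def make_toy_matrix(n=200, p_hier=10, n_class=2, seed=0, rho=0.3,
                    beta=None, resid_sd=1.0, n_cov=2):
    """Small synthetic AnalysisMatrix for sampler/oracle tests.

    Exposure columns are exactly standardized; classes are assigned
    round-robin from the canonical hierarchical class labels.
    """
    from edcmix.catalog import HIERARCHICAL_CLASSES
    from edcmix.preprocess import AnalysisMatrix, standardize

    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    raw = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, p_hier))
    X = pd.DataFrame(
        {f"chem_{j}": standardize(raw[:, j], name=f"chem_{j}")[0]
         for j in range(p_hier)}
    )
    classes = [HIERARCHICAL_CLASSES[j % n_class] for j in range(p_hier)]
    class_map = dict(zip(X.columns, classes))
    C = pd.DataFrame(
        {f"cov_{k}": rng.standard_normal(n) for k in range(n_cov)}
    )
    if beta is None:
        beta = rng.normal(0.0, 1.0, size=p_hier)
    y = X.to_numpy() @ beta + C.to_numpy() @ np.ones(n_cov) * 0.5
    y = y + rng.normal(0.0, resid_sd, size=n)
    return AnalysisMatrix(
        y=y,
        X=X,
        C=C,
        B=None,
        sd_log10=pd.Series(0.5, index=X.columns),
        class_map=class_map,
    ), np.asarray(beta)
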