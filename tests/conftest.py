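import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# derandomized hypothesis profile so the suite is reproducible everywhere
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_harmonized(ratios, weights=None, b_x=None, se_x=None, ids=None):
    """Build a harmonized-instrument table directly from Wald ratios/weights.

    With b_x fixed at 1, the outcome beta equals the ratio and the outcome se
    equals the Wald se, so arbitrary (ratio, weight) configurations can be
    constructed exactly.
    """
    ratios = np.asarray(ratios, float)
    k = len(ratios)
    weights = np.ones(k) if weights is None else np.asarray(weights, float)
    b_x = np.ones(k) if b_x is None else np.asarray(b_x, float)
    se_x = np.full(k, 0.01) if se_x is None else np.asarray(se_x, float)
    wald_se = 1.0 / np.sqrt(weights)
    b_y = ratios * b_x
    se_y = wald_se * np.abs(b_x)
    return pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"rs{i}" for i in range(k)],
            "b_x": b_x,
            "se_x": se_x,
            "p_x": 1e-8,
            "b_y": b_y,
            "se_y": se_y,
            "p_y": 0.5,
            "eaf_x": 0.3,
            "eaf_y": 0.3,
            "wald_ratio": ratios,
            "wald_se": wald_se,
            "weight": weights,
            "f_stat": (b_x / se_x) ** 2,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cohort():
    """Deterministic 60-record cohort with a positive dose effect."""
    from gxekit.simulate import CohortSimConfig, gen_cohort

    return gen_cohort(
        CohortSimConfig(n=60, beta_dose=5e-4, baseline_hazard=0.08, seed=42)
    )
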