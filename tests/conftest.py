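import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from osteophen import cohortsim  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> cohortsim.SimulationConfig:
    """Compact study: full 8 x 2 x 9 design but a 6-trait panel."""
    traits = tuple(
        t for t in cohortsim.default_trait_panel()
        if t.name in {"BMC", "Ct.Ar", "TMD", "Fu", "PYD", "Su"}
    )
    return cohortsim.SimulationConfig(traits=traits, n_do_per_sex=10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    table, effects = cohortsim.simulate_founder_cohort(small_config)
    return table, effects


def brute_force_anova_ss(
    strain: np.ndarray, sex: np.ndarray, y: np.ndarray, model: str = "additive"
) -> dict:
    """Independent two-factor ANOVA oracle via explicit projections.

    Builds sum-to-zero-coded design matrices and computes each factor's
    Type III sum of squares as the residual-sum-of-squares increase when that
    factor's columns are dropped from the full model.
    """
    strain = np.asarray(strain)
    sex = np.asarray(sex)
    y = np.asarray(y, dtype=float)
    s_levels = sorted(pd.unique(strain))
    x_levels = sorted(pd.unique(sex))

    def sum_code(values, levels):
        k = len(levels)
        cols = np.zeros((len(values), k - 1))
        for j, lev in enumerate(levels[:-1]):
            cols[values == lev, j] = 1.0
        cols[values == levels[-1], :] = -1.0
        return cols

    a = sum_code(strain, s_levels)
    b = sum_code(sex, x_levels)
    ab = np.concatenate(
        [a[:, i:i + 1] * b[:, j:j + 1] for i in range(a.shape[1]) for j in range(b.shape[1])],
        axis=1,
    )
    one = np.ones((len(y), 1))

    def rss(*blocks):
        x = np.concatenate([one, *blocks], axis=1)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    if model == "additive":
        full = rss(a, b)
        return {
            "ss_strain": rss(b) - full,
            "ss_sex": rss(a) - full,
            "ss_res": full,
        }
    full = rss(a, b, ab)
    return {
        "ss_strain": rss(b, ab) - full,
        "ss_sex": rss(a, ab) - full,
        "ss_interaction": rss(a, b) - full,
        "ss_res": full,
    }
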