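"""Shared fixtures: small synthetic panels and the replicated
confounded-pipeline experiment used by several recovery tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

import healthdea as hd

#: Strong-environmental-confounding study condition for pipeline-recovery
#: experiments: a larger province (42 cities) so the slack regressions are
#: well identified, dominant managerial variance, weak noise.
CONFOUNDED = dict(
    sigma_u=0.4, sigma_v=0.05,
    env_effect=(-0.45, -0.27, -0.09, -0.18, -0.09, -0.18),
    u_env_scale=0.0,
    n_cities=42, region_sizes=(18, 8, 6, 10),
)


@pytest.fixture(scope="session")
def default_panel():
    """One year of the default synthetic province (21 cities)."""
    cfg = hd.SimConfig(seed=11, years=(2020,))
    return hd.simulate_panel(cfg)


def _r_squared(y, Z):
    Zc = np.column_stack([np.ones(len(y)), Z])
    b, *_ = np.linalg.lstsq(Zc, y, rcond=None)
    resid = y - Zc @ b
    tss = float((y - y.mean()) @ (y - y.mean()))
    return 1.0 - float(resid @ resid) / tss


@pytest.fixture(scope="session")
def confounded_replicates():
    """25 seeded replicates of the three-stage pipeline under strong
    environmental confounding, with rank correlations against true
    efficiency and the environment R-squared of the scores at each stage."""
    out = []
    for seed in range(25):
        cfg = hd.SimConfig(seed=seed, years=(2020,), **CONFOUNDED)
        panel, truth = hd.simulate_panel(cfg)
        res = hd.run_three_stage(panel, 2020)
        te = truth.true_efficiency(2020)
        rows = panel.year_slice(2020)
        Z = np.array([list(r.env) for r in rows])
        Zs = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        out.append({
            "corr_stage1": spearmanr(res.stage1_scores, te).statistic,
            "corr_stage3": spearmanr(res.stage3_scores, te).statistic,
            "r2_stage1": _r_squared(res.stage1_scores, Zs),
            "r2_stage3": _r_squared(res.stage3_scores, Zs),
            "adjusted_ge_raw": bool(
                np.all(res.adjusted_inputs >= res.raw_inputs - 1e-9)),
        })
    return out


def random_dea_instance(rng, n_max=6):
    """A small random DEA instance with strictly positive inputs."""
    n = rng.integers(2, n_max + 1)
    m = rng.integers(1, 4)
    s = rng.integers(1, 3)
    X = rng.uniform(0.5, 10.0, size=(m, n))
    Y = rng.uniform(0.5, 10.0, size=(s, n))
    return hd.DEAInstance(X=X, Y=Y)
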