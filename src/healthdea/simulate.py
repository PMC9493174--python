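"""Synthetic city panels with known ground truth.

The study population this generator emulates is a province of 21
prefecture-level cities in four development regions (9/4/3/5 cities), one
dominant high-development region and three lagging ones, observed over
several years. Each city's public-hospital system is a production unit:

* outputs (visits, discharges, examinations, medical revenue) scale with
  population and with the city's development level;
* minimal ("frontier") inputs follow a constant-returns Cobb-Douglas
  inverse of the outputs;
* observed inputs exceed the frontier by three multiplicative factors:
  an environment-driven slack term (cities in worse environments waste
  more), half-normal managerial inefficiency ``u`` whose scale can also
  shift with the environment, and symmetric log-normal noise ``v``;
* the six environmental variables (per-capita GDP, urbanization, density,
  education, insurance coverage, government health spending share) are
  correlated with region identity, mimicking a development gap.

``inequality_level`` rescales every log-deviation of the four resource
indicators (hospitals, beds, technicians, subsidies) from exact
population-proportionality; at 0 the per-capita allocation is identical
everywhere and every population-basis Gini is exactly zero.

The random stream is split deterministically by (variable, city, year),
so adding a new variable leaves earlier draws untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel import ENV_COLUMNS, CityYearRecord, Panel
from .sfa import SlackRegressionData

__all__ = ["SimConfig", "GroundTruth", "simulate_panel",
           "simulate_slack_dataset"]

_REGION_NAMES = ("pearl_river_delta", "eastern", "western", "mountainous")
_REGION_LOGDEV = (0.55, -0.15, -0.20, -0.45)

# baseline city used to calibrate frontier constants (pop 5e6, delta = 0)
_BASE_POP = 5.0e6
_BASE_OUTPUT_RATES = (2.0, 0.11, 0.30, 1.6e-6)   # per person
_BASE_INPUT_LEVELS = (45.0, 16000.0, 20000.0)    # hospitals, beds, technicians
_BASE_SUBSIDY_RATE = 2.0e-4                      # million per person


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic province.

    ``frontier_coefficients`` is a 3x4 row-stochastic matrix of output
    elasticities per input (rows sum to 1, giving constant returns);
    ``env_effect`` links the standardized environmental variables to
    log-input slack (negative entries: a better environment wastes less);
    ``u_env_scale`` lets the half-normal inefficiency scale itself drift
    with the environment index; ``inequality_level`` is the dispersion
    multiplier for per-capita resources (1 = as calibrated, 0 = perfectly
    equal).
    """

    seed: int = 0
    n_cities: int = 21
    region_sizes: tuple = (9, 4, 3, 5)
    years: tuple = (2016, 2017, 2018, 2019, 2020)
    frontier_coefficients: tuple = (
        (0.30, 0.30, 0.20, 0.20),
        (0.25, 0.45, 0.10, 0.20),
        (0.40, 0.30, 0.15, 0.15),
    )
    sigma_u: float = 0.25
    sigma_v: float = 0.10
    env_effect: tuple = (-0.05, -0.03, -0.01, -0.02, -0.01, -0.02)
    u_env_scale: float = 0.20
    inequality_level: float = 1.0

    def __post_init__(self):
        if sum(self.region_sizes) != self.n_cities:
            raise ValueError("region_sizes must sum to n_cities")
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be > 0 (SFA likelihood is "
                             "degenerate at sigma_v = 0)")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        A = np.asarray(self.frontier_coefficients, dtype=float)
        if A.shape != (3, 4) or not np.allclose(A.sum(axis=1), 1.0):
            raise ValueError("frontier_coefficients must be 3x4 with rows "
                             "summing to 1 (constant returns)")
        if len(self.env_effect) != len(ENV_COLUMNS):
            raise ValueError(f"env_effect must have {len(ENV_COLUMNS)} entries")


@dataclass(frozen=True)
class GroundTruth:
    """True latent quantities behind a simulated panel.

    ``u``, ``v`` and ``frontier_inputs`` map year -> (3, n_cities) arrays
    aligned with the panel's city order; ``env_link`` maps year -> the
    city-level environmental slack index actually applied.
    """

    u: dict
    v: dict
    frontier_inputs: dict
    env_link: dict
    cities: tuple
    beta_true: tuple
    sigma_u: float
    sigma_v: float

    @property
    def gamma_true(self) -> float:
        if self.sigma_u == 0 and self.sigma_v == 0:
            return 0.0
        return self.sigma_u ** 2 / (self.sigma_u ** 2 + self.sigma_v ** 2)

    def true_efficiency(self, year: int) -> np.ndarray:
        """City-level true technical efficiency exp(-mean_i u_i)."""
        return np.exp(-self.u[year].mean(axis=0))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), *map(int, key))))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _frontier_constants(alpha: np.ndarray) -> np.ndarray:
    """Calibrate A_i so the baseline city hits realistic input levels."""
    y0 = np.array(_BASE_OUTPUT_RATES) * _BASE_POP
    return np.array(_BASE_INPUT_LEVELS) / np.exp(alpha @ np.log(y0))


def simulate_panel(config: SimConfig) -> tuple[Panel, GroundTruth]:
    """Draw one balanced synthetic panel plus its ground truth."""
    cfg = config
    n = cfg.n_cities
    seed = cfg.seed
    alpha = np.asarray(cfg.frontier_coefficients, dtype=float)
    A = _frontier_constants(alpha)
    beta = np.asarray(cfg.env_effect, dtype=float)
    level = float(cfg.inequality_level)

    regions = []
    for size, name in zip(cfg.region_sizes,
                          list(_REGION_NAMES) + [f"region_{i}" for i in range(4, 99)]):
        regions += [name] * size
    logdev_by_region = dict(zip(_REGION_NAMES, _REGION_LOGDEV))
    cities = tuple(f"C{i + 1:02d}" for i in range(n))

    # time-invariant city characteristics
    delta = np.array([
        logdev_by_region.get(regions[c], 0.0) + 0.25 * _rng(seed, 1, c).standard_normal()
        for c in range(n)
    ])
    pop0 = np.array([
        math.exp(_rng(seed, 2, c).normal(
            math.log(5.5e6 if regions[c] == _REGION_NAMES[0] else 4.8e6), 0.08))
        for c in range(n)
    ])
    area = np.array([
        math.exp(_rng(seed, 3, c).normal(math.log(
            {_REGION_NAMES[0]: 6000.0, _REGION_NAMES[1]: 5000.0,
             _REGION_NAMES[2]: 7500.0, _REGION_NAMES[3]: 12000.0}.get(regions[c], 8000.0)), 0.30))
        for c in range(n)
    ])

    records = []
    gt_u, gt_v, gt_front, gt_link = {}, {}, {}, {}
    for t, year in enumerate(cfg.years):
        pop = pop0 * 1.01 ** t
        noise = {v: np.array([_rng(seed, 10 + v, c, year).standard_normal()
                              for c in range(n)]) for v in range(12)}
        gdp_pc = 4.5e4 * np.exp(delta + 0.12 * noise[0]) * 1.06 ** t
        urb = _sigmoid(0.2 + 1.5 * delta + 0.3 * noise[1])
        dens = pop / area
        hs = np.clip(0.13 + 0.05 * delta + 0.015 * noise[2], 0.01, 0.6)
        ins = np.clip(0.93 + 0.025 * noise[3], 0.5, 1.0)
        ghs = np.clip(0.08 - 0.02 * delta + 0.012 * noise[4], 0.01, 0.3)
        Zenv = np.column_stack([gdp_pc, urb, dens, hs, ins, ghs])

        # standardized environment -> slack index (worse environment, more slack)
        Zstd = (Zenv - Zenv.mean(axis=0)) / np.where(Zenv.std(axis=0) > 0,
                                                     Zenv.std(axis=0), 1.0)
        link = Zstd @ beta
        link_std = (link - link.mean()) / (link.std() if link.std() > 0 else 1.0)

        # outputs: per-capita rates shifted by development
        visits = _BASE_OUTPUT_RATES[0] * pop * np.exp(0.15 * delta + 0.05 * noise[5]) * 1.02 ** t
        discharges = _BASE_OUTPUT_RATES[1] * pop * np.exp(0.15 * delta + 0.05 * noise[6])
        exams = _BASE_OUTPUT_RATES[2] * pop * np.exp(0.20 * delta + 0.06 * noise[7])
        revenue = _BASE_OUTPUT_RATES[3] * pop * np.exp(0.25 * delta + 0.06 * noise[8]) * 1.04 ** t
        Y = np.vstack([visits, discharges, exams, revenue])

        # frontier inputs and the three excess factors; managerial
        # inefficiency u is a city trait shared by all three inputs
        log_xstar = np.log(A)[:, None] + alpha @ np.log(Y)
        sigma_u_city = cfg.sigma_u * np.exp(cfg.u_env_scale * link_std)
        u_city = np.abs(np.array([_rng(seed, 30, c, year).standard_normal()
                                  for c in range(n)])) * sigma_u_city
        u_raw = np.tile(u_city, (3, 1))
        v_raw = np.vstack([
            np.array([_rng(seed, 40 + i, c, year).standard_normal()
                      for c in range(n)]) * cfg.sigma_v
            for i in range(3)
        ])
        log_x = log_xstar + link[None, :] + u_raw + v_raw

        # inequality_level rescales the whole log-deviation of each
        # resource from exact population-proportionality
        percap = np.array(_BASE_INPUT_LEVELS) / _BASE_POP
        log_prop = np.log(percap)[:, None] + np.log(pop)[None, :]
        log_x_final = log_prop + level * (log_x - log_prop)
        X = np.exp(log_x_final)

        u_applied = level * u_raw
        v_applied = level * v_raw
        gt_u[year] = u_applied
        gt_v[year] = v_applied
        gt_front[year] = np.exp(log_x_final - u_applied - v_applied)
        gt_link[year] = level * link

        subsidies = (_BASE_SUBSIDY_RATE * pop
                     * np.exp(level * (1.3 * delta + 0.25 * noise[9]))
                     * 1.2 ** t)

        for c in range(n):
            records.append(CityYearRecord(
                city_id=cities[c], region=regions[c], year=int(year),
                population=float(pop[c]), area=float(area[c]),
                hospitals=float(X[0, c]), beds=float(X[1, c]),
                technicians=float(X[2, c]), subsidies=float(subsidies[c]),
                visits=float(Y[0, c]), discharges=float(Y[1, c]),
                examinations=float(Y[2, c]), revenue=float(Y[3, c]),
                env=tuple(float(x) for x in Zenv[c]),
            ))

    panel = Panel(records=tuple(records),
                  region_partition=dict(zip(cities, regions)))
    truth = GroundTruth(
        u=gt_u, v=gt_v, frontier_inputs=gt_front, env_link=gt_link,
        cities=cities, beta_true=tuple(beta.tolist()),
        sigma_u=cfg.sigma_u * level, sigma_v=cfg.sigma_v * level,
    )
    return panel, truth


def simulate_slack_dataset(n: int, beta_true, sigma_u: float, sigma_v: float,
                           seed: int):
    """Draw one slack-regression dataset ``S = Z beta + v + u``.

    ``Z`` is an intercept column followed by standardized continuous
    covariates (one per remaining entry of ``beta_true``);
    ``v ~ N(0, sigma_v^2)`` and ``u = sigma_u |N(0, 1)|`` (half-normal).
    Returns ``(SlackRegressionData, ground_truth_dict)``.
    """
    beta_true = np.asarray(beta_true, dtype=float)
    k = beta_true.size
    if n < 30:
        raise ValueError("need n >= 30 observations")
    if n < k + 2:
        raise ValueError("model unidentifiable: n < number of covariates + 2")
    if sigma_v <= 0:
        raise ValueError("sigma_v must be > 0")
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    rng = _rng(seed, 99)
    Zc = rng.standard_normal((n, k - 1)) if k > 1 else np.empty((n, 0))
    if k > 1:  # standardize the continuous covariates
        Zc = (Zc - Zc.mean(axis=0)) / Zc.std(axis=0)
    Z = np.column_stack([np.ones(n), Zc])
    v = rng.normal(0.0, sigma_v, size=n)
    u = sigma_u * np.abs(rng.standard_normal(n))
    S = Z @ beta_true + v + u
    data = SlackRegressionData(S=S, Z=Z, input_label="simulated")
    s2 = sigma_u ** 2 + sigma_v ** 2
    truth = {
        "beta_true": beta_true, "u": u, "v": v,
        "sigma_u": float(sigma_u), "sigma_v": float(sigma_v),
        "gamma_true": float(sigma_u ** 2 / s2) if s2 > 0 else 0.0,
    }
    return data, truth
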