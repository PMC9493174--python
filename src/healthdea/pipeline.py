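"""Orchestration of the improved three-stage DEA and the equity-efficiency
coordination analysis.

Per year: stage 1 solves the input-oriented CCR model under constant
returns to obtain each input's total slack and the composite SBM /
super-efficiency SBM score on raw data; stage 2 regresses each input's
slacks on the six environmental variables with a half-normal stochastic
frontier and raises every city's inputs to the worst observed environment
and worst observed luck; stage 3 re-solves the composite SBM /
super-efficiency scores on the adjusted inputs with unchanged outputs.

Scores are then aggregated to provincial and regional arithmetic means,
efficient cities counted (score >= 1), and cities placed in the
equity-efficiency quadrant matrix around the all-city means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dea, sfa
from .dea import DEAInstance, EFFICIENCY_TOL
from .panel import ENV_COLUMNS, Panel

__all__ = ["ThreeStageResult", "ScoreSummary", "QuadrantAssignment",
           "run_three_stage", "summarize_scores", "region_period_means",
           "coordination_matrix", "INPUT_FIELDS", "OUTPUT_FIELDS"]

INPUT_FIELDS = ("hospitals", "beds", "technicians")
OUTPUT_FIELDS = ("visits", "discharges", "examinations", "revenue")

#: slacks with coefficient of variation below this are treated as "all
#: DMUs efficient in that input": no frontier regression is attempted.
_DEGENERATE_SLACK_TOL = 1e-9


@dataclass(frozen=True)
class ThreeStageResult:
    """All artifacts of one per-year three-stage run."""

    year: int
    cities: tuple
    regions: tuple
    stage1_scores: np.ndarray
    stage3_scores: np.ndarray
    slacks: np.ndarray            # (3, n) total input slacks from stage 1
    adjusted_inputs: np.ndarray   # (3, n)
    raw_inputs: np.ndarray
    outputs: np.ndarray
    sfa_fits: tuple               # per input: SFAFit or None
    lr_tests: tuple               # per input: LRTestResult or None
    audit: tuple = field(default=())

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "city_id": self.cities, "region": self.regions, "year": self.year,
            "stage1_score": self.stage1_scores,
            "stage3_score": self.stage3_scores,
            "efficient": self.stage3_scores >= 1.0 - EFFICIENCY_TOL,
        })


@dataclass(frozen=True)
class ScoreSummary:
    provincial_mean: float
    region_means: dict
    efficient_count: int
    efficient_share_pct: float
    n: int


@dataclass(frozen=True)
class QuadrantAssignment:
    """A city's position in the equity-efficiency two-dimensional matrix.

    Quadrant 1: x >= mean and y >= mean (adequate resources, efficient);
    2: x < mean, y >= mean; 3: both below; 4: x >= mean, y < mean.
    Boundary values go to the "high" side, matching the right-inclusive
    ``score >= 1`` efficiency convention.
    """

    city_id: str
    x: float
    y: float
    quadrant: int


def _instance_for_year(panel: Panel, year: int):
    rows = panel.year_slice(year)
    X = np.array([[getattr(r, f) for r in rows] for f in INPUT_FIELDS])
    Y = np.array([[getattr(r, f) for r in rows] for f in OUTPUT_FIELDS])
    Z = np.array([list(r.env) for r in rows])
    cities = tuple(r.city_id for r in rows)
    regions = tuple(r.region for r in rows)
    return X, Y, Z, cities, regions


def _composite_scores(instance: DEAInstance) -> np.ndarray:
    return np.array([dea.efficiency_score(instance, j).delta
                     for j in range(instance.n_dmus)])


def run_three_stage(panel: Panel, year: int) -> ThreeStageResult:
    """Run stages 1-3 for one year of a validated panel."""
    X, Y, Zenv, cities, regions = _instance_for_year(panel, year)
    inst1 = DEAInstance(X=X, Y=Y, labels=cities)
    inst1.validate_discriminative_power()

    # stage 1: CCR total slacks + composite SBM/super-SBM scores
    slacks = np.array([dea.ccr_input(inst1, j).total_slacks
                       for j in range(inst1.n_dmus)]).T  # (m, n)
    stage1 = _composite_scores(inst1)

    # stage 2: per-input frontier regression of slack on environment
    Zstd = (Zenv - Zenv.mean(axis=0)) / np.where(Zenv.std(axis=0) > 0,
                                                 Zenv.std(axis=0), 1.0)
    Z = np.column_stack([np.ones(len(cities)), Zstd])
    fits, jlms_list, datasets, lr_tests, audit = [], [], [], [], []
    for i, label in enumerate(INPUT_FIELDS):
        S = slacks[i]
        data = sfa.SlackRegressionData(S=S, Z=Z, input_label=label)
        if S.max() <= _DEGENERATE_SLACK_TOL * X[i].mean() or S.std() == 0:
            fits.append(None)
            jlms_list.append(None)
            datasets.append(data)
            lr_tests.append(None)
            audit.append(f"{label}: slacks degenerate, carried unadjusted")
            continue
        try:
            fit = sfa.fit_sfa_halfnormal(data)
        except Exception as exc:  # pipeline continues with input unadjusted
            fits.append(None)
            jlms_list.append(None)
            datasets.append(data)
            lr_tests.append(None)
            audit.append(f"{label}: SFA failed ({exc}), carried unadjusted")
            continue
        fits.append(fit)
        datasets.append(data)
        jlms_list.append(sfa.jlms_inefficiency(fit, data))
        lr_tests.append(sfa.lr_test_gamma(fit))
        audit.append(f"{label}: gamma={fit.gamma:.3f}, "
                     f"loglik={fit.loglik:.3f}, converged={fit.converged}")

    XA = sfa.adjust_inputs(X, fits, datasets, jlms_list)

    # stage 3: composite scores on adjusted inputs, outputs unchanged
    inst3 = DEAInstance(X=XA, Y=Y, labels=cities)
    stage3 = _composite_scores(inst3)

    return ThreeStageResult(
        year=year, cities=cities, regions=regions,
        stage1_scores=stage1, stage3_scores=stage3, slacks=slacks,
        adjusted_inputs=XA, raw_inputs=X, outputs=Y,
        sfa_fits=tuple(fits), lr_tests=tuple(lr_tests), audit=tuple(audit),
    )


def summarize_scores(cities, scores, regions, tol: float = EFFICIENCY_TOL) -> ScoreSummary:
    """Provincial/regional arithmetic means and efficient-DMU counts.

    ``regions`` maps city -> region (or is a sequence aligned with
    ``cities``). A city is efficient when its score is >= 1 - tol; the
    efficient share is in percent.
    """
    scores = np.asarray(scores, dtype=float)
    cities = list(cities)
    if len(cities) != scores.size or not cities:
        raise ValueError("cities and scores must align and be non-empty")
    if isinstance(regions, dict):
        region_of = [regions[c] for c in cities]
    else:
        region_of = list(regions)
        if len(region_of) != len(cities):
            raise ValueError("regions must align with cities")
    region_means = {}
    for g in dict.fromkeys(region_of):
        vals = scores[[r == g for r in region_of]]
        if vals.size == 0:
            raise ValueError(f"region {g!r} is empty")
        region_means[g] = float(vals.mean())
    count = int(np.sum(scores >= 1.0 - tol))
    return ScoreSummary(
        provincial_mean=float(scores.mean()),
        region_means=region_means,
        efficient_count=count,
        efficient_share_pct=100.0 * count / scores.size,
        n=scores.size,
    )


def region_period_means(score_table: pd.DataFrame) -> pd.Series:
    """Arithmetic mean score per region pooled over all years.

    Expects columns ``region`` and ``score`` (one row per city-year); the
    pooled mean equals the mean of the yearly region means for a balanced
    panel.
    """
    return score_table.groupby("region", sort=False)["score"].mean()


def coordination_matrix(cities, x, y) -> list:
    """Place cities in the four equity-efficiency quadrants.

    ``x`` is the resource endowment axis (HRDI of the comprehensive
    indicator, or per-thousand-person subsidies); ``y`` the stage-3
    efficiency score. Thresholds are the unweighted means over the
    supplied cities; boundary values count as "high".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cities = list(cities)
    if not (len(cities) == x.size == y.size) or len(cities) < 2:
        raise ValueError("need >= 2 cities with aligned x and y")
    x_bar, y_bar = x.mean(), y.mean()
    out = []
    for c, xi, yi in zip(cities, x, y):
        if xi >= x_bar:
            q = 1 if yi >= y_bar else 4
        else:
            q = 2 if yi >= y_bar else 3
        out.append(QuadrantAssignment(city_id=c, x=float(xi), y=float(yi),
                                      quadrant=q))
    return out
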