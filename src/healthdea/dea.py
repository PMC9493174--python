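"""Input-oriented DEA models under constant returns to scale.

Three linear programs, all solved with HiGHS via ``scipy.optimize.linprog``:

* ``ccr_input`` — the radial CCR model, two-phase (radial contraction
  ``theta`` followed by slack maximisation), yielding total input slacks
  ``S_i = x_io - (X lambda*)_i`` (radial plus non-radial reduction);
* ``sbm_input`` — the non-radial slack-based measure, whose score
  ``delta = (1/m) sum_i xbar_i / x_io`` averages the proportional input
  reductions and never exceeds the CCR ``theta``;
* ``super_sbm_input`` — the super-efficiency SBM, which excludes the
  evaluated DMU from the reference set so that efficient units obtain
  scores above 1 and can be ranked.

``efficiency_score`` composes the last two the way efficiency is reported
in practice: inefficient units keep their standard SBM score (< 1),
efficient units are re-scored with the super-efficiency model (>= 1).

The input orientation fixes the output bundle at the evaluated DMU's
observed outputs, which keeps even the super-efficiency objective linear:
no fractional (Charnes-Cooper) transformation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = ["DEAInstance", "CCRResult", "SBMScore",
           "ccr_input", "sbm_input", "super_sbm_input", "efficiency_score",
           "EFFICIENCY_TOL"]

#: Classification tolerance: a score >= 1 - EFFICIENCY_TOL counts as efficient.
EFFICIENCY_TOL = 1e-6


@dataclass(frozen=True)
class DEAInstance:
    """Inputs X (m x n) and outputs Y (s x n) over n decision-making units."""

    X: np.ndarray
    Y: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape[1] != Y.shape[1]:
            raise ValueError("X and Y must cover the same DMUs (columns)")
        if np.any(X <= 0):
            raise ValueError("all inputs must be strictly positive")
        if np.any(Y < 0):
            raise ValueError("outputs must be non-negative")
        if np.any(Y.sum(axis=0) <= 0):
            raise ValueError("every DMU needs at least one positive output")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(range(X.shape[1])))
        elif len(self.labels) != X.shape[1]:
            raise ValueError("labels must match the number of DMUs")

    @property
    def n_dmus(self) -> int:
        return self.X.shape[1]

    @property
    def n_inputs(self) -> int:
        return self.X.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[0]

    def validate_discriminative_power(self) -> None:
        """DEA rule of thumb: n >= 2 (m + s) for discriminative power."""
        need = 2 * (self.n_inputs + self.n_outputs)
        if self.n_dmus < need:
            raise ValueError(
                f"{self.n_dmus} DMUs < 2(m+s) = {need}: insufficient "
                "discriminative power for DEA"
            )


@dataclass(frozen=True)
class CCRResult:
    theta: float
    lam: np.ndarray
    input_targets: np.ndarray
    total_slacks: np.ndarray


@dataclass(frozen=True)
class SBMScore:
    delta: float
    efficient: bool
    mode: str
    lam: np.ndarray | None = None


def _solve(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None, label=""):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success and res.status != 2:  # 2 = infeasible, handled by caller
        raise RuntimeError(f"LP solver failed for DMU {label!r}: {res.message}")
    return res


def ccr_input(instance: DEAInstance, dmu: int) -> CCRResult:
    """Two-phase input-oriented CCR model.

    Phase I minimises the radial contraction ``theta`` subject to
    ``X lambda <= theta x_o``, ``Y lambda >= y_o``; phase II maximises the
    residual slacks at the optimal ``theta``. The reported total slack per
    input is observed minus frontier target, i.e. radial plus non-radial.
    """
    X, Y = instance.X, instance.Y
    m, n, s = instance.n_inputs, instance.n_dmus, instance.n_outputs
    x_o, y_o = X[:, dmu], Y[:, dmu]
    label = instance.labels[dmu]

    # Phase I: vars (theta, lambda)
    c = np.zeros(1 + n)
    c[0] = 1.0
    A_ub = np.block([
        [-x_o[:, None], X],          # X lam - theta x_o <= 0
        [np.zeros((s, 1)), -Y],      # -Y lam <= -y_o
    ])
    b_ub = np.concatenate([np.zeros(m), -y_o])
    res = _solve(c, A_ub=A_ub, b_ub=b_ub,
                 bounds=[(0, None)] * (1 + n), label=label)
    if res.status == 2:
        raise RuntimeError(f"CCR phase I infeasible for DMU {label!r}")
    theta = float(res.x[0])

    # Phase II: vars (lambda, s_minus, s_plus); maximise total slack
    c2 = np.concatenate([np.zeros(n), -np.ones(m + s)])
    A_eq = np.block([
        [X, np.eye(m), np.zeros((m, s))],    # X lam + s- = theta x_o
        [Y, np.zeros((s, m)), -np.eye(s)],   # Y lam - s+ = y_o
    ])
    b_eq = np.concatenate([theta * x_o, y_o])
    res2 = _solve(c2, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (n + m + s), label=label)
    if res2.status == 2:
        # theta from phase I sits at the edge of feasibility; nudge within
        # solver tolerance rather than fail
        b_eq[:m] = (theta + 1e-9) * x_o
        res2 = _solve(c2, A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * (n + m + s), label=label)
        if res2.status == 2:
            raise RuntimeError(f"CCR phase II infeasible for DMU {label!r}")
    lam = res2.x[:n]
    targets = X @ lam
    slacks = x_o - targets
    return CCRResult(theta=theta, lam=lam, input_targets=targets,
                     total_slacks=np.maximum(slacks, 0.0))


def sbm_input(instance: DEAInstance, dmu: int) -> SBMScore:
    """Standard input-oriented SBM score ``delta in (0, 1]``.

    Minimise ``(1/m) sum_i xbar_i / x_io`` over reference points
    ``xbar`` with ``X lambda <= xbar <= x_o`` and ``Y lambda >= y_o``.
    """
    X, Y = instance.X, instance.Y
    m, n, s = instance.n_inputs, instance.n_dmus, instance.n_outputs
    x_o, y_o = X[:, dmu], Y[:, dmu]
    label = instance.labels[dmu]

    # vars (xbar, lambda)
    c = np.concatenate([1.0 / (m * x_o), np.zeros(n)])
    A_ub = np.block([
        [-np.eye(m), X],                       # X lam - xbar <= 0
        [np.zeros((s, m)), -Y],                # -Y lam <= -y_o
        [np.eye(m), np.zeros((m, n))],         # xbar <= x_o
    ])
    b_ub = np.concatenate([np.zeros(m), -y_o, x_o])
    res = _solve(c, A_ub=A_ub, b_ub=b_ub,
                 bounds=[(0, None)] * (m + n), label=label)
    if res.status == 2:
        raise RuntimeError(f"SBM infeasible for DMU {label!r}")
    delta = float(res.fun)
    return SBMScore(delta=delta, efficient=delta >= 1.0 - EFFICIENCY_TOL,
                    mode="standard", lam=res.x[m:])


def super_sbm_input(instance: DEAInstance, dmu: int) -> SBMScore:
    """Super-efficiency SBM: the evaluated DMU leaves the reference set.

    Minimise ``(1/m) sum_i xbar_i / x_io`` with ``xbar >= X_{-o} lambda``,
    ``xbar >= x_o`` and ``Y_{-o} lambda >= y_o``; the score is >= 1.
    If no convex-cone combination of the other DMUs can produce ``y_o``
    the program is infeasible and the score is reported as ``inf``.
    """
    X, Y = instance.X, instance.Y
    m, n, s = instance.n_inputs, instance.n_dmus, instance.n_outputs
    x_o, y_o = X[:, dmu], Y[:, dmu]
    label = instance.labels[dmu]
    others = [j for j in range(n) if j != dmu]
    if not others:
        return SBMScore(delta=float("inf"), efficient=True, mode="super", lam=None)
    Xo, Yo = X[:, others], Y[:, others]

    # vars (xbar, lambda over others); xbar >= x_o via bounds
    c = np.concatenate([1.0 / (m * x_o), np.zeros(n - 1)])
    A_ub = np.block([
        [-np.eye(m), Xo],               # Xo lam - xbar <= 0
        [np.zeros((s, m)), -Yo],        # -Yo lam <= -y_o
    ])
    b_ub = np.concatenate([np.zeros(m), -y_o])
    bounds = [(xi, None) for xi in x_o] + [(0, None)] * (n - 1)
    res = _solve(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, label=label)
    if res.status == 2:
        return SBMScore(delta=float("inf"), efficient=True, mode="super", lam=None)
    lam = np.zeros(n)
    lam[others] = res.x[m:]
    return SBMScore(delta=float(res.fun), efficient=True, mode="super", lam=lam)


def efficiency_score(instance: DEAInstance, dmu: int) -> SBMScore:
    """Composite score: standard SBM if inefficient, super-SBM otherwise.

    Scores >= 1 indicate efficiency and rank the efficient units.
    """
    base = sbm_input(instance, dmu)
    if base.delta < 1.0 - EFFICIENCY_TOL:
        return base
    return super_sbm_input(instance, dmu)
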