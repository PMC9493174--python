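"""Entropy-weight method for objective multi-criteria scoring.

Given a decision matrix of m evaluation objects (cities) by n criteria
(resource indicators), criteria whose values fluctuate more across objects
carry more discriminating information, have lower Shannon entropy, and
receive larger weights. The weighted sum of the criteria is the
comprehensive indicator representing a city's overall resource endowment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DecisionMatrix", "WeightVector", "normalize_minmax",
           "entropy_weights", "composite_indicator"]


@dataclass(frozen=True)
class DecisionMatrix:
    """m x n table of indicator values with object and criterion labels."""

    a: np.ndarray
    objects: tuple
    criteria: tuple

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        if a.ndim != 2:
            raise ValueError("decision matrix must be 2-D")
        if a.shape[0] < 2:
            raise ValueError("need at least 2 evaluation objects")
        if not np.all(np.isfinite(a)):
            raise ValueError("decision matrix contains non-finite entries")
        if a.shape != (len(self.objects), len(self.criteria)):
            raise ValueError("label lengths do not match matrix shape")

    @classmethod
    def from_arrays(cls, a, objects=None, criteria=None) -> "DecisionMatrix":
        a = np.asarray(a, dtype=float)
        if objects is None:
            objects = tuple(range(a.shape[0]))
        if criteria is None:
            criteria = tuple(range(a.shape[1]))
        return cls(a=a, objects=tuple(objects), criteria=tuple(criteria))


@dataclass(frozen=True)
class WeightVector:
    """Entropy weights (sum to 1) with the per-criterion entropies."""

    w: np.ndarray
    e: np.ndarray
    criteria: tuple
    degenerate: tuple = ()


def normalize_minmax(dm: DecisionMatrix):
    """Column-wise min-max scaling ``(a - min) / (max - min)`` to [0, 1].

    Constant columns are mapped to all zeros and reported as degenerate;
    they carry no discriminating information.
    """
    a = dm.a
    lo, hi = a.min(axis=0), a.max(axis=0)
    span = hi - lo
    degenerate = span <= 0
    safe = np.where(degenerate, 1.0, span)
    a_star = (a - lo) / safe
    a_star[:, degenerate] = 0.0
    return a_star, tuple(np.asarray(dm.criteria)[degenerate].tolist())


def entropy_weights(dm: DecisionMatrix) -> WeightVector:
    """Shannon-entropy weights of the criteria.

    With ``p_ij = a*_ij / sum_i a*_ij`` the entropy of criterion *j* is
    ``e_j = -(sum_i p_ij ln p_ij) / ln m`` (with ``p ln p -> 0`` at
    ``p = 0``) and its weight ``w_j = (1 - e_j) / (n - sum_j e_j)``.
    Degenerate (constant) columns get ``e_j = 1`` and weight 0.
    """
    a_star, degenerate = normalize_minmax(dm)
    m, n = a_star.shape
    col_sum = a_star.sum(axis=0)
    e = np.ones(n)
    live = col_sum > 0
    if not np.any(live):
        raise ValueError("all criteria are degenerate: no information to weight")
    if degenerate:
        warnings.warn(
            f"constant criteria receive zero weight: {degenerate}",
            stacklevel=2,
        )
    p = a_star[:, live] / col_sum[live]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    e[live] = -plogp.sum(axis=0) / np.log(m)
    # clip tiny numerical excursions outside [0, 1]
    e = np.clip(e, 0.0, 1.0)
    w = (1.0 - e) / (n - e.sum())
    return WeightVector(w=w, e=e, criteria=dm.criteria, degenerate=degenerate)


def composite_indicator(dm: DecisionMatrix, wv: WeightVector,
                        mode: str = "raw") -> np.ndarray:
    """Comprehensive indicator ``C_i = sum_j w_j a_ij`` per object.

    ``mode='raw'`` weights the original indicator values; ``'normalized'``
    weights the min-max scaled values instead (invariant to affine
    rescaling of any criterion).
    """
    if tuple(wv.criteria) != tuple(dm.criteria):
        raise ValueError("weight vector criteria do not match decision matrix")
    if mode == "raw":
        basis = dm.a
    elif mode == "normalized":
        basis, _ = normalize_minmax(dm)
    else:
        raise ValueError(f"unknown composite mode {mode!r}; use 'raw' or 'normalized'")
    return basis @ wv.w
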