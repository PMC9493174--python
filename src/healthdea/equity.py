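"""Inequality measures for regional health resource allocation.

Implements the three equity instruments commonly used in health-resource
studies:

* the Lorenz curve and the Gini coefficient ``G`` of a resource allocated
  by population or by geographical area,
* the Theil index ``T`` with its within-/between-region decomposition and
  the associated contribution rates,
* the health resource density index (HRDI), the geometric mean of a
  resource's density per thousand persons and per square kilometre.

All functions accept plain sequences or numpy arrays of per-city amounts;
sorting and share normalisation happen internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GiniResult",
    "TheilDecomposition",
    "HRDIResult",
    "lorenz_points",
    "gini",
    "fairness_band",
    "theil",
    "theil_decompose",
    "contribution_rates",
    "hrdi",
]

#: Conventional fairness cutoffs for the Gini coefficient; a boundary value
#: is assigned to the fairer band (e.g. G = 0.2 is still "absolutely fair").
_FAIRNESS_BANDS = (
    (0.2, "absolutely fair"),
    (0.3, "fair"),
    (0.4, "relatively fair"),
    (0.5, "relatively unfair"),
    (np.inf, "very unfair"),
)


def _as_positive(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _sorted_shares(resource, denominator, labels=None):
    """Shares (P, Y) sorted ascending by resource per denominator unit.

    Ties are broken by label (stable), so the reported ranking is
    deterministic even though G itself is invariant to tie order.
    """
    y = _as_positive(resource, "resource")
    p = _as_positive(denominator, "denominator")
    if y.shape != p.shape:
        raise ValueError("resource and denominator must have equal length")
    if np.any(y < 0):
        raise ValueError("resource amounts must be non-negative")
    if np.any(p <= 0):
        raise ValueError("denominator entries must be strictly positive")
    if y.sum() <= 0:
        raise ValueError("total resource is zero; Lorenz curve undefined")
    if labels is None:
        labels = np.arange(y.size)
    labels = np.asarray(labels)
    percap = y / p
    order = np.lexsort((labels, percap))
    P = p[order] / p.sum()
    Y = y[order] / y.sum()
    return P, Y, labels[order]


def lorenz_points(resource, denominator, labels=None) -> np.ndarray:
    """Lorenz coordinates (cumP, cumY), from (0, 0) to (1, 1).

    Cities are ranked from the lowest to the highest resource holding per
    denominator unit, so the curve lies on or below the diagonal.
    """
    P, Y, _ = _sorted_shares(resource, denominator, labels)
    cum_p = np.concatenate(([0.0], np.cumsum(P)))
    cum_y = np.concatenate(([0.0], np.cumsum(Y)))
    # guard cumulative rounding so the curve ends exactly at (1, 1)
    cum_p[-1] = 1.0
    cum_y[-1] = 1.0
    return np.column_stack([cum_p, cum_y])


@dataclass(frozen=True)
class GiniResult:
    """Gini coefficient of one resource on one basis (population or area)."""

    G: float
    basis: str
    resource: str
    sort_order: tuple = ()
    band: str = field(default="")

    def __post_init__(self):
        if not self.band:
            object.__setattr__(self, "band", fairness_band(self.G))


def fairness_band(g: float) -> str:
    for cutoff, label in _FAIRNESS_BANDS:
        if g <= cutoff:
            return label
    raise AssertionError("unreachable")


def gini(resource, denominator, labels=None, basis: str = "population",
         resource_name: str = "resource") -> GiniResult:
    """Gini coefficient ``G = sum P_i Y_i + 2 sum P_i (1 - V_i) - 1``.

    ``P_i`` is city *i*'s share of the denominator (population or area),
    ``Y_i`` its share of the resource and ``V_i`` the cumulative resource
    share after ranking cities by per-unit holdings, ascending.
    """
    P, Y, order = _sorted_shares(resource, denominator, labels)
    V = np.cumsum(Y)
    g = float(P @ Y + 2.0 * P @ (1.0 - V) - 1.0)
    g = max(g, 0.0)  # clip -eps from cumulative rounding at perfect equality
    return GiniResult(G=g, basis=basis, resource=resource_name,
                      sort_order=tuple(order.tolist()))


def theil(P, Y, *, log=np.log) -> float:
    """Theil index ``T = sum P_i log(P_i / Y_i)`` on share vectors.

    Both arguments must be non-negative and sum to one. Natural logarithm
    by default; pass ``log=np.log10`` for a base-10 sensitivity check.
    Cities with ``P_i = 0`` contribute nothing; ``Y_i = 0`` with
    ``P_i > 0`` is a domain error.
    """
    P = _as_positive(P, "P")
    Y = _as_positive(Y, "Y")
    if P.shape != Y.shape:
        raise ValueError("P and Y must have equal length")
    for name, v in (("P", P), ("Y", Y)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum():.12g})")
    if np.any((Y == 0) & (P > 0)):
        raise ValueError("Y_i = 0 with P_i > 0: Theil term log(P/Y) undefined")
    mask = P > 0
    return float(np.sum(P[mask] * log(P[mask] / Y[mask])))


@dataclass(frozen=True)
class TheilDecomposition:
    """Theil index split into within- and between-region components.

    ``T = T_intra + T_inter`` holds as an algebraic identity; the
    contribution rates are the proportions ``T_intra/T``, ``T_inter/T``
    and ``P_g T_g / T`` per region.
    """

    T: float
    T_intra: float
    T_inter: float
    T_g: dict
    P_g: dict
    Y_g: dict
    contrib_intra: float
    contrib_inter: float
    contrib_region: dict


def theil_decompose(amounts, denominators, regions, *, log=np.log) -> TheilDecomposition:
    """Decompose the Theil index by a region partition.

    ``T_intra = sum_g P_g T_g`` with ``T_g`` the Theil index of region *g*
    on shares renormalised within the region, and
    ``T_inter = sum_g P_g log(P_g / Y_g)``.
    """
    y = _as_positive(amounts, "amounts")
    p = _as_positive(denominators, "denominators")
    regions = np.asarray(regions)
    if not (y.shape == p.shape == regions.shape):
        raise ValueError("amounts, denominators and regions must align")
    P = p / p.sum()
    Y = y / y.sum()
    T = theil(P, Y, log=log)

    T_g, P_g, Y_g = {}, {}, {}
    for g in dict.fromkeys(regions.tolist()):  # preserves first-seen order
        m = regions == g
        pg, yg = float(P[m].sum()), float(Y[m].sum())
        if yg <= 0:
            raise ValueError(f"region {g!r} holds zero resource")
        P_g[g], Y_g[g] = pg, yg
        T_g[g] = theil(P[m] / pg, Y[m] / yg, log=log)

    T_intra = float(sum(P_g[g] * T_g[g] for g in T_g))
    T_inter = float(sum(P_g[g] * log(np.array(P_g[g] / Y_g[g])) for g in T_g))
    if T > 0:
        ci, ce = T_intra / T, T_inter / T
        cr = {g: P_g[g] * T_g[g] / T for g in T_g}
    else:  # perfect equality: rates undefined, reported as NaN
        ci = ce = float("nan")
        cr = {g: float("nan") for g in T_g}
    return TheilDecomposition(
        T=T, T_intra=T_intra, T_inter=T_inter, T_g=T_g, P_g=P_g, Y_g=Y_g,
        contrib_intra=ci, contrib_inter=ce, contrib_region=cr,
    )


def contribution_rates(dec: TheilDecomposition):
    """Contribution proportions of the within part, the between part and
    each region (``P_g T_g / T``). Undefined at T = 0 (perfect equality)."""
    if dec.T <= 0:
        raise ValueError("contribution rates undefined at T = 0 (perfect equality)")
    return (
        dec.T_intra / dec.T,
        dec.T_inter / dec.T,
        {g: dec.P_g[g] * dec.T_g[g] / dec.T for g in dec.T_g},
    )


@dataclass(frozen=True)
class HRDIResult:
    """Health resource density index and its two component densities."""

    value: float
    density_per_1000: float
    density_per_km2: float


def hrdi(resource: float, population: float, area: float) -> HRDIResult:
    """Geometric mean of resource per 1000 persons and resource per km²."""
    if population <= 0 or area <= 0:
        raise ValueError("population and area must be strictly positive")
    if resource < 0:
        raise ValueError("resource must be non-negative")
    per_1000 = resource / (population / 1000.0)
    per_km2 = resource / area
    return HRDIResult(
        value=float(np.sqrt(per_1000 * per_km2)),
        density_per_1000=float(per_1000),
        density_per_km2=float(per_km2),
    )
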