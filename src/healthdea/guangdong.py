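"""Published provincial summary figures for Guangdong, 2016-2020.

These are the aggregate tables printed in the published analysis of
Guangdong's public-hospital resources: provincial resource totals with
their per-thousand-person and per-km^2 densities, and the adjusted
(three-stage) efficiency scores of the 21 cities. The city-level raw
inputs behind them were never published, so these aggregates serve as
fixed reference inputs for arithmetic cross-checks (density division,
mean/efficient-count aggregation), not as something the package can
recompute from primary data.
"""

from __future__ import annotations

import pandas as pd

from .panel import DEFAULT_REGION_PARTITION

__all__ = ["LAND_AREA_KM2", "RESOURCE_TOTALS", "ADJUSTED_EFFICIENCY",
           "REGION_OF_CITY", "YEARS", "resource_totals_frame",
           "adjusted_efficiency_frame"]

#: Guangdong land area, km^2.
LAND_AREA_KM2 = 179_700.0

YEARS = (2016, 2017, 2018, 2019, 2020)

#: Provincial totals and printed densities:
#: resource -> year -> (per_1000_persons, per_km2, total).
#: Subsidies are in millions of RMB.
RESOURCE_TOTALS = {
    "hospitals": {
        2016: (0.0076, 0.0051, 909),
        2017: (0.0075, 0.0050, 907),
        2018: (0.0073, 0.0050, 898),
        2019: (0.0072, 0.0050, 900),
        2020: (0.0071, 0.0050, 898),
    },
    "beds": {
        2016: (2.7532, 1.8242, 327_846),
        2017: (2.8077, 1.8967, 340_888),
        2018: (2.8673, 1.9700, 354_058),
        2019: (2.9867, 2.0764, 373_008),
        2020: (3.0063, 2.1126, 379_521),
    },
    "technicians": {
        2016: (3.3433, 2.2162, 398_118),
        2017: (3.4573, 2.3366, 419_752),
        2018: (3.5578, 2.4455, 439_316),
        2019: (3.6818, 2.5596, 459_825),
        2020: (3.7705, 2.6496, 475_989),
    },
    "subsidies": {
        2016: (0.1950, 0.1292, 23_218),
        2017: (0.2391, 0.1615, 29_033),
        2018: (0.2817, 0.1935, 34_783),
        2019: (0.3299, 0.2293, 41_205),
        2020: (0.4816, 0.3383, 60_796),
    },
}

#: Adjusted (stage-3) super-SBM efficiency scores of the 21 cities.
ADJUSTED_EFFICIENCY = {
    "GZ": (1.255, 1.316, 1.303, 1.310, 1.267),
    "SZ": (1.300, 1.224, 1.289, 1.244, 1.079),
    "ZH": (0.768, 0.802, 0.869, 0.896, 1.200),
    "FS": (1.121, 1.087, 1.089, 1.104, 1.103),
    "HZ": (0.851, 0.857, 0.879, 0.881, 0.859),
    "DG": (0.928, 0.975, 0.977, 1.013, 1.049),
    "ZS": (1.080, 1.079, 1.065, 1.054, 1.042),
    "JM": (0.858, 0.862, 0.883, 0.858, 0.894),
    "ZQ": (0.636, 0.669, 0.694, 0.683, 0.716),
    "ST": (0.764, 0.737, 0.774, 0.795, 0.844),
    "SW": (0.623, 0.639, 0.660, 0.635, 0.614),
    "CZ": (0.654, 0.673, 0.674, 0.672, 0.663),
    "JY": (0.813, 0.840, 0.918, 0.921, 0.903),
    "YJ": (0.713, 0.716, 0.781, 0.787, 0.725),
    "ZJ": (0.820, 0.810, 0.900, 0.936, 0.935),
    "MM": (1.023, 1.031, 1.035, 1.039, 1.085),
    "SG": (0.785, 0.799, 0.854, 0.861, 0.870),
    "HY": (0.760, 0.776, 0.769, 0.752, 0.734),
    "MZ": (0.759, 0.783, 0.840, 0.841, 0.841),
    "QY": (0.838, 0.877, 1.010, 1.005, 1.005),
    "YF": (0.724, 0.703, 0.765, 0.732, 0.784),
}

REGION_OF_CITY = {c: g for g, cities in DEFAULT_REGION_PARTITION.items()
                  for c in cities}


def resource_totals_frame() -> pd.DataFrame:
    rows = []
    for resource, by_year in RESOURCE_TOTALS.items():
        for year, (per_1000, per_km2, total) in by_year.items():
            rows.append({"resource": resource, "year": year,
                         "per_1000_persons": per_1000,
                         "per_km2": per_km2, "total": total})
    return pd.DataFrame(rows)


def adjusted_efficiency_frame() -> pd.DataFrame:
    rows = [
        {"city_id": c, "region": REGION_OF_CITY[c], "year": y, "score": s}
        for c, scores in ADJUSTED_EFFICIENCY.items()
        for y, s in zip(YEARS, scores)
    ]
    return pd.DataFrame(rows)
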