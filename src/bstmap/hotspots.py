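"""Exceedance-probability hotspot detection against yearly median thresholds.

A hotspot is an area-year whose posterior probability of exceeding the
cross-area median rate for that year is above 1 − alpha. The threshold q_t
is the median of the *observed* rates across areas within year t, and the
comparison is made on the log scale — P(mu_z_it > ln q_t) — i.e. the
geometric-mean rate exp(mu_z) is compared with q_t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import SpaceTimePanel

__all__ = [
    "ExceedanceResult",
    "yearly_median_threshold",
    "exceedance_probability",
    "classify_hotspots",
    "detect_hotspots",
    "hotspot_geojson",
]


@dataclass
class ExceedanceResult:
    area_ids: list[str]
    years: np.ndarray
    thresholds: np.ndarray  # per-year q_t, deaths per 100,000
    probabilities: np.ndarray  # (n_areas, n_years)
    hotspot: np.ndarray  # boolean grid
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, aid in enumerate(self.area_ids):
            for j, yr in enumerate(self.years):
                rows.append(
                    {
                        "area_id": aid,
                        "year": int(yr),
                        "threshold": self.thresholds[j],
                        "exceedance_probability": self.probabilities[i, j],
                        "hotspot": bool(self.hotspot[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def yearly_median_threshold(panel: SpaceTimePanel) -> np.ndarray:
    """q_t: the median observed rate across areas within each year.

    For an even number of observed areas the mean of the middle two is used
    (the ordinary sample median). A year with no observed area is a hard
    error.
    """
    thresholds = np.empty(panel.n_years)
    for j, yr in enumerate(panel.years):
        col = panel.rates[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"year {int(yr)} has no observed rates")
        thresholds[j] = np.median(col)
    return thresholds


def exceedance_probability(mu_z_draws: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """p_it = fraction of posterior draws with mu_z_it above ln q_t."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be strictly positive (log is taken)")
    log_q = np.log(thresholds)  # (T,)
    return np.mean(mu_z_draws > log_q[None, None, :], axis=0)


def classify_hotspots(
    probabilities: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Hotspot iff p_it > 1 − alpha (strict: a tie at the cutoff is not a hotspot)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return np.asarray(probabilities) > 1.0 - alpha


def detect_hotspots(panel: SpaceTimePanel, mu_z_draws: np.ndarray, alpha: float = 0.05) -> ExceedanceResult:
    """Full detection pass: thresholds, probabilities and classification."""
    thresholds = yearly_median_threshold(panel)
    probabilities = exceedance_probability(mu_z_draws, thresholds)
    return ExceedanceResult(
        area_ids=list(panel.area_ids),
        years=panel.years,
        thresholds=thresholds,
        probabilities=probabilities,
        hotspot=classify_hotspots(probabilities, alpha),
        alpha=alpha,
    )


def hotspot_geojson(result: ExceedanceResult, polygons: dict[str, dict], path) -> None:
    """Write a choropleth-ready FeatureCollection: per-area yearly p and flags.

    ``polygons`` maps area_id -> GeoJSON geometry dict. Hotspot years are
    listed per area; the conventional red/blue colour split is carried as a
    property on the last year's classification.
    """
    features = []
    for i, aid in enumerate(result.area_ids):
        if aid not in polygons:
            continue
        props = {
            "area_id": aid,
            "hotspot_years": [int(y) for y, h in zip(result.years, result.hotspot[i]) if h],
            "color": "red" if result.hotspot[i, -1] else "blue",
        }
        for j, yr in enumerate(result.years):
            props[f"p_{int(yr)}"] = float(result.probabilities[i, j])
        features.append(
            {"type": "Feature", "geometry": polygons[aid], "properties": props}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
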