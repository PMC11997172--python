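"""Descriptive trend reporting: yearly group means, percent changes, rankings.

Group means are unweighted cross-country means of the observed rates —
every country counts equally, whatever its population — matching how a few
extreme countries can dominate a regional average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import SpaceTimePanel

__all__ = [
    "TrendSummary",
    "yearly_group_means",
    "percent_change",
    "top_k_mean_rates",
    "plot_trends",
]


@dataclass
class TrendSummary:
    group: str
    years: np.ndarray
    yearly_means: np.ndarray  # NaN where the group-year had no observations
    anchor_years: tuple[int, int]
    percent_change: float  # 100·(mean_end − mean_start)/mean_start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "year": self.years, "mean_rate": self.yearly_means}
        )


def percent_change(start_value: float, end_value: float) -> float:
    """Signed percent change 100·(end − start)/start; negative for declines.

    The magnitude |percent_change| is the "decrease of X%" convention used
    when narrating declines.
    """
    if start_value <= 0:
        raise ValueError("start value must be positive")
    return 100.0 * (end_value - start_value) / start_value


def yearly_group_means(
    panel: SpaceTimePanel,
    grouping: str | dict[str, str] = "global",
    weights: dict[str, float] | None = None,
) -> list[TrendSummary]:
    """Per-group yearly mean rates with the start-to-end percent change.

    ``grouping`` is "global" (one group of all areas), "region" (use the
    panel's region labels), or an explicit area_id -> group mapping.
    ``weights`` optionally supplies population-style weights per area;
    the default is the unweighted cross-country mean.
    """
    if grouping == "global":
        mapping = {aid: "global" for aid in panel.area_ids}
    elif grouping == "region":
        mapping = {aid: panel.regions.get(aid, "") for aid in panel.area_ids}
        if any(v == "" for v in mapping.values()):
            missing = [a for a, v in mapping.items() if v == ""][:3]
            raise ValueError(f"areas without region labels: {missing} ...")
    else:
        mapping = dict(grouping)
        absent = [a for a in panel.area_ids if a not in mapping]
        if absent:
            raise ValueError(f"grouping does not cover areas: {absent[:3]} ...")

    summaries = []
    for group in sorted(set(mapping.values())):
        idx = [i for i, aid in enumerate(panel.area_ids) if mapping[aid] == group]
        sub = panel.rates[idx, :]
        if weights is not None:
            w = np.array([weights[panel.area_ids[i]] for i in idx], dtype=float)
            wsum = np.where(np.isfinite(sub), w[:, None], 0.0).sum(axis=0)
            means = np.nansum(sub * w[:, None], axis=0) / np.where(wsum > 0, wsum, np.nan)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means = np.nanmean(sub, axis=0)
        empty = ~np.isfinite(means)
        if empty.any():
            warnings.warn(
                f"group {group!r}: no observations in year(s) "
                f"{[int(panel.years[j]) for j in np.flatnonzero(empty)]}",
                stacklevel=2,
            )
        observed_years = np.flatnonzero(np.isfinite(means))
        start_j, end_j = observed_years[0], observed_years[-1]
        summaries.append(
            TrendSummary(
                group=group,
                years=panel.years,
                yearly_means=means,
                anchor_years=(int(panel.years[start_j]), int(panel.years[end_j])),
                percent_change=percent_change(means[start_j], means[end_j]),
            )
        )
    return summaries


def top_k_mean_rates(panel: SpaceTimePanel, k: int) -> pd.DataFrame:
    """Areas ranked by their mean observed rate over the whole period.

    Returns the top k (descending period mean; ties broken by area_id) with
    columns area_id, region, mean_rate.
    """
    if k > panel.n_areas:
        raise ValueError(f"k={k} exceeds {panel.n_areas} areas")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(panel.rates, axis=1)
    table = pd.DataFrame(
        {
            "area_id": panel.area_ids,
            "region": [panel.regions.get(a, "") for a in panel.area_ids],
            "mean_rate": means,
        }
    )
    table = table.sort_values(
        by=["mean_rate", "area_id"], ascending=[False, True], kind="mergesort"
    )
    return table.head(k).reset_index(drop=True)


def plot_trends(summaries: list[TrendSummary], path) -> None:
    """Simple line plot of group yearly means for visual QA (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for s in summaries:
        ax.plot(s.years, s.yearly_means, marker="o", markersize=3, label=s.group)
    ax.set_xlabel("year")
    ax.set_ylabel("mean age-standardized rate (per 100,000)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
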