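"""Shared in-memory containers for area-by-year rate and covariate panels.

The pipeline works on a dense area × year grid of age-standardized mortality
rates y_it (deaths per 100,000) and its natural-log transform z_it = ln y_it,
together with an aligned area × year × covariate array of risk-factor values.
Areas are always ordered lexicographically by area id and years ascending, so
panels, graphs and posterior draws align by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpaceTimePanel", "CovariatePanel"]


@dataclass
class SpaceTimePanel:
    """Dense area × year grid of observed rates with a missingness mask.

    Attributes
    ----------
    area_ids : list of str
        Area identifiers, sorted lexicographically.
    years : numpy.ndarray
        Consecutive calendar years, ascending.
    rates : numpy.ndarray, shape (n_areas, n_years)
        Observed rates per 100,000; NaN where missing.
    log_rates : numpy.ndarray, shape (n_areas, n_years)
        Natural log of ``rates`` where observed and positive; NaN otherwise.
    missing_mask : numpy.ndarray of bool
        True where the cell is missing (no usable observation).
    regions : dict, optional
        area_id -> region label, when the source file carried one.
    stratum : str
        The stratum this panel was extracted for (e.g. "both").
    """

    area_ids: list[str]
    years: np.ndarray
    rates: np.ndarray
    log_rates: np.ndarray
    missing_mask: np.ndarray
    regions: dict[str, str] = field(default_factory=dict)
    stratum: str = "both"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.rates.shape != (len(self.area_ids), len(self.years)):
            raise ValueError(
                f"rates shape {self.rates.shape} does not match "
                f"{len(self.area_ids)} areas x {len(self.years)} years"
            )
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive integers")

    @classmethod
    def from_rates(
        cls,
        area_ids: list[str],
        years,
        rates,
        regions: dict[str, str] | None = None,
        stratum: str = "both",
    ) -> "SpaceTimePanel":
        """Build a panel from a rate grid, deriving log rates and the mask.

        Zero rates have no finite log and are flagged missing with a warning;
        negative rates are rejected.
        """
        rates = np.asarray(rates, dtype=float)
        if np.any(rates[np.isfinite(rates)] < 0):
            raise ValueError("rates must be non-negative")
        missing = ~np.isfinite(rates)
        n_zero = int(np.sum(rates[~missing] == 0))
        if n_zero:
            warnings.warn(
                f"{n_zero} zero rate cell(s) have undefined log; treated as missing",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            log_rates = np.where(rates > 0, np.log(np.where(rates > 0, rates, 1.0)), np.nan)
        missing = missing | ~np.isfinite(log_rates)
        rates = np.where(missing, np.nan, rates)
        log_rates = np.where(missing, np.nan, log_rates)
        return cls(
            area_ids=list(area_ids),
            years=np.asarray(years, dtype=int),
            rates=rates,
            log_rates=log_rates,
            missing_mask=missing,
            regions=dict(regions or {}),
            stratum=stratum,
        )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (area_id, region, year, stratum, rate); observed cells only."""
        rows = []
        for i, aid in enumerate(self.area_ids):
            for j, yr in enumerate(self.years):
                if not self.missing_mask[i, j]:
                    rows.append(
                        {
                            "area_id": aid,
                            "region": self.regions.get(aid, ""),
                            "year": int(yr),
                            "stratum": self.stratum,
                            "rate": self.rates[i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["area_id", "region", "year", "stratum", "rate"])


@dataclass
class CovariatePanel:
    """Area × year × covariate array X_itm aligned to a SpaceTimePanel.

    ``standardization_record`` maps covariate name -> (mean, sd) used when
    :meth:`standardized` was applied, so multiplicative effect sizes reported
    per standardized unit can be mapped back to native units.
    """

    area_ids: list[str]
    years: np.ndarray
    names: list[str]
    values: np.ndarray  # (n_areas, n_years, n_covariates), NaN = missing
    standardization_record: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.area_ids), len(self.years), len(self.names))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def select(self, names: list[str]) -> "CovariatePanel":
        idx = [self.names.index(n) for n in names]
        return CovariatePanel(
            area_ids=self.area_ids,
            years=self.years,
            names=list(names),
            values=self.values[:, :, idx].copy(),
            standardization_record={
                n: self.standardization_record[n]
                for n in names
                if n in self.standardization_record
            },
        )

    def standardized(self) -> "CovariatePanel":
        """Return a copy with each covariate centred and scaled to unit sd.

        Means/sds are computed over observed cells; the record of the
        transformation is attached. Already-standardized panels pass through
        with an updated record.
        """
        vals = self.values.copy()
        record: dict[str, tuple[float, float]] = {}
        for m, name in enumerate(self.names):
            col = vals[:, :, m]
            obs = np.isfinite(col)
            mu = float(np.nanmean(col))
            sd = float(np.nanstd(col))
            if sd == 0:
                raise ValueError(f"covariate {name!r} is constant; cannot standardize")
            vals[:, :, m] = np.where(obs, (col - mu) / sd, np.nan)
            record[name] = (mu, sd)
        return CovariatePanel(
            area_ids=self.area_ids,
            years=self.years,
            names=list(self.names),
            values=vals,
            standardization_record=record,
        )

    def imputed(self) -> tuple["CovariatePanel", pd.DataFrame]:
        """Fill missing covariate cells: forward-fill within area, then area mean.

        Returns the filled panel and a log of imputed cells
        (area_id, year, name, method).
        """
        vals = self.values.copy()
        log_rows = []
        for m, name in enumerate(self.names):
            for i, aid in enumerate(self.area_ids):
                series = vals[i, :, m]
                missing = ~np.isfinite(series)
                if not missing.any():
                    continue
                filled = pd.Series(series).ffill().to_numpy()
                newly = missing & np.isfinite(filled)
                for j in np.flatnonzero(newly):
                    log_rows.append((aid, int(self.years[j]), name, "forward_fill"))
                still = ~np.isfinite(filled)
                if still.any():
                    if np.isfinite(filled).any():
                        fill_value = float(np.nanmean(filled))
                        method = "area_mean"
                    else:
                        fill_value = float(np.nanmean(vals[:, :, m]))
                        method = "global_mean"
                    for j in np.flatnonzero(still):
                        log_rows.append((aid, int(self.years[j]), name, method))
                    filled = np.where(still, fill_value, filled)
                vals[i, :, m] = filled
        log = pd.DataFrame(log_rows, columns=["area_id", "year", "name", "method"])
        panel = CovariatePanel(
            area_ids=self.area_ids,
            years=self.years,
            names=list(self.names),
            values=vals,
            standardization_record=dict(self.standardization_record),
        )
        return panel, log

    def to_frame(self) -> pd.DataFrame:
        """Long-format (area_id, year, name, value) view; observed cells only."""
        rows = []
        for i, aid in enumerate(self.area_ids):
            for j, yr in enumerate(self.years):
                for m, name in enumerate(self.names):
                    v = self.values[i, j, m]
                    if np.isfinite(v):
                        rows.append({"area_id": aid, "year": int(yr), "name": name, "value": v})
        return pd.DataFrame(rows, columns=["area_id", "year", "name", "value"])
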