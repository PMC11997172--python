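"""Two-step model selection: covariate screening, then a structure search.

Step one screens candidate risk factors by their Pearson correlation with the
log rate over pooled area-year cells and prunes collinear pairs, keeping from
each highly correlated pair the member more strongly correlated with the
outcome. Step two fits every candidate random-effect structure (by default
the full 3 spatial × 3 temporal × 4 interaction grid of 36 combinations) and
scores each fit with DIC, WAIC, LPML (summed log conditional predictive
ordinates), bias, RMSE, the fitted-observed Pearson correlation, and wall
time. WAIC is the headline criterion; ties break by DIC, then LPML, then
RMSE.
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import pearsonr, spearmanr

from .model import (
    MCMCSettings,
    ModelSpec,
    PosteriorDraws,
    arithmetic_mean_rate,
    fit_gibbs,
)
from .panels import CovariatePanel, SpaceTimePanel
from .structures import AreaGraph

__all__ = [
    "FitMetrics",
    "ScreeningReport",
    "screen_covariates",
    "pointwise_loglik",
    "compute_dic",
    "plugin_pointwise_loglik",
    "compute_waic",
    "compute_cpo",
    "compute_fit_errors",
    "candidate_grid",
    "evaluate_fit",
    "two_step_select",
]


@dataclass
class FitMetrics:
    dic: float
    p_dic: float
    waic: float
    p_waic: float
    lpml: float
    bias: float
    rmse: float
    pearson_r: float
    runtime_seconds: float


@dataclass
class ScreeningReport:
    candidate_names: list[str]
    correlation_with_outcome: dict[str, float]
    pruned_pairs: list[tuple[str, str, float]]  # (kept, dropped, pairwise r)
    retained_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.candidate_names,
                "r_with_outcome": [
                    self.correlation_with_outcome.get(n, np.nan) for n in self.candidate_names
                ],
                "retained": [n in self.retained_names for n in self.candidate_names],
            }
        )


def screen_covariates(
    covariates: CovariatePanel,
    panel: SpaceTimePanel,
    collinearity_threshold: float = 0.7,
    method: str = "pearson",
) -> ScreeningReport:
    """Correlation screening with greedy collinearity pruning.

    Correlations are computed over pooled observed area-year cells against
    z = ln(rate). Pairs with |pairwise r| above the threshold are resolved
    from the most collinear downward, dropping the member with the weaker
    |correlation with the outcome|. Constant covariates are dropped with a
    warning (their correlation is undefined).
    """
    if not (0.0 < collinearity_threshold < 1.0):
        raise ValueError("collinearity threshold must be in (0, 1)")
    corr = {"pearson": pearsonr, "spearman": spearmanr}[method]
    names = list(covariates.names)
    z = panel.log_rates
    obs = ~panel.missing_mask

    outcome_r: dict[str, float] = {}
    usable: list[str] = []
    for m, name in enumerate(names):
        x = covariates.values[:, :, m]
        mask = obs & np.isfinite(x)
        if mask.sum() < 3 or np.nanstd(x[mask]) == 0:
            warnings.warn(f"covariate {name!r} constant or too sparse; dropped", stacklevel=2)
            continue
        outcome_r[name] = float(corr(x[mask], z[mask])[0])
        usable.append(name)

    # pairwise correlations among usable covariates
    pair_r: dict[tuple[str, str], float] = {}
    for a, b_name in itertools.combinations(usable, 2):
        xa = covariates.values[:, :, names.index(a)]
        xb = covariates.values[:, :, names.index(b_name)]
        mask = np.isfinite(xa) & np.isfinite(xb)
        if mask.sum() >= 3 and np.nanstd(xa[mask]) > 0 and np.nanstd(xb[mask]) > 0:
            pair_r[(a, b_name)] = float(corr(xa[mask], xb[mask])[0])

    retained = list(usable)
    pruned: list[tuple[str, str, float]] = []
    while True:
        violating = [
            (pair, r)
            for pair, r in pair_r.items()
            if abs(r) > collinearity_threshold and pair[0] in retained and pair[1] in retained
        ]
        if not violating:
            break
        (a, b_name), r = max(violating, key=lambda item: abs(item[1]))
        keep, drop = (a, b_name) if abs(outcome_r[a]) >= abs(outcome_r[b_name]) else (b_name, a)
        retained.remove(drop)
        pruned.append((keep, drop, r))
    return ScreeningReport(
        candidate_names=names,
        correlation_with_outcome=outcome_r,
        pruned_pairs=pruned,
        retained_names=retained,
    )


# ---------------------------------------------------------------------------
# Fit metrics
# ---------------------------------------------------------------------------


def pointwise_loglik(draws: PosteriorDraws, panel: SpaceTimePanel) -> np.ndarray:
    """Normal log density of each observed z_it under each posterior draw.

    Returns an array of shape (n_draws, n_observed_cells).
    """
    obs = ~panel.missing_mask
    z = panel.log_rates[obs]  # (n_obs,)
    mu = draws.mu_z[:, obs]  # (n_draws, n_obs)
    sig = draws.sigma_z_sq[:, None]
    return -0.5 * (np.log(2.0 * np.pi * sig) + (z[None, :] - mu) ** 2 / sig)


def compute_dic(
    loglik: np.ndarray, plugin_loglik: np.ndarray | None = None
) -> tuple[float, float]:
    """Deviance information criterion from the pointwise log likelihood.

    With ``plugin_loglik`` — the pointwise log likelihood at the posterior
    means of (mu_z, sigma_z^2) — the classic p_DIC = D-bar − D-hat is used.
    Without it the only draw-level estimate available is Gelman's
    half-variance form, p_DIC = var(deviance)/2, which agrees with the
    plug-in form for approximately Gaussian deviance posteriors; both vanish
    when all draws are identical.
    """
    if loglik.shape[0] < 2:
        raise ValueError("need at least 2 draws")
    deviance = -2.0 * loglik.sum(axis=1)
    d_bar = float(deviance.mean())
    if plugin_loglik is not None:
        d_hat = float(-2.0 * plugin_loglik.sum())
        p_dic = d_bar - d_hat
    else:
        p_dic = float(deviance.var(ddof=1) / 2.0)
    return d_bar + p_dic, p_dic


def plugin_pointwise_loglik(
    mu_draws: np.ndarray, sigma_sq_draws: np.ndarray, z_obs: np.ndarray
) -> np.ndarray:
    """Pointwise Normal log likelihood at posterior means of (mu, sigma^2)."""
    mu_hat = mu_draws.mean(axis=0)
    sig_hat = float(np.mean(sigma_sq_draws))
    return -0.5 * (np.log(2.0 * np.pi * sig_hat) + (z_obs - mu_hat) ** 2 / sig_hat)


def compute_waic(loglik: np.ndarray) -> tuple[float, float]:
    """Widely applicable information criterion from the pointwise log likelihood.

    lppd sums, per cell, the log of the posterior-mean likelihood (via
    log-sum-exp); the effective-parameter term sums the per-cell variance of
    the log likelihood across draws.
    """
    if loglik.shape[0] < 2:
        raise ValueError("need at least 2 draws")
    n = loglik.shape[0]
    lppd = float(np.sum(logsumexp(loglik, axis=0) - np.log(n)))
    p_waic = float(np.sum(np.var(loglik, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def compute_cpo(loglik: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-cell conditional predictive ordinates and the summed log (LPML).

    CPO_i is the harmonic mean of the likelihood across draws, computed in
    log space; cells whose harmonic-mean term overflows are flagged unstable
    (returned as NaN) and excluded from LPML with a warning.
    """
    if loglik.shape[0] < 2:
        raise ValueError("need at least 2 draws")
    n = loglik.shape[0]
    log_cpo = np.log(n) - logsumexp(-loglik, axis=0)
    unstable = ~np.isfinite(log_cpo)
    if unstable.any():
        warnings.warn(f"{int(unstable.sum())} unstable CPO cell(s) excluded", stacklevel=2)
        log_cpo = np.where(unstable, np.nan, log_cpo)
    lpml = float(np.nansum(log_cpo))
    return np.exp(log_cpo), lpml


def compute_fit_errors(
    panel: SpaceTimePanel, draws: PosteriorDraws
) -> tuple[float, float, float]:
    """(bias, rmse, pearson r) of posterior-mean fitted rates vs observed rates.

    Fitted values are posterior means of the arithmetic-scale expected rate
    exp(mu_z + sigma_z^2/2).
    """
    obs = ~panel.missing_mask
    fitted = arithmetic_mean_rate(draws.mu_z, draws.sigma_z_sq).mean(axis=0)[obs]
    observed = panel.rates[obs]
    err = fitted - observed
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    r = float(pearsonr(fitted, observed)[0]) if len(observed) > 2 else np.nan
    return bias, rmse, r


def evaluate_fit(panel: SpaceTimePanel, draws: PosteriorDraws, runtime_seconds: float = 0.0) -> FitMetrics:
    """All fit metrics for one posterior sample."""
    loglik = pointwise_loglik(draws, panel)
    obs = ~panel.missing_mask
    plugin = plugin_pointwise_loglik(draws.mu_z[:, obs], draws.sigma_z_sq, panel.log_rates[obs])
    dic, p_dic = compute_dic(loglik, plugin)
    if p_dic < 0:
        warnings.warn(f"negative p_DIC ({p_dic:.3f})", stacklevel=2)
    waic, p_waic = compute_waic(loglik)
    _, lpml = compute_cpo(loglik)
    bias, rmse, r = compute_fit_errors(panel, draws)
    return FitMetrics(
        dic=dic,
        p_dic=p_dic,
        waic=waic,
        p_waic=p_waic,
        lpml=lpml,
        bias=bias,
        rmse=rmse,
        pearson_r=r,
        runtime_seconds=runtime_seconds,
    )


# ---------------------------------------------------------------------------
# Structure search
# ---------------------------------------------------------------------------

SPATIAL_GRID = ("iid", "besag", "bym")
TEMPORAL_GRID = ("iid", "rw1", "rw2")
INTERACTION_GRID = ("I", "II", "III", "IV")


def candidate_grid(
    covariate_names=(),
    coefficient_mode: str = "area_varying",
    hyperpriors=None,
) -> list[ModelSpec]:
    """The full 3 × 3 × 4 = 36 cross of candidate structures."""
    from .model import HyperPriors

    hp = hyperpriors or HyperPriors()
    specs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-combination warnings
        for sf, tf, it in itertools.product(SPATIAL_GRID, TEMPORAL_GRID, INTERACTION_GRID):
            specs.append(
                ModelSpec(
                    covariate_names=tuple(covariate_names),
                    coefficient_mode=coefficient_mode,
                    spatial_family=sf,
                    temporal_family=tf,
                    interaction_type=it,
                    hyperpriors=hp,
                )
            )
    return specs


def _candidate_seed(master_seed: int, label: str) -> int:
    """Stable per-candidate seed derived from the master seed and the label."""
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return int((master_seed * 1000003 + h) % (2**31 - 1))


def two_step_select(
    panel: SpaceTimePanel,
    covariates: CovariatePanel | None,
    graph: AreaGraph,
    candidate_specs: list[ModelSpec] | None = None,
    mcmc: MCMCSettings = MCMCSettings(),
) -> tuple[pd.DataFrame, ModelSpec | None]:
    """Fit and rank every candidate structure; return the table and the winner.

    The covariate set is assumed already screened (step one feeds step two a
    fixed set, carried on each candidate spec). The winner minimizes WAIC;
    ties break by DIC, then maximal LPML, then RMSE. A failed fit becomes a
    `failed` row rather than aborting the search. Per-candidate seeds are
    derived from the master seed and the structure label, so results do not
    depend on evaluation order.
    """
    if candidate_specs is None:
        names = () if covariates is None else tuple(covariates.names)
        candidate_specs = candidate_grid(covariate_names=names)
    rows = []
    fits: list[FitMetrics | None] = []
    for spec in candidate_specs:
        run_mcmc = MCMCSettings(
            iterations=mcmc.iterations,
            burn_in=mcmc.burn_in,
            chains=mcmc.chains,
            seed=_candidate_seed(mcmc.seed, spec.label),
            thin=mcmc.thin,
            fixed_sigma_z_sq=mcmc.fixed_sigma_z_sq,
        )
        start = time.perf_counter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                draws = fit_gibbs(panel, covariates, graph, spec, run_mcmc)
                metrics = evaluate_fit(panel, draws, time.perf_counter() - start)
            row = {
                "spatial_family": spec.spatial_family,
                "temporal_family": spec.temporal_family,
                "interaction_type": spec.interaction_type,
                "status": "ok",
                **asdict(metrics),
            }
            fits.append(metrics)
        except Exception as exc:
            row = {
                "spatial_family": spec.spatial_family,
                "temporal_family": spec.temporal_family,
                "interaction_type": spec.interaction_type,
                "status": f"failed: {exc}",
            }
            fits.append(None)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    best_spec = None
    if len(ok):
        ranked = ok.sort_values(
            by=["waic", "dic", "lpml", "rmse"], ascending=[True, True, False, True]
        )
        best_spec = candidate_specs[int(ranked.index[0])]
    order = table.index if not len(ok) else table.sort_values(
        by=["waic"], ascending=True, na_position="last"
    ).index
    return table.loc[order].reset_index(drop=True), best_spec
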