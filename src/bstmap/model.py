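"""Bayesian hierarchical space-time model for log-normal area-level rates.

The observed age-standardized rate y_it for area i in year t is modelled on
the log scale, z_it = ln y_it, as

    z_it ~ Normal(mu_z_it, sigma_z^2)
    mu_z_it = beta_0 + sum_m (beta_m + b_im) X_itm + u_i + v_i + phi_t + delta_it

with an overall intercept beta_0, global covariate coefficients beta_m with
optional exchangeable area-level deviations b_im (an area-varying, time-
constant coefficient per risk factor), a structured spatial effect u (ICAR on
the contiguity graph), an unstructured spatial effect v, a temporal effect
phi (exchangeable or a random walk of order 1/2), and a space-time
interaction delta whose structure is one of the four Kronecker combinations
of the spatial and temporal factors.

All full conditionals are conjugate (Gaussian for location blocks, inverse
gamma for variances), so the model is fitted by a systematic-scan Gibbs
sampler. Structured blocks are updated in the eigenbasis of their structure
matrix — cheap because the residual precision is homoscedastic once missing
outcome cells are imputed each sweep — and re-centred against their
constraint basis after every update. On the arithmetic scale the expected
rate is exp(mu_z + sigma_z^2/2); the geometric mean is exp(mu_z); a
coefficient beta maps to a 100·(exp(beta) − 1) percent change in the
geometric-mean rate per one (standardized) unit of the risk factor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import CovariatePanel, SpaceTimePanel
from .structures import (
    RANK_TOL,
    AreaGraph,
    PrecisionStructure,
    icar_precision,
    iid_precision,
    interaction_precision,
    rw_precision,
    scale_structure,
)

__all__ = [
    "HyperPriors",
    "ModelSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "fit_gibbs",
    "arithmetic_mean_rate",
    "coefficient_percent_effect",
    "coefficient_significance",
    "posterior_summary",
    "save_draws",
    "load_draws",
]

SPATIAL_FAMILIES = ("none", "iid", "besag", "bym")
TEMPORAL_FAMILIES = ("none", "iid", "rw1", "rw2")
INTERACTION_TYPES = ("none", "I", "II", "III", "IV")


@dataclass(frozen=True)
class HyperPriors:
    """Weakly-informative conjugate hyperpriors.

    Every random-effect variance and the observation variance sigma_z^2 get
    an inverse-gamma(variance_shape, variance_rate) prior; the intercept and
    the global coefficients get zero-mean Gaussians with the stated sds.
    """

    variance_shape: float = 1.0
    variance_rate: float = 0.01
    intercept_sd: float = 100.0
    coefficient_sd: float = 10.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model structure.

    interaction III/IV always take their structured-spatial factor from the
    contiguity graph's ICAR, and II/IV their structured-temporal factor from
    the temporal family's random-walk order, so every member of the
    3 spatial × 3 temporal × 4 interaction candidate grid is a valid model;
    combinations that collapse onto a simpler type (II or IV with an
    exchangeable temporal family) are flagged with a warning.
    """

    covariate_names: tuple[str, ...] = ()
    coefficient_mode: str = "area_varying"  # "global" | "area_varying"
    spatial_family: str = "bym"
    temporal_family: str = "rw2"
    interaction_type: str = "I"
    hyperpriors: HyperPriors = field(default_factory=HyperPriors)

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        if self.spatial_family not in SPATIAL_FAMILIES:
            raise ValueError(f"unknown spatial family {self.spatial_family!r}")
        if self.temporal_family not in TEMPORAL_FAMILIES:
            raise ValueError(f"unknown temporal family {self.temporal_family!r}")
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if self.coefficient_mode not in ("global", "area_varying"):
            raise ValueError(f"unknown coefficient mode {self.coefficient_mode!r}")
        if self.interaction_type in ("II", "IV") and self.temporal_family in ("none", "iid"):
            warnings.warn(
                f"interaction type {self.interaction_type} with temporal family "
                f"{self.temporal_family!r} has no temporal structure to interact with; "
                f"it collapses to type {'I' if self.interaction_type == 'II' else 'III'}",
                stacklevel=2,
            )

    @property
    def label(self) -> str:
        return f"{self.spatial_family}+{self.temporal_family}+{self.interaction_type}"


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 5000
    burn_in: int = 2000
    chains: int = 2
    seed: int = 0
    thin: int = 1
    fixed_sigma_z_sq: float | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 1 or self.thin < 1:
            raise ValueError("chains and thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Posterior draws for every model unknown, concatenated across chains.

    Structured-effect arrays are None when the model omits the component.
    ``variances`` maps component name -> draw vector and always contains
    ``sigma_z_sq``. ``mu_z`` holds the linear predictor per kept draw.
    """

    intercept: np.ndarray  # (n_draws,)
    global_coefficients: np.ndarray  # (n_draws, M)
    local_coefficients: np.ndarray | None  # (n_draws, S, M)
    spatial_structured: np.ndarray | None  # (n_draws, S)
    spatial_unstructured: np.ndarray | None  # (n_draws, S)
    temporal_effect: np.ndarray | None  # (n_draws, T)
    interaction_effect: np.ndarray | None  # (n_draws, S, T)
    variances: dict[str, np.ndarray]
    mu_z: np.ndarray  # (n_draws, S, T)
    meta: dict

    @property
    def n_draws(self) -> int:
        return len(self.intercept)

    @property
    def sigma_z_sq(self) -> np.ndarray:
        return self.variances["sigma_z_sq"]

    def coefficient_draws(self, name: str, area_index: int | None = None) -> np.ndarray:
        """Total coefficient draws beta_m (+ b_im when area_index given)."""
        m = list(self.meta["covariate_names"]).index(name)
        draws = self.global_coefficients[:, m]
        if area_index is not None:
            if self.local_coefficients is None:
                raise ValueError("model has no area-varying coefficients")
            draws = draws + self.local_coefficients[:, area_index, m]
        return draws

    def by_chain(self, array: np.ndarray) -> np.ndarray:
        """Reshape a (n_draws, ...) array to (chains, draws_per_chain, ...)."""
        chains = self.meta["chains"]
        return array.reshape(chains, -1, *array.shape[1:])


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


class _EigenBlock:
    """A structured effect block updated in the eigenbasis of its structure."""

    def __init__(self, structure: PrecisionStructure):
        self.structure = structure
        evals, evecs = structure.eigendecomposition()
        tol = RANK_TOL * max(float(evals.max()), 1.0)
        self.evals = np.where(evals > tol, evals, 0.0)
        self.evecs = evecs
        self.rank = int(np.sum(self.evals > 0))
        self.q = structure.matrix


def _interaction_factors(
    spec: ModelSpec, graph: AreaGraph, T: int
) -> tuple[PrecisionStructure, PrecisionStructure]:
    S = graph.n_areas
    if spec.interaction_type in ("III", "IV"):
        fs = scale_structure(icar_precision(graph))
    else:
        fs = iid_precision(S)
    order = {"rw1": 1, "rw2": 2}.get(spec.temporal_family)
    if spec.interaction_type in ("II", "IV") and order is not None:
        ft = scale_structure(rw_precision(T, order))
    else:
        ft = iid_precision(T)
    return fs, ft


def _prepare_covariates(covariates: CovariatePanel | None, spec: ModelSpec):
    if len(spec.covariate_names) and covariates is None:
        raise ValueError(
            f"model spec names covariates {list(spec.covariate_names)} but no covariate panel given"
        )
    if covariates is None or len(spec.covariate_names) == 0:
        return None, pd.DataFrame(columns=["area_id", "year", "name", "method"])
    cov = covariates.select(list(spec.covariate_names))
    cov, log = cov.imputed()
    cov = cov.standardized()
    return cov, log


def fit_gibbs(
    panel: SpaceTimePanel,
    covariates: CovariatePanel | None,
    graph: AreaGraph | None,
    spec: ModelSpec,
    mcmc: MCMCSettings = MCMCSettings(),
) -> PosteriorDraws:
    """Fit the hierarchical model by conjugate Gibbs sampling.

    Missing outcome cells are treated as unknowns and imputed from their
    Gaussian full conditional each sweep; missing covariate cells are filled
    (forward-fill within area, then area mean) before fitting and the
    imputation log attached to the result's meta. Deterministic given the
    seed, chain count and iteration count.
    """
    S, T = panel.n_areas, panel.n_years
    if S < 2 or T < 3:
        raise ValueError(f"need at least 2 areas and 3 years, got {S} x {T}")
    all_missing = np.flatnonzero(panel.missing_mask.all(axis=1))
    if all_missing.size:
        raise ValueError(f"area {panel.area_ids[all_missing[0]]!r} has no observed rates")
    needs_graph = spec.spatial_family in ("besag", "bym") or spec.interaction_type in ("III", "IV")
    if needs_graph and graph is None:
        raise ValueError(f"model {spec.label} requires a contiguity graph")
    if graph is not None and list(graph.area_ids) != list(panel.area_ids):
        raise ValueError("graph areas do not match panel areas")

    cov, imputation_log = _prepare_covariates(covariates, spec)
    M = 0 if cov is None else len(cov.names)
    if cov is not None:
        if list(cov.area_ids) != list(panel.area_ids) or not np.array_equal(cov.years, panel.years):
            raise ValueError("covariate panel axes do not match rate panel axes")
        X = cov.values  # (S, T, M), complete
    else:
        X = np.zeros((S, T, 0))

    hp = spec.hyperpriors
    obs = ~panel.missing_mask
    z_obs = panel.log_rates

    # precompute eigen blocks
    spatial_block = None
    if spec.spatial_family in ("besag", "bym"):
        spatial_block = _EigenBlock(scale_structure(icar_precision(graph)))
    temporal_block = None
    temporal_order = {"rw1": 1, "rw2": 2}.get(spec.temporal_family)
    if temporal_order is not None:
        temporal_block = _EigenBlock(scale_structure(rw_precision(T, temporal_order)))
    use_v = spec.spatial_family in ("iid", "bym")
    use_phi_iid = spec.temporal_family == "iid"

    inter = spec.interaction_type
    fs_block = ft_block = None
    inter_deficiency = 0
    if inter != "none":
        fs, ft = _interaction_factors(spec, graph if graph is not None else None, T)
        fs_block, ft_block = _EigenBlock(fs), _EigenBlock(ft)
        d_s = fs.size - fs_block.rank
        d_t = ft.size - ft_block.rank
        inter_deficiency = S * T - (S - d_s) * (T - d_t)
        inter_rank = S * T - inter_deficiency
        # per-cell structure eigenvalues in the (spatial, temporal) eigenbasis
        inter_evals = np.outer(fs_block.evals, ft_block.evals) if inter == "IV" else None

    n_keep = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
    total = n_keep * mcmc.chains

    out = {
        "intercept": np.empty(total),
        "global_coefficients": np.empty((total, M)),
        "local_coefficients": (
            np.empty((total, S, M)) if (spec.coefficient_mode == "area_varying" and M) else None
        ),
        "spatial_structured": np.empty((total, S)) if spatial_block is not None else None,
        "spatial_unstructured": np.empty((total, S)) if use_v else None,
        "temporal_effect": (
            np.empty((total, T)) if (temporal_block is not None or use_phi_iid) else None
        ),
        "interaction_effect": np.empty((total, S, T)) if inter != "none" else None,
        "mu_z": np.empty((total, S, T)),
    }
    var_names = ["sigma_z_sq"]
    if spatial_block is not None:
        var_names.append("tau_spatial_sq")
    if use_v:
        var_names.append("tau_unstructured_sq")
    if temporal_block is not None or use_phi_iid:
        var_names.append("tau_temporal_sq")
    if inter != "none":
        var_names.append("tau_interaction_sq")
    if out["local_coefficients"] is not None:
        var_names += [f"tau_b_{name}_sq" for name in spec.covariate_names]
    variances_out = {name: np.empty(total) for name in var_names}

    Xsq_sum = np.sum(X**2, axis=1) if M else None  # (S, M): sum over t of X^2

    for chain in range(mcmc.chains):
        rng = np.random.default_rng([int(mcmc.seed), chain])
        # --- state ---
        z = np.where(obs, z_obs, np.nanmean(z_obs))
        beta0 = float(np.mean(z))
        beta = np.zeros(M)
        b = np.zeros((S, M))
        u = np.zeros(S)
        v = np.zeros(S)
        phi = np.zeros(T)
        delta = np.zeros((S, T))
        tau = {name: 1.0 for name in var_names if name != "sigma_z_sq"}
        sigma_sq = mcmc.fixed_sigma_z_sq if mcmc.fixed_sigma_z_sq is not None else 1.0

        def coef_effect() -> np.ndarray:
            if M == 0:
                return np.zeros((S, T))
            total_coef = beta[None, :] + b  # (S, M)
            return np.einsum("stm,sm->st", X, total_coef)

        fitted = beta0 + coef_effect() + u[:, None] + v[:, None] + phi[None, :] + delta

        kept = 0
        for it in range(mcmc.iterations):
            # impute missing outcome cells
            if panel.n_missing:
                miss = panel.missing_mask
                z[miss] = fitted[miss] + np.sqrt(sigma_sq) * rng.standard_normal(int(miss.sum()))

            # intercept
            resid = z - (fitted - beta0)
            prec = S * T / sigma_sq + 1.0 / hp.intercept_sd**2
            mean = resid.sum() / sigma_sq / prec
            new_beta0 = mean + rng.standard_normal() / np.sqrt(prec)
            fitted += new_beta0 - beta0
            beta0 = new_beta0

            # covariate coefficients
            for m in range(M):
                xm = X[:, :, m]
                contrib = (beta[m] + b[:, m])[:, None] * xm
                resid = z - (fitted - contrib)
                if out["local_coefficients"] is not None:
                    # blocked update: beta_m with the area deviations b
                    # marginalized out (each area's projection c_i/s_i is
                    # N(beta + b_i, sigma^2/s_i), so marginally
                    # N(beta, sigma^2/s_i + tau_b)), then b | beta — the
                    # sum beta + b mixes poorly under one-at-a-time scans
                    tau_b = tau[f"tau_b_{spec.covariate_names[m]}_sq"]
                    s_i = Xsq_sum[:, m]
                    c_i = np.sum(xm * resid, axis=1)
                    lik_prec = 1.0 / (sigma_sq / s_i + tau_b)
                    prec = lik_prec.sum() + 1.0 / hp.coefficient_sd**2
                    mean = np.sum((c_i / s_i) * lik_prec) / prec
                    beta[m] = mean + rng.standard_normal() / np.sqrt(prec)
                    # area deviations given the global slope (vectorized)
                    r = resid - beta[m] * xm
                    prec_i = s_i / sigma_sq + 1.0 / tau_b
                    mean_i = np.sum(xm * r, axis=1) / sigma_sq / prec_i
                    b[:, m] = mean_i + rng.standard_normal(S) / np.sqrt(prec_i)
                else:
                    prec = np.sum(xm**2) / sigma_sq + 1.0 / hp.coefficient_sd**2
                    mean = np.sum(xm * resid) / sigma_sq / prec
                    beta[m] = mean + rng.standard_normal() / np.sqrt(prec)
                new_contrib = (beta[m] + b[:, m])[:, None] * xm
                fitted += new_contrib - contrib

            # structured spatial effect (ICAR)
            if spatial_block is not None:
                resid = z - (fitted - u[:, None])
                canon = spatial_block.evecs.T @ (resid.sum(axis=1) / sigma_sq)
                prec = spatial_block.evals / tau["tau_spatial_sq"] + T / sigma_sq
                coords = canon / prec + rng.standard_normal(S) / np.sqrt(prec)
                new_u = spatial_block.evecs @ coords
                # re-centre: one sum-to-zero constraint per graph component
                basis = spatial_block.structure.constraint_basis
                new_u -= basis @ (basis.T @ new_u)
                fitted += (new_u - u)[:, None]
                u = new_u

            # unstructured spatial effect
            if use_v:
                resid = z - (fitted - v[:, None])
                prec = T / sigma_sq + 1.0 / tau["tau_unstructured_sq"]
                mean = resid.sum(axis=1) / sigma_sq / prec
                new_v = mean + rng.standard_normal(S) / np.sqrt(prec)
                fitted += (new_v - v)[:, None]
                v = new_v

            # temporal effect
            if temporal_block is not None:
                resid = z - (fitted - phi[None, :])
                canon = temporal_block.evecs.T @ (resid.sum(axis=0) / sigma_sq)
                prec = temporal_block.evals / tau["tau_temporal_sq"] + S / sigma_sq
                coords = canon / prec + rng.standard_normal(T) / np.sqrt(prec)
                new_phi = temporal_block.evecs @ coords
                basis = temporal_block.structure.constraint_basis
                new_phi -= basis @ (basis.T @ new_phi)
                fitted += (new_phi - phi)[None, :]
                phi = new_phi
            elif use_phi_iid:
                resid = z - (fitted - phi[None, :])
                prec = S / sigma_sq + 1.0 / tau["tau_temporal_sq"]
                mean = resid.sum(axis=0) / sigma_sq / prec
                new_phi = mean + rng.standard_normal(T) / np.sqrt(prec)
                fitted += (new_phi - phi)[None, :]
                phi = new_phi

            # space-time interaction
            if inter != "none":
                resid = z - (fitted - delta)
                tau_d = tau["tau_interaction_sq"]
                if inter == "I":
                    prec = 1.0 / tau_d + 1.0 / sigma_sq
                    mean = resid / sigma_sq / prec
                    new_delta = mean + rng.standard_normal((S, T)) / np.sqrt(prec)
                else:
                    # rotate the residual into the factor eigenbases
                    canon = fs_block.evecs.T @ (resid / sigma_sq) @ ft_block.evecs
                    if inter == "II":
                        lam = np.broadcast_to(ft_block.evals[None, :], (S, T))
                    elif inter == "III":
                        lam = np.broadcast_to(fs_block.evals[:, None], (S, T))
                    else:
                        lam = inter_evals
                    prec = lam / tau_d + 1.0 / sigma_sq
                    coords = canon / prec + rng.standard_normal((S, T)) / np.sqrt(prec)
                    coords[lam == 0] = 0.0  # exact projection off the null space
                    new_delta = fs_block.evecs @ coords @ ft_block.evecs.T
                fitted += new_delta - delta
                delta = new_delta

            # variances (inverse-gamma conjugate updates)
            a, c = hp.variance_shape, hp.variance_rate
            if spatial_block is not None:
                quad = float(u @ (spatial_block.q @ u))
                tau["tau_spatial_sq"] = 1.0 / rng.gamma(
                    a + spatial_block.rank / 2.0, 1.0 / (c + quad / 2.0)
                )
            if use_v:
                tau["tau_unstructured_sq"] = 1.0 / rng.gamma(
                    a + S / 2.0, 1.0 / (c + float(v @ v) / 2.0)
                )
            if temporal_block is not None:
                quad = float(phi @ (temporal_block.q @ phi))
                tau["tau_temporal_sq"] = 1.0 / rng.gamma(
                    a + temporal_block.rank / 2.0, 1.0 / (c + quad / 2.0)
                )
            elif use_phi_iid:
                tau["tau_temporal_sq"] = 1.0 / rng.gamma(
                    a + T / 2.0, 1.0 / (c + float(phi @ phi) / 2.0)
                )
            if inter != "none":
                if inter == "I":
                    quad = float(np.sum(delta**2))
                else:
                    coords_d = fs_block.evecs.T @ delta @ ft_block.evecs
                    if inter == "II":
                        lam = np.broadcast_to(ft_block.evals[None, :], (S, T))
                    elif inter == "III":
                        lam = np.broadcast_to(fs_block.evals[:, None], (S, T))
                    else:
                        lam = inter_evals
                    quad = float(np.sum(lam * coords_d**2))
                tau["tau_interaction_sq"] = 1.0 / rng.gamma(
                    a + inter_rank / 2.0, 1.0 / (c + quad / 2.0)
                )
            if out["local_coefficients"] is not None:
                for m, name in enumerate(spec.covariate_names):
                    tau[f"tau_b_{name}_sq"] = 1.0 / rng.gamma(
                        a + S / 2.0, 1.0 / (c + float(b[:, m] @ b[:, m]) / 2.0)
                    )
            if mcmc.fixed_sigma_z_sq is None:
                sse = float(np.sum((z - fitted) ** 2))
                sigma_sq = 1.0 / rng.gamma(a + S * T / 2.0, 1.0 / (c + sse / 2.0))

            # store
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                idx = chain * n_keep + kept
                out["intercept"][idx] = beta0
                out["global_coefficients"][idx] = beta
                if out["local_coefficients"] is not None:
                    out["local_coefficients"][idx] = b
                if out["spatial_structured"] is not None:
                    out["spatial_structured"][idx] = u
                if out["spatial_unstructured"] is not None:
                    out["spatial_unstructured"][idx] = v
                if out["temporal_effect"] is not None:
                    out["temporal_effect"][idx] = phi
                if out["interaction_effect"] is not None:
                    out["interaction_effect"][idx] = delta
                out["mu_z"][idx] = fitted
                variances_out["sigma_z_sq"][idx] = sigma_sq
                for name in tau:
                    variances_out[name][idx] = tau[name]
                kept += 1

    meta = {
        "area_ids": list(panel.area_ids),
        "years": [int(y) for y in panel.years],
        "covariate_names": list(spec.covariate_names),
        "coefficient_mode": spec.coefficient_mode,
        "spatial_family": spec.spatial_family,
        "temporal_family": spec.temporal_family,
        "interaction_type": spec.interaction_type,
        "chains": mcmc.chains,
        "iterations": mcmc.iterations,
        "burn_in": mcmc.burn_in,
        "thin": mcmc.thin,
        "seed": int(mcmc.seed),
        "draws_per_chain": n_keep,
        "fixed_sigma_z_sq": mcmc.fixed_sigma_z_sq,
        "standardization_record": {} if cov is None else cov.standardization_record,
        "covariate_imputation": imputation_log.to_dict("records"),
    }
    return PosteriorDraws(variances=variances_out, meta=meta, **out)


# ---------------------------------------------------------------------------
# Posterior functionals
# ---------------------------------------------------------------------------


def arithmetic_mean_rate(mu_z_draws: np.ndarray, sigma_z_sq_draws: np.ndarray) -> np.ndarray:
    """Expected rate per draw: exp(mu_z + sigma_z^2 / 2), the log-normal mean."""
    mu = np.asarray(mu_z_draws, dtype=float)
    sig = np.asarray(sigma_z_sq_draws, dtype=float)
    sig = sig.reshape(sig.shape + (1,) * (mu.ndim - sig.ndim))
    return np.exp(mu + sig / 2.0)


def coefficient_percent_effect(beta_draws: np.ndarray) -> np.ndarray:
    """Percent change in the geometric-mean rate per unit of the risk factor."""
    return 100.0 * (np.exp(np.asarray(beta_draws, dtype=float)) - 1.0)


def coefficient_significance(beta_draws: np.ndarray, level: float = 0.05) -> tuple[bool, int]:
    """Flag a coefficient whose posterior mass is concentrated on one sign.

    Significant iff max(P(beta > 0), P(beta < 0)) exceeds 1 - level/2, i.e.
    the equal-tailed (1 - level) credible interval excludes zero. Returns
    (significant, direction) with direction the sign of the posterior median.
    """
    draws = np.asarray(beta_draws, dtype=float)
    p_pos = float(np.mean(draws > 0))
    p_neg = float(np.mean(draws < 0))
    significant = max(p_pos, p_neg) > 1.0 - level / 2.0
    direction = int(np.sign(np.median(draws)))
    return significant, direction


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Mean/sd/95% interval and split-chain diagnostics for scalar unknowns.

    R-hat and effective sample size come from arviz; R-hat is omitted (with a
    warning) for single-chain runs, and any R-hat above 1.1 is flagged.
    """
    import arviz as az

    unknowns: dict[str, np.ndarray] = {"intercept": draws.intercept}
    for m, name in enumerate(draws.meta["covariate_names"]):
        unknowns[f"beta_{name}"] = draws.global_coefficients[:, m]
    for name, vec in draws.variances.items():
        unknowns[name] = vec

    single_chain = draws.meta["chains"] < 2
    if single_chain:
        warnings.warn("single chain: R-hat omitted", stacklevel=2)
    rows = []
    for name, vec in unknowns.items():
        by_chain = draws.by_chain(vec)
        ess = float(az.ess(az.convert_to_dataset(by_chain)).x)
        rhat = None if single_chain else float(az.rhat(az.convert_to_dataset(by_chain)).x)
        rows.append(
            {
                "unknown": name,
                "mean": float(vec.mean()),
                "sd": float(vec.std()),
                "ci_2.5%": float(np.quantile(vec, 0.025)),
                "ci_97.5%": float(np.quantile(vec, 0.975)),
                "ess": ess,
                "rhat": rhat,
            }
        )
    table = pd.DataFrame(rows)
    flagged = (
        table[table["rhat"].notna() & (table["rhat"] > 1.1)]
        if not single_chain
        else table.iloc[0:0]
    )
    if len(flagged):
        warnings.warn(
            f"R-hat > 1.1 for: {', '.join(flagged['unknown'])}", stacklevel=2
        )
    return table


# ---------------------------------------------------------------------------
# Persistence: flat binary arrays + JSON manifest
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = [
    "intercept",
    "global_coefficients",
    "local_coefficients",
    "spatial_structured",
    "spatial_unstructured",
    "temporal_effect",
    "interaction_effect",
    "mu_z",
]


def save_draws(draws: PosteriorDraws, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"meta": draws.meta, "arrays": {}, "variances": []}
    for name in _ARRAY_FIELDS:
        arr = getattr(draws, name)
        if arr is not None:
            np.save(directory / f"{name}.npy", arr)
            manifest["arrays"][name] = {"shape": list(arr.shape), "dtype": str(arr.dtype)}
    for name, vec in draws.variances.items():
        np.save(directory / f"variance_{name}.npy", vec)
        manifest["variances"].append(name)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_draws(directory) -> PosteriorDraws:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    kwargs = {
        name: (np.load(directory / f"{name}.npy") if name in manifest["arrays"] else None)
        for name in _ARRAY_FIELDS
    }
    variances = {
        name: np.load(directory / f"variance_{name}.npy") for name in manifest["variances"]
    }
    return PosteriorDraws(variances=variances, meta=manifest["meta"], **kwargs)
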