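"""Ground-truth-annotated synthetic panels with the model's assumed structure.

The generator emulates a WHO-style extract — ~183 areas in 5 regions, 20
yearly time points, log-normal age-standardized rates around 10–13 per
100,000 — built from a known intercept (default ln 12), area-varying
covariate effects, BYM spatial effects, random-walk temporal effects, a
chosen space-time interaction, and i.i.d. log-scale noise. Every draw is
reproducible bit-for-bit from its seed, and the truth record retains every
component (including the noise), so z can be reconstructed exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely import voronoi_polygons
from shapely.geometry import MultiPoint, Point, box, mapping

from .model import ModelSpec
from .panels import CovariatePanel, SpaceTimePanel
from .structures import (
    AreaGraph,
    icar_precision,
    iid_precision,
    rw_precision,
    sample_structured_effect,
    scale_structure,
)

__all__ = [
    "DEFAULT_COVARIATE_NAMES",
    "SyntheticTruth",
    "generate_area_graph",
    "simulate_panel",
    "make_hotspot_scenario",
    "export_dataset",
]

#: the ten risk factors retained in the association analysis
DEFAULT_COVARIATE_NAMES = (
    "ncd_mortality_rate",
    "che_pct_gdp",
    "gghe_d_pct_che",
    "gghe_d_pct_gge",
    "pvt_d_per_capita",
    "ext_per_capita",
    "people_living_with_hiv",
    "road_traffic_deaths",
    "basic_drinking_water_pct",
    "tb_incidence",
)

REGIONS = ("Africa", "Americas", "Asia", "Europe", "Oceania")

DEFAULT_VARIANCES = {
    "spatial": 0.10,
    "unstructured": 0.05,
    "temporal": 0.05,
    "interaction": 0.02,
    "local_coefficients": 0.01,
}


@dataclass
class SyntheticTruth:
    """Everything needed to reconstruct the generated log-rate surface."""

    spec: ModelSpec
    intercept: float
    global_coefficients: np.ndarray  # (M,)
    local_coefficients: np.ndarray | None  # (S, M)
    effect_vectors: dict[str, np.ndarray]  # component name -> vector/grid (incl. noise)
    variances: dict[str, float]
    sigma_z_sq: float
    seed: int
    intended_hotspots: list[str] = field(default_factory=list)

    def reconstruct_z(self, covariates: CovariatePanel | None) -> np.ndarray:
        """Rebuild the z grid exactly from the stored components."""
        eff = self.effect_vectors
        S = len(eff["noise"])
        z = np.full_like(eff["noise"], self.intercept)
        if covariates is not None and len(self.global_coefficients):
            coef = np.broadcast_to(
                self.global_coefficients[None, :], (S, len(self.global_coefficients))
            )
            if self.local_coefficients is not None:
                coef = coef + self.local_coefficients
            z = z + np.einsum("stm,sm->st", covariates.values, coef)
        for name in ("spatial_structured", "spatial_unstructured"):
            if name in eff:
                z = z + eff[name][:, None]
        if "temporal" in eff:
            z = z + eff["temporal"][None, :]
        if "interaction" in eff:
            z = z + eff["interaction"]
        if "elevation" in eff:
            z = z + eff["elevation"]
        return z + eff["noise"]

    def to_json(self, path) -> None:
        payload = {
            "spec": {
                "covariate_names": list(self.spec.covariate_names),
                "coefficient_mode": self.spec.coefficient_mode,
                "spatial_family": self.spec.spatial_family,
                "temporal_family": self.spec.temporal_family,
                "interaction_type": self.spec.interaction_type,
            },
            "intercept": self.intercept,
            "global_coefficients": self.global_coefficients.tolist(),
            "local_coefficients": (
                None if self.local_coefficients is None else self.local_coefficients.tolist()
            ),
            "effect_vectors": {k: v.tolist() for k, v in self.effect_vectors.items()},
            "variances": self.variances,
            "sigma_z_sq": self.sigma_z_sq,
            "seed": self.seed,
            "intended_hotspots": self.intended_hotspots,
        }
        Path(path).write_text(json.dumps(payload))


def _area_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"A{idx:0{width}d}" for idx in range(n)]


def _region_map(area_ids: list[str]) -> dict[str, str]:
    n = len(area_ids)
    return {aid: REGIONS[min(i * len(REGIONS) // n, len(REGIONS) - 1)] for i, aid in enumerate(area_ids)}


def generate_area_graph(
    n_areas: int, layout: str = "grid", seed: int = 0
) -> tuple[AreaGraph, dict[str, dict]]:
    """A contiguity graph plus matching GeoJSON-style polygons.

    ``grid`` tiles a near-square lattice of unit squares with queen
    contiguity (corner contact counts); ``random_planar`` builds Voronoi
    cells of seeded uniform points in the unit square, with adjacency from
    shared cell boundaries.
    """
    if n_areas < 2:
        raise ValueError("need at least 2 areas")
    ids = _area_ids(n_areas)
    polygons: dict[str, dict] = {}
    edges: set[frozenset[str]] = set()
    if layout == "grid":
        ncols = math.ceil(math.sqrt(n_areas))
        cells = {}
        for idx, aid in enumerate(ids):
            r, c = divmod(idx, ncols)
            cells[aid] = (r, c)
            polygons[aid] = mapping(box(c, -r - 1, c + 1, -r))
        pos = {rc: aid for aid, rc in cells.items()}
        for aid, (r, c) in cells.items():
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    other = pos.get((r + dr, c + dc))
                    if other is not None:
                        edges.add(frozenset((aid, other)))
    elif layout == "random_planar":
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0.0, 1.0, size=(n_areas, 2))
        envelope = box(-0.05, -0.05, 1.05, 1.05)
        cells = voronoi_polygons(MultiPoint([Point(p) for p in pts]), extend_to=envelope)
        matched: dict[str, object] = {}
        for cell in cells.geoms:
            clipped = cell.intersection(envelope)
            for k, p in enumerate(pts):
                if clipped.covers(Point(p)):
                    matched[ids[k]] = clipped
                    break
        if len(matched) != n_areas:
            raise RuntimeError("failed to match every Voronoi cell to its seed point")
        for aid, geom in matched.items():
            polygons[aid] = mapping(geom)
        for i in range(n_areas):
            for j in range(i + 1, n_areas):
                if matched[ids[i]].intersects(matched[ids[j]]):
                    edges.add(frozenset((ids[i], ids[j])))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return AreaGraph(area_ids=ids, edges=edges), polygons


def _draw_covariates(
    rng: np.random.Generator,
    area_ids: list[str],
    years: np.ndarray,
    names: tuple[str, ...],
    correlation: np.ndarray | None,
) -> CovariatePanel:
    S, T, M = len(area_ids), len(years), len(names)
    X = rng.standard_normal((S, T, M))
    if correlation is not None:
        chol = np.linalg.cholesky(np.asarray(correlation, dtype=float))
        X = np.einsum("stm,km->stk", X, chol)
    # exact empirical standardization keeps the stated effect sizes on the
    # same scale the model fits on (covariates are standardized before fitting)
    X = (X - X.mean(axis=(0, 1))) / X.std(axis=(0, 1))
    return CovariatePanel(area_ids=list(area_ids), years=years, names=list(names), values=X)


def simulate_panel(
    graph: AreaGraph,
    n_years: int = 20,
    spec: ModelSpec | None = None,
    effect_sizes: np.ndarray | None = None,
    variances: dict[str, float] | None = None,
    sigma_z_sq: float = 0.05,
    baseline_log_rate: float = math.log(12.0),
    missing_fraction: float = 0.0,
    seed: int = 0,
    covariate_correlation: np.ndarray | None = None,
) -> tuple[SpaceTimePanel, CovariatePanel | None, SyntheticTruth]:
    """Simulate a rate panel plus covariates from the hierarchical model.

    Covariates are i.i.d. standard Normal per area-year (optionally given a
    correlation matrix across covariates); structured random effects are
    drawn from their intrinsic Gaussians orthogonal to the constraint basis;
    z = beta0 + sum_m (beta_m + b_im) X + u + v + phi + delta + eps and
    y = exp(z). Years run 2000 … 2000 + n_years − 1.
    """
    if spec is None:
        spec = ModelSpec(covariate_names=DEFAULT_COVARIATE_NAMES)
    var = dict(DEFAULT_VARIANCES)
    var.update(variances or {})
    S = graph.n_areas
    T = n_years
    years = np.arange(2000, 2000 + T)
    M = len(spec.covariate_names)
    if effect_sizes is None:
        effect_sizes = np.array([0.05 * (-1) ** m for m in range(M)])
    effect_sizes = np.asarray(effect_sizes, dtype=float)
    if effect_sizes.shape != (M,):
        raise ValueError(f"effect_sizes must have length {M}, got {effect_sizes.shape}")

    rng = np.random.default_rng(seed)
    covariates = (
        _draw_covariates(rng, graph.area_ids, years, spec.covariate_names, covariate_correlation)
        if M
        else None
    )
    local = None
    if M and spec.coefficient_mode == "area_varying":
        local = rng.standard_normal((S, M)) * math.sqrt(var["local_coefficients"])

    effects: dict[str, np.ndarray] = {}
    z = np.full((S, T), baseline_log_rate)
    if M:
        coef = effect_sizes[None, :] + (local if local is not None else 0.0)
        z = z + np.einsum("stm,sm->st", covariates.values, np.broadcast_to(coef, (S, M)))
    if spec.spatial_family in ("besag", "bym"):
        u = sample_structured_effect(scale_structure(icar_precision(graph)), var["spatial"], rng)
        effects["spatial_structured"] = u
        z = z + u[:, None]
    if spec.spatial_family in ("iid", "bym"):
        v = rng.standard_normal(S) * math.sqrt(var["unstructured"])
        effects["spatial_unstructured"] = v
        z = z + v[:, None]
    if spec.temporal_family in ("rw1", "rw2"):
        order = 1 if spec.temporal_family == "rw1" else 2
        phi = sample_structured_effect(scale_structure(rw_precision(T, order)), var["temporal"], rng)
        effects["temporal"] = phi
        z = z + phi[None, :]
    elif spec.temporal_family == "iid":
        phi = rng.standard_normal(T) * math.sqrt(var["temporal"])
        effects["temporal"] = phi
        z = z + phi[None, :]
    if spec.interaction_type != "none":
        from .model import _interaction_factors

        fs, ft = _interaction_factors(spec, graph, T)
        from .structures import interaction_precision

        structure = interaction_precision(fs, ft, spec.interaction_type)
        delta = sample_structured_effect(structure, var["interaction"], rng).reshape(S, T)
        effects["interaction"] = delta
        z = z + delta
    noise = (
        rng.standard_normal((S, T)) * math.sqrt(sigma_z_sq) if sigma_z_sq > 0 else np.zeros((S, T))
    )
    effects["noise"] = noise
    z = z + noise

    rates = np.exp(z)
    if missing_fraction > 0:
        mask = rng.uniform(size=(S, T)) < missing_fraction
        rates = np.where(mask, np.nan, rates)
    panel = SpaceTimePanel.from_rates(
        graph.area_ids, years, rates, regions=_region_map(graph.area_ids)
    )
    truth = SyntheticTruth(
        spec=spec,
        intercept=baseline_log_rate,
        global_coefficients=effect_sizes,
        local_coefficients=local,
        effect_vectors=effects,
        variances=var,
        sigma_z_sq=sigma_z_sq,
        seed=int(seed),
    )
    return panel, covariates, truth


def make_hotspot_scenario(
    graph: AreaGraph,
    n_years: int = 10,
    elevated_areas: list[str] = (),
    elevation_factor: float = 3.0,
    seed: int = 0,
    sigma_z_sq: float = 0.05,
) -> tuple[SpaceTimePanel, SyntheticTruth]:
    """A panel with a known set of elevated areas and a near-flat baseline.

    The listed areas' true mean rates are multiplied by ``elevation_factor``
    in every year (an additive ln-factor shift on the log scale); the truth
    records the intended hotspot set (empty when the factor is 1). Baseline
    between-area variation is kept well below the posterior resolution
    sqrt(sigma_z_sq / n_years), so the intended set is the unique set of
    areas genuinely above the yearly medians.
    """
    if not len(elevated_areas):
        raise ValueError("elevated_areas must be nonempty")
    unknown = [a for a in elevated_areas if a not in graph.area_ids]
    if unknown:
        raise ValueError(f"unknown area id(s): {unknown}")
    spec = ModelSpec(
        covariate_names=(),
        spatial_family="iid",
        temporal_family="rw1",
        interaction_type="none",
    )
    panel, _, truth = simulate_panel(
        graph,
        n_years=n_years,
        spec=spec,
        variances={"unstructured": 0.005, "temporal": 0.005},
        sigma_z_sq=sigma_z_sq,
        seed=seed,
    )
    shift = np.zeros((graph.n_areas, n_years))
    idx = [graph.area_ids.index(a) for a in elevated_areas]
    shift[idx, :] = math.log(elevation_factor)
    truth.effect_vectors["elevation"] = shift
    truth.intended_hotspots = list(elevated_areas) if elevation_factor != 1.0 else []
    rates = np.where(panel.missing_mask, np.nan, panel.rates * np.exp(shift))
    panel = SpaceTimePanel.from_rates(
        panel.area_ids, panel.years, rates, regions=panel.regions, stratum=panel.stratum
    )
    return panel, truth


def export_dataset(
    directory,
    panel: SpaceTimePanel,
    covariates: CovariatePanel | None,
    graph: AreaGraph,
    polygons: dict[str, dict] | None,
    truth: SyntheticTruth | None,
) -> dict[str, str]:
    """Write the generated inputs in the pipeline's external formats.

    Returns a map of logical name -> written path (rates CSV, covariates
    CSV, neighbor list, GeoJSON boundaries, truth JSON).
    """
    from . import io as io_formats

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    io_formats.write_rate_panel(panel, directory / "rates.csv")
    written["rates"] = str(directory / "rates.csv")
    if covariates is not None:
        io_formats.write_covariate_panel(covariates, directory / "covariates.csv")
        written["covariates"] = str(directory / "covariates.csv")
    io_formats.write_adjacency(graph, directory / "adjacency.txt")
    written["adjacency"] = str(directory / "adjacency.txt")
    if polygons is not None:
        features = [
            {"type": "Feature", "geometry": geom, "properties": {"area_id": aid}}
            for aid, geom in polygons.items()
        ]
        (directory / "boundaries.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )
        written["boundaries"] = str(directory / "boundaries.geojson")
    if truth is not None:
        truth.to_json(directory / "truth.json")
        written["truth"] = str(directory / "truth.json")
    return written
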