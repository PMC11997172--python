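"""Config-driven orchestration: load → describe → screen → select → fit → hotspots.

A run reads its inputs (rate/covariate/adjacency files, or a synthetic
preset), writes each stage's tables under one output directory, and records
a manifest with the config, seed, per-stage runtimes and a checksum of every
output. Fully deterministic given the seed; a stage failure keeps the
partial outputs and marks the failing stage in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_formats
from .hotspots import detect_hotspots, hotspot_geojson
from .model import (
    MCMCSettings,
    ModelSpec,
    coefficient_percent_effect,
    coefficient_significance,
    fit_gibbs,
    posterior_summary,
)
from .selection import screen_covariates, two_step_select, candidate_grid
from .synthetic import export_dataset, generate_area_graph, simulate_panel
from .trends import top_k_mean_rates, yearly_group_means

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_STRATUM_SPECS", "parse_spec_label"]

#: structures selected for each stratum in the source analysis:
#: convolution (BYM) + RW2 + interaction I for combined sexes and females,
#: Besag + RW2 + interaction I for males.
DEFAULT_STRATUM_SPECS = {
    "both": ("bym", "rw2", "I"),
    "female": ("bym", "rw2", "I"),
    "male": ("besag", "rw2", "I"),
}

SYNTHETIC_PRESETS = {
    "small": {"n_areas": 20, "n_years": 8},
    "study": {"n_areas": 183, "n_years": 20},
}


def parse_spec_label(label: str, covariate_names=(), coefficient_mode="area_varying") -> ModelSpec:
    """Parse a "spatial+temporal+interaction" label (e.g. "bym+rw2+I")."""
    try:
        spatial, temporal, interaction = label.split("+")
    except ValueError as exc:
        raise ValueError(f"bad spec label {label!r}; expected spatial+temporal+interaction") from exc
    return ModelSpec(
        covariate_names=tuple(covariate_names),
        coefficient_mode=coefficient_mode,
        spatial_family=spatial,
        temporal_family=temporal,
        interaction_type=interaction,
    )


@dataclass
class RunConfig:
    rates_path: str | None = None
    covariates_path: str | None = None
    adjacency_path: str | None = None
    geojson_path: str | None = None
    synthetic_preset: str | None = None  # "small" | "study"
    stratum: str = "both"
    screening_threshold: float = 0.7
    candidates: str | list[str] = "all36"
    mcmc_iterations: int = 2000
    mcmc_burn_in: int = 800
    mcmc_chains: int = 2
    alpha: float = 0.05
    output_dir: str = "bstmap_run"
    seed: int = 0
    top_k: int = 10
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_files = self.rates_path is not None
        has_preset = self.synthetic_preset is not None
        if has_files == has_preset:
            raise ValueError("set exactly one of rates_path or synthetic_preset")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    mcmc = MCMCSettings(
        iterations=config.mcmc_iterations,
        burn_in=config.mcmc_burn_in,
        chains=config.mcmc_chains,
        seed=config.seed,
    )

    def record(stage: str, start: float) -> None:
        manifest["stages"][stage] = {"runtime_seconds": time.perf_counter() - start}

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        start = time.perf_counter()
        polygons = None
        if config.synthetic_preset is not None:
            preset = SYNTHETIC_PRESETS[config.synthetic_preset]
            graph, polygons = generate_area_graph(preset["n_areas"], seed=config.seed)
            panel, covariates, truth = simulate_panel(
                graph, n_years=preset["n_years"], seed=config.seed
            )
            export_dataset(out / "inputs", panel, covariates, graph, polygons, truth)
        else:
            panel = io_formats.read_rate_panel(config.rates_path, stratum=config.stratum)
            covariates = (
                io_formats.read_covariate_panel(config.covariates_path, like=panel)
                if config.covariates_path
                else None
            )
            if config.adjacency_path:
                graph = io_formats.read_adjacency(config.adjacency_path)
            elif config.geojson_path:
                graph = io_formats.polygons_to_adjacency(config.geojson_path)
            else:
                raise ValueError("an adjacency or GeoJSON boundary file is required")
        record(stage, start)

        stage = "describe"
        start = time.perf_counter()
        groupings = ["global"] + (["region"] if panel.regions else [])
        trend_frames = []
        for grouping in groupings:
            for summary in yearly_group_means(panel, grouping):
                frame = summary.to_frame()
                frame["percent_change"] = summary.percent_change
                trend_frames.append(frame)
        pd.concat(trend_frames).to_csv(out / "trends.csv", index=False)
        register("trends", out / "trends.csv")
        top_k_mean_rates(panel, min(config.top_k, panel.n_areas)).to_csv(
            out / "top_areas.csv", index=False
        )
        register("top_areas", out / "top_areas.csv")
        record(stage, start)

        stage = "screen"
        start = time.perf_counter()
        retained = ()
        if covariates is not None:
            report = screen_covariates(covariates, panel, config.screening_threshold)
            report.to_frame().to_csv(out / "screening.csv", index=False)
            register("screening", out / "screening.csv")
            (out / "screening.json").write_text(
                json.dumps(
                    {
                        "correlation_with_outcome": report.correlation_with_outcome,
                        "pruned_pairs": report.pruned_pairs,
                        "retained": report.retained_names,
                    }
                )
            )
            register("screening_json", out / "screening.json")
            retained = tuple(report.retained_names)
        record(stage, start)

        stage = "select"
        start = time.perf_counter()
        if config.candidates == "all36":
            specs = candidate_grid(covariate_names=retained)
        else:
            specs = [parse_spec_label(lbl, covariate_names=retained) for lbl in config.candidates]
        screened_cov = covariates.select(list(retained)) if retained else None
        table, best_spec = two_step_select(panel, screened_cov, graph, specs, mcmc)
        # wall time lives in the manifest's stage timings; dropping it here
        # keeps reruns with the same seed byte-identical
        table.drop(columns=["runtime_seconds"], errors="ignore").to_csv(
            out / "model_comparison.csv", index=False
        )
        register("model_comparison", out / "model_comparison.csv")
        if best_spec is None:
            raise RuntimeError("every candidate fit failed")
        record(stage, start)

        stage = "fit"
        start = time.perf_counter()
        draws = fit_gibbs(panel, screened_cov, graph, best_spec, mcmc)
        posterior_summary(draws).to_csv(out / "posterior_summary.csv", index=False)
        register("posterior_summary", out / "posterior_summary.csv")
        rows = []
        for name in best_spec.covariate_names:
            for i, aid in enumerate(panel.area_ids):
                beta = draws.coefficient_draws(
                    name, i if draws.local_coefficients is not None else None
                )
                significant, direction = coefficient_significance(beta, level=config.alpha)
                pct = coefficient_percent_effect(beta)
                rows.append(
                    {
                        "covariate": name,
                        "area_id": aid,
                        "posterior_median": float(np.median(beta)),
                        "percent_effect_median": float(np.median(pct)),
                        "significant": significant,
                        "direction": direction,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "coefficient_significance.csv", index=False)
        register("coefficient_significance", out / "coefficient_significance.csv")
        record(stage, start)

        stage = "hotspots"
        start = time.perf_counter()
        result = detect_hotspots(panel, draws.mu_z, alpha=config.alpha)
        result.to_frame().to_csv(out / "hotspots.csv", index=False)
        register("hotspots", out / "hotspots.csv")
        if polygons is not None:
            hotspot_geojson(result, polygons, out / "hotspots.geojson")
            register("hotspots_geojson", out / "hotspots.geojson")
        record(stage, start)

        manifest["status"] = "ok"
        manifest["best_model"] = None if best_spec is None else best_spec.label
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
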