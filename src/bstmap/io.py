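"""Readers and writers for every external format the pipeline touches.

Rate and covariate panels travel as comma-separated UTF-8 text with a header
(the layout of WHO Global Health Observatory exports); the contiguity graph
as a colon-delimited neighbor list; boundaries as GeoJSON FeatureCollections,
from which queen contiguity (any shared boundary point makes two areas
neighbors) is derived.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape
from shapely.strtree import STRtree

from .panels import CovariatePanel, SpaceTimePanel
from .structures import AreaGraph

__all__ = [
    "read_rate_panel",
    "write_rate_panel",
    "read_covariate_panel",
    "write_covariate_panel",
    "read_adjacency",
    "write_adjacency",
    "polygons_to_adjacency",
]

RATE_COLUMNS = ["area_id", "region", "year", "stratum", "rate"]
COVARIATE_COLUMNS = ["area_id", "year", "name", "value"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header lacks required column(s) {missing}")
    return df


def read_rate_panel(path, stratum: str = "both") -> SpaceTimePanel:
    """Read a long-format rate file and return the dense panel for one stratum.

    The area and year axes are derived from the whole file (all strata), so
    panels for different strata of the same file share identical axes. Cells
    absent from the file, and zero rates (whose log is undefined), are flagged
    missing.
    """
    df = _read_csv(path, RATE_COLUMNS)
    strata = sorted(df["stratum"].unique())
    if stratum not in strata:
        raise ValueError(f"{path}: stratum {stratum!r} not present (has {strata})")
    # validate rates with line numbers (header = line 1)
    rates = pd.to_numeric(df["rate"], errors="coerce")
    bad = ~np.isfinite(rates)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: non-numeric rate {df['rate'].iloc[line - 2]!r} at line {line}")
    years_num = pd.to_numeric(df["year"], errors="coerce")
    if years_num.isna().any():
        line = int(np.flatnonzero(years_num.isna().to_numpy())[0]) + 2
        raise ValueError(f"{path}: non-integer year at line {line}")
    # to_numeric only validates; float() parses with correct rounding
    df = df.assign(rate=df["rate"].map(float), year=years_num.astype(int))
    if (df["rate"] < 0).any():
        row = df[df["rate"] < 0].iloc[0]
        raise ValueError(f"{path}: negative rate for ({row['area_id']}, {row['year']})")

    dup = df.duplicated(subset=["area_id", "year", "stratum"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for key "
            f"(area_id={row['area_id']!r}, year={row['year']}, stratum={row['stratum']!r})"
        )

    area_ids = sorted(df["area_id"].unique())
    years = np.arange(df["year"].min(), df["year"].max() + 1)
    regions = (
        df[df["region"] != ""]
        .drop_duplicates("area_id")
        .set_index("area_id")["region"]
        .to_dict()
    )

    sub = df[df["stratum"] == stratum]
    grid = np.full((len(area_ids), len(years)), np.nan)
    a_index = {a: i for i, a in enumerate(area_ids)}
    y_index = {int(y): j for j, y in enumerate(years)}
    for _, row in sub.iterrows():
        grid[a_index[row["area_id"]], y_index[int(row["year"])]] = row["rate"]
    return SpaceTimePanel.from_rates(area_ids, years, grid, regions=regions, stratum=stratum)


def write_rate_panel(panel: SpaceTimePanel, path) -> None:
    """Write observed cells of a panel as long-format CSV (one stratum)."""
    panel.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_covariate_panel(
    path, names: list[str] | None = None, like: SpaceTimePanel | None = None
) -> CovariatePanel:
    """Read a long-format covariate file into an area × year × covariate array.

    When ``like`` is given, the output is aligned to that panel's area/year
    axes; otherwise axes are derived from the file. A requested name entirely
    absent from the file is a hard error listing what is available.
    """
    df = _read_csv(path, COVARIATE_COLUMNS)
    df = df.assign(
        value=df["value"].map(lambda s: float(s) if s != "" else np.nan),
        year=pd.to_numeric(df["year"], errors="coerce").astype(int),
    )
    dup = df.duplicated(subset=["area_id", "year", "name"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate covariate record "
            f"(area_id={row['area_id']!r}, year={row['year']}, name={row['name']!r})"
        )
    available = sorted(df["name"].unique())
    if names is None:
        names = available
    absent = [n for n in names if n not in available]
    if absent:
        raise ValueError(f"{path}: covariate(s) {absent} absent; available: {available}")

    if like is not None:
        area_ids, years = list(like.area_ids), like.years
    else:
        area_ids = sorted(df["area_id"].unique())
        years = np.arange(df["year"].min(), df["year"].max() + 1)
    values = np.full((len(area_ids), len(years), len(names)), np.nan)
    a_index = {a: i for i, a in enumerate(area_ids)}
    y_index = {int(y): j for j, y in enumerate(years)}
    for _, row in df[df["name"].isin(names)].iterrows():
        if row["area_id"] in a_index and int(row["year"]) in y_index:
            m = names.index(row["name"])
            values[a_index[row["area_id"]], y_index[int(row["year"])], m] = row["value"]
    return CovariatePanel(area_ids=area_ids, years=years, names=list(names), values=values)


def write_covariate_panel(covariates: CovariatePanel, path) -> None:
    covariates.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_adjacency(path) -> AreaGraph:
    """Read a colon-delimited neighbor list ("area: n1 n2 ...") into a graph.

    A neighbor token that never appears as a line key is a hard error; an
    asymmetric listing is symmetrized with a warning; self-neighbors are
    rejected.
    """
    neighbor_map: dict[str, list[str]] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        area, _, rest = line.partition(":")
        area = area.strip()
        if area in neighbor_map:
            raise ValueError(f"{path}: duplicate area line {area!r}")
        neighbor_map[area] = rest.split()
    area_ids = sorted(neighbor_map)
    known = set(area_ids)
    edges: set[frozenset[str]] = set()
    asymmetric = []
    for area, neighbors in neighbor_map.items():
        for nb in neighbors:
            if nb == area:
                raise ValueError(f"{path}: {area!r} lists itself as a neighbor")
            if nb not in known:
                raise ValueError(f"{path}: unknown neighbor token {nb!r} under {area!r}")
            if area not in neighbor_map[nb]:
                asymmetric.append((area, nb))
            edges.add(frozenset((area, nb)))
    if asymmetric:
        warnings.warn(
            f"{path}: {len(asymmetric)} asymmetric listing(s) symmetrized "
            f"(first: {asymmetric[0]})",
            stacklevel=2,
        )
    return AreaGraph(area_ids=area_ids, edges=edges)


def write_adjacency(graph: AreaGraph, path) -> None:
    """Write the neighbor-list file; symmetry is enforced by construction."""
    neighbor_map: dict[str, list[str]] = {a: [] for a in graph.area_ids}
    for e in graph.edges:
        a, b = tuple(e)
        neighbor_map[a].append(b)
        neighbor_map[b].append(a)
    lines = [f"{a}: {' '.join(sorted(neighbor_map[a]))}".rstrip() for a in graph.area_ids]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def polygons_to_adjacency(geojson_path, id_property: str = "area_id") -> AreaGraph:
    """Derive queen contiguity from a GeoJSON FeatureCollection.

    Two areas are neighbors when their polygons share at least one boundary
    point. Invalid geometries are skipped with a warning and become isolated
    nodes only if absent entirely; duplicate area ids are a hard error.
    """
    with open(geojson_path, encoding="utf-8") as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise ValueError(f"{geojson_path}: not a GeoJSON FeatureCollection")
    geoms, ids = [], []
    seen = set()
    for feature in collection.get("features", []):
        props = feature.get("properties") or {}
        aid = props.get(id_property)
        if aid is None:
            raise ValueError(f"{geojson_path}: feature lacks property {id_property!r}")
        if aid in seen:
            raise ValueError(f"{geojson_path}: duplicate area id {aid!r}")
        seen.add(aid)
        try:
            geom = shape(feature["geometry"])
            if not geom.is_valid:
                raise ValueError("invalid geometry")
        except Exception as exc:  # malformed feature: keep the node, drop the shape
            warnings.warn(f"{geojson_path}: skipping geometry of {aid!r} ({exc})", stacklevel=2)
            geom = None
        ids.append(str(aid))
        geoms.append(geom)

    valid = [(i, g) for i, g in enumerate(geoms) if g is not None]
    edges: set[frozenset[str]] = set()
    if valid:
        tree = STRtree([g for _, g in valid])
        positions = [i for i, _ in valid]
        for k, (i, g) in enumerate(valid):
            for j in tree.query(g, predicate="intersects"):
                other = positions[int(j)]
                if other != i:
                    edges.add(frozenset((ids[i], ids[other])))
    return AreaGraph(area_ids=sorted(ids), edges=edges)
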