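"""Areal study regions: data model, distances, neighbourhoods and file I/O.

A *region* is one areal unit (typically a county) carrying a centroid,
an adult population denominator, a disease count, and optional region-level
covariates expressed as percentages of the population.  A *study area* is an
ordered collection of regions over which scan statistics operate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "StudyArea",
    "NeighborStructure",
    "load_region_table",
    "write_region_table",
    "load_geojson",
    "distance_matrix",
    "k_nearest",
]

#: Mean Earth radius in kilometres, used for great-circle distances.
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Region:
    """One areal unit.

    Parameters
    ----------
    id : str
        Unique identifier (e.g. a FIPS code).
    name : str
        Human-readable name.
    x, y : float
        Centroid coordinates.  Interpreted as planar units or as
        longitude/latitude degrees depending on the study area's
        ``coordinate_mode``.
    population : int
        Adult population denominator N_i (> 0).
    cases : int
        Observed case count c_i, 0 <= c_i <= N_i.
    covariates : mapping of str to float
        Region-level covariate values (percent of population).
    """

    id: str
    name: str
    x: float
    y: float
    population: int
    cases: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"region {self.id!r}: population must be positive")
        if not 0 <= self.cases <= self.population:
            raise ValueError(
                f"region {self.id!r}: cases ({self.cases}) must lie in "
                f"[0, population={self.population}]"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"region {self.id!r}: non-finite centroid")
        for k, v in self.covariates.items():
            if not math.isfinite(v):
                raise ValueError(f"region {self.id!r}: covariate {k!r} not finite")


class StudyArea:
    """An ordered collection of regions with study-wide aggregates.

    Attributes
    ----------
    regions : list of Region
    total_cases : int
        C = sum of region cases.
    total_population : int
        N = sum of region populations.
    coordinate_mode : {"planar", "spherical"}
        How centroid coordinates are interpreted; "spherical" treats
        (x, y) as (longitude, latitude) in degrees.
    """

    def __init__(
        self,
        regions: Iterable[Region],
        coordinate_mode: str = "planar",
        geometry: Sequence[dict] | None = None,
    ):
        self.regions: list[Region] = list(regions)
        if len(self.regions) < 2:
            raise ValueError("a study area needs at least 2 regions")
        if coordinate_mode not in ("planar", "spherical"):
            raise ValueError(f"unknown coordinate_mode {coordinate_mode!r}")
        self.coordinate_mode = coordinate_mode
        ids = [r.id for r in self.regions]
        seen: set[str] = set()
        for rid in ids:
            if rid in seen:
                raise ValueError(f"duplicate region id {rid!r}")
            seen.add(rid)
        self.ids: list[str] = ids
        self._index = {rid: i for i, rid in enumerate(ids)}
        # optional per-region GeoJSON geometry dicts (same order as regions)
        self.geometry = list(geometry) if geometry is not None else None
        if self.geometry is not None and len(self.geometry) != len(self.regions):
            raise ValueError("geometry list length must match region count")

    # -- array views -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def populations(self) -> np.ndarray:
        return np.array([r.population for r in self.regions], dtype=float)

    @property
    def cases(self) -> np.ndarray:
        return np.array([r.cases for r in self.regions], dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[r.x, r.y] for r in self.regions], dtype=float)

    @property
    def total_cases(self) -> int:
        return int(sum(r.cases for r in self.regions))

    @property
    def total_population(self) -> int:
        return int(sum(r.population for r in self.regions))

    def index_of(self, region_id: str) -> int:
        return self._index[region_id]

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Stack the named covariates into an (n_regions, len(names)) array."""
        out = np.empty((self.n_regions, len(names)))
        for j, name in enumerate(names):
            for i, r in enumerate(self.regions):
                if name not in r.covariates:
                    raise KeyError(f"region {r.id!r} lacks covariate {name!r}")
                out[i, j] = r.covariates[name]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Region table as a DataFrame (one row per region, row order kept)."""
        cov_names: list[str] = []
        for r in self.regions:
            for k in r.covariates:
                if k not in cov_names:
                    cov_names.append(k)
        rows = []
        for r in self.regions:
            row = {
                "id": r.id,
                "name": r.name,
                "x": r.x,
                "y": r.y,
                "population": r.population,
                "cases": r.cases,
            }
            for k in cov_names:
                row[k] = r.covariates.get(k, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        return (
            f"StudyArea(n_regions={self.n_regions}, C={self.total_cases}, "
            f"N={self.total_population}, mode={self.coordinate_mode!r})"
        )


DEFAULT_COLUMNS = {
    "id": "id",
    "name": "name",
    "x": "x",
    "y": "y",
    "population": "population",
    "cases": "cases",
}


def _area_from_frame(
    df: pd.DataFrame,
    column_map: Mapping[str, str] | None,
    coordinate_mode: str,
) -> StudyArea:
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    required = ["id", "x", "y", "population", "cases"]
    for key in required:
        if cmap[key] not in df.columns:
            raise ValueError(f"missing required column {cmap[key]!r} (for {key})")
    has_name = cmap["name"] in df.columns
    core_cols = {cmap[k] for k in cmap if cmap[k] in df.columns}
    cov_cols = [c for c in df.columns if c not in core_cols]
    regions = []
    for pos, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        rid = str(rec[cmap["id"]])
        try:
            covs = {c: float(rec[c]) for c in cov_cols if pd.notna(rec[c])}
            regions.append(
                Region(
                    id=rid,
                    name=str(rec[cmap["name"]]) if has_name else rid,
                    x=float(rec[cmap["x"]]),
                    y=float(rec[cmap["y"]]),
                    population=int(rec[cmap["population"]]),
                    cases=int(rec[cmap["cases"]]),
                    covariates=covs,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {pos} (id {rid!r}): {exc}") from exc
    return StudyArea(regions, coordinate_mode=coordinate_mode)


def load_region_table(
    path,
    column_map: Mapping[str, str] | None = None,
    coordinate_mode: str = "spherical",
    sep: str | None = None,
) -> StudyArea:
    """Read a delimited region table (CSV/TSV with header) into a StudyArea.

    ``column_map`` maps the canonical field names (id, name, x, y,
    population, cases) to the file's column names; any remaining numeric
    columns become covariates.  Row order is preserved.  The default
    ``coordinate_mode`` is spherical because region tables usually carry
    longitude/latitude centroids.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return _area_from_frame(df, column_map, coordinate_mode)


def write_region_table(area: StudyArea, path, sep: str = ",") -> None:
    """Write the region table back to delimited text (round-trips with
    :func:`load_region_table`)."""
    area.to_frame().to_csv(path, sep=sep, index=False)


def load_geojson(
    path,
    column_map: Mapping[str, str] | None = None,
    coordinate_mode: str = "spherical",
) -> StudyArea:
    """Read a GeoJSON FeatureCollection of polygon (or point) features.

    Centroids are representative points of the polygon geometry; population,
    cases and covariates are read from feature properties.  The polygon
    geometry is retained on the StudyArea for later export.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    props_rows = []
    geoms = []
    for feat in fc["features"]:
        props = dict(feat.get("properties") or {})
        geom = feat.get("geometry")
        if geom is None:
            raise ValueError("feature without geometry")
        pt = shape(geom).representative_point()
        props.setdefault("x", pt.x)
        props.setdefault("y", pt.y)
        props_rows.append(props)
        geoms.append(geom)
    df = pd.DataFrame(props_rows)
    area = _area_from_frame(df, column_map, coordinate_mode)
    area.geometry = geoms
    return area


def _haversine_matrix(coords: np.ndarray) -> np.ndarray:
    lon = np.radians(coords[:, 0])[:, None]
    lat = np.radians(coords[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_matrix(area: StudyArea) -> np.ndarray:
    """Pairwise centroid distances (symmetric, zero diagonal).

    Planar mode uses Euclidean distance in the coordinate units; spherical
    mode treats (x, y) as (lon, lat) degrees and returns great-circle
    kilometres on a sphere of radius 6371 km.
    """
    coords = area.coords
    if area.coordinate_mode == "planar":
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        d = _haversine_matrix(coords)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class NeighborStructure:
    """Per-region neighbour orderings by ascending centroid distance.

    ``order[i]`` lists the indices of the other regions sorted by distance
    from region i, ties broken by lexicographic region id so the ordering
    is reproducible and invariant to input row order.
    """

    ids: list[str]
    order: list[np.ndarray]  # per region: indices of other regions

    def neighbors_of(self, region_id: str, k: int | None = None) -> list[str]:
        i = self.ids.index(region_id)
        idx = self.order[i] if k is None else self.order[i][:k]
        return [self.ids[j] for j in idx]


def k_nearest(area: StudyArea, k: int) -> NeighborStructure:
    """K-nearest-neighbour structure: each region's K-1 nearest others.

    ``k`` counts the region itself, matching the convention of a scanning
    window of at most K regions; each returned list has K-1 entries.
    """
    n = area.n_regions
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = distance_matrix(area)
    ids = area.ids
    order = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        others.sort(key=lambda j: (d[i, j], ids[j]))  # id breaks exact ties
        order.append(np.array(others[: k - 1], dtype=int))
    return NeighborStructure(ids=list(ids), order=order)
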