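"""Gridded spatial model: half-degree cells, EEZ regions, and the neighbor graph.

The grid is a regular lon/lat lattice.  Cell areas use the spherical
approximation ``A_eq * cos(lat)`` with an authalic Earth radius, which keeps
per-pair area proportions exact under center-point cell assignment.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape

EARTH_RADIUS_KM = 6371.0088  # authalic sphere

TERRITORY_CLASSES = (
    "continental",
    "subregion_of_country",
    "territory_same_nation",
    "territory_other_nation",
    "associated_state",
)

UNUSABLE_SAME_COUNTRY = "same-country-subregion"
UNUSABLE_SAME_NATION_TERRITORY = "same-nation-territory"


def equatorial_cell_area_km2(resolution: float) -> float:
    """Area of a resolution x resolution cell centered on the equator."""
    side = EARTH_RADIUS_KM * math.radians(resolution)
    return side * side


def cell_area_km2(lat_center: float | np.ndarray, resolution: float):
    """Latitude-corrected cell area, spherical approximation."""
    return equatorial_cell_area_km2(resolution) * np.cos(np.radians(lat_center))


def _check_bbox(bbox) -> tuple[float, float, float, float]:
    lon_min, lat_min, lon_max, lat_max = map(float, bbox)
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError(f"degenerate bbox: {bbox!r}")
    return lon_min, lat_min, lon_max, lat_max


def _n_steps(extent: float, resolution: float) -> int:
    n = extent / resolution
    n_round = round(n)
    if n_round < 1 or abs(n - n_round) > 1e-9 * max(1.0, abs(n)):
        raise ValueError(
            f"resolution {resolution} does not divide extent {extent}"
        )
    return int(n_round)


@dataclass(frozen=True)
class GridCell:
    cell_id: int
    lon: float
    lat: float
    area_km2: float
    region_id: str | None = None


class Grid:
    """Regular lon/lat grid over a bbox.

    Cells are numbered row-major with longitude varying fastest, starting at
    the south-west corner.  ``region_id`` is filled by :func:`assign_cells`.
    """

    def __init__(self, bbox, resolution: float = 0.5):
        lon_min, lat_min, lon_max, lat_max = _check_bbox(bbox)
        self.bbox = (lon_min, lat_min, lon_max, lat_max)
        self.resolution = float(resolution)
        nx = _n_steps(lon_max - lon_min, resolution)
        ny = _n_steps(lat_max - lat_min, resolution)
        lon_centers = lon_min + resolution * (np.arange(nx) + 0.5)
        lat_centers = lat_min + resolution * (np.arange(ny) + 0.5)
        lon2d, lat2d = np.meshgrid(lon_centers, lat_centers)
        self.lon = lon2d.ravel()
        self.lat = lat2d.ravel()
        self.cell_id = np.arange(self.lon.size, dtype=np.int64)
        self.area_km2 = cell_area_km2(self.lat, self.resolution)
        self.region_id: np.ndarray = np.full(self.lon.size, None, dtype=object)

    @property
    def n_cells(self) -> int:
        return int(self.cell_id.size)

    def cells(self) -> Iterable[GridCell]:
        for i in range(self.n_cells):
            yield GridCell(
                cell_id=int(self.cell_id[i]),
                lon=float(self.lon[i]),
                lat=float(self.lat[i]),
                area_km2=float(self.area_km2[i]),
                region_id=self.region_id[i],
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "lon": self.lon,
                "lat": self.lat,
                "area_km2": self.area_km2,
                "region_id": self.region_id,
            }
        )

    def assignment(self) -> pd.DataFrame:
        """Cell assignment table indexed by cell_id."""
        return self.to_frame().set_index("cell_id")


def build_grid(bbox, resolution: float = 0.5) -> Grid:
    return Grid(bbox, resolution)


@dataclass
class EEZRegion:
    region_id: str
    name: str
    country_id: str
    country_name: str = ""
    un_subregion: str = ""
    territory_class: str = "continental"
    parent_country_for_grouping: str | None = None
    area_km2: float = 0.0

    def __post_init__(self):
        if self.territory_class not in TERRITORY_CLASSES:
            raise ValueError(
                f"region {self.region_id}: unknown territory_class "
                f"{self.territory_class!r}"
            )

    @property
    def grouping_country(self) -> str:
        """Country identity used for the neighbor rules.

        Associated states inherit the parent country before edge evaluation.
        """
        if (
            self.territory_class == "associated_state"
            and self.parent_country_for_grouping
        ):
            return self.parent_country_for_grouping
        return self.country_id


def polygon_area_km2(geom) -> float:
    """Approximate geodesic area via the sinusoidal equal-area projection."""

    def _proj(coords: np.ndarray) -> np.ndarray:
        lam = np.radians(coords[:, 0])
        phi = np.radians(coords[:, 1])
        out = np.empty_like(coords)
        out[:, 0] = EARTH_RADIUS_KM * lam * np.cos(phi)
        out[:, 1] = EARTH_RADIUS_KM * phi
        return out

    # densify edges so the projected shape follows the parallels
    dense = shapely.segmentize(geom, 0.25)
    return float(shapely.transform(dense, _proj).area)


class RegionSet:
    """EEZ regions with their polygons, keyed by region_id."""

    def __init__(self, regions: Iterable[EEZRegion], polygons: Mapping[str, object]):
        self.regions: dict[str, EEZRegion] = {r.region_id: r for r in regions}
        self.polygons: dict[str, object] = dict(polygons)
        missing = set(self.regions) ^ set(self.polygons)
        if missing:
            raise ValueError(f"regions without polygons (or vice versa): {sorted(missing)}")
        for rid, reg in self.regions.items():
            if reg.area_km2 <= 0:
                reg.area_km2 = polygon_area_km2(self.polygons[rid])

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions.values())

    @property
    def region_ids(self) -> list[str]:
        return sorted(self.regions)

    def to_geojson(self) -> dict:
        features = []
        for rid in self.region_ids:
            reg = self.regions[rid]
            features.append(
                {
                    "type": "Feature",
                    "geometry": geom_mapping(self.polygons[rid]),
                    "properties": {
                        "region_id": reg.region_id,
                        "name": reg.name,
                        "country_id": reg.country_id,
                        "country_name": reg.country_name,
                        "un_subregion": reg.un_subregion,
                        "territory_class": reg.territory_class,
                        "parent_country_for_grouping": reg.parent_country_for_grouping,
                        "area_km2": reg.area_km2,
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def from_geojson(cls, source) -> "RegionSet":
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = source
        regions, polygons = [], {}
        for feat in data["features"]:
            props = feat["properties"]
            reg = EEZRegion(
                region_id=str(props["region_id"]),
                name=props.get("name", str(props["region_id"])),
                country_id=str(props["country_id"]),
                country_name=props.get("country_name", ""),
                un_subregion=props.get("un_subregion", ""),
                territory_class=props.get("territory_class", "continental"),
                parent_country_for_grouping=props.get("parent_country_for_grouping"),
                area_km2=float(props.get("area_km2") or 0.0),
            )
            regions.append(reg)
            polygons[reg.region_id] = geom_shape(feat["geometry"])
        return cls(regions, polygons)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_id": r.region_id,
                "name": r.name,
                "country_id": r.country_id,
                "country_name": r.country_name,
                "un_subregion": r.un_subregion,
                "territory_class": r.territory_class,
                "grouping_country": r.grouping_country,
                "area_km2": r.area_km2,
            }
            for r in self
        ]
        return pd.DataFrame(rows).set_index("region_id")


def assign_cells(grid: Grid, regions: RegionSet) -> Grid:
    """Assign each cell to the region containing its center point.

    Centers strictly inside a polygon take that region; a center falling
    exactly on a shared boundary is given deterministically to the
    lexicographically smallest covering region.  Two regions whose interiors
    both contain a center indicate overlapping polygons and raise.
    """
    claimed = np.full(grid.n_cells, None, dtype=object)
    for rid in regions.region_ids:
        poly = regions.polygons[rid]
        if not poly.is_valid:
            raise ValueError(f"region {rid}: invalid polygon")
        inside = shapely.contains_xy(poly, grid.lon, grid.lat)
        clash = inside & (claimed != None)  # noqa: E711
        if clash.any():
            other = claimed[clash][0]
            raise ValueError(
                f"overlapping polygons: regions {other!r} and {rid!r} both "
                f"contain cell center {int(grid.cell_id[clash.argmax()])}"
            )
        claimed[inside] = rid
    # boundary fallback: covered but not strictly inside
    open_mask = claimed == None  # noqa: E711
    if open_mask.any():
        idx = np.nonzero(open_mask)[0]
        for rid in regions.region_ids:
            if not idx.size:
                break
            poly = regions.polygons[rid]
            touch = shapely.intersects_xy(poly, grid.lon[idx], grid.lat[idx])
            claimed[idx[touch]] = rid
            idx = idx[~touch]
    grid.region_id = claimed
    return grid


@dataclass(frozen=True)
class NeighborEdge:
    region_a: str
    region_b: str
    usable: bool
    reason: str | None = None  # set iff not usable

    @property
    def key(self) -> frozenset:
        return frozenset((self.region_a, self.region_b))


@dataclass
class NeighborGraph:
    nodes: list[str]
    edges: dict[frozenset, NeighborEdge] = field(default_factory=dict)

    def add_edge(self, edge: NeighborEdge) -> None:
        if edge.region_a == edge.region_b:
            raise ValueError(f"self-edge on {edge.region_a}")
        self.edges[edge.key] = edge

    def edge(self, a: str, b: str) -> NeighborEdge | None:
        return self.edges.get(frozenset((a, b)))

    def usable_edges(self) -> list[NeighborEdge]:
        return [e for e in self.edges.values() if e.usable]

    def usable_neighbors(self, region_id: str) -> set[str]:
        out = set()
        for e in self.usable_edges():
            if region_id in e.key:
                out.update(e.key - {region_id})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.edges.values():
            a, b = sorted(e.key)
            rows.append(
                {"region_a": a, "region_b": b, "usable": e.usable, "reason": e.reason or ""}
            )
        return (
            pd.DataFrame(rows, columns=["region_a", "region_b", "usable", "reason"])
            .sort_values(["region_a", "region_b"])
            .reset_index(drop=True)
        )


def _split_antimeridian(geom):
    # polygons spanning the dateline are split at +/-180 before adjacency tests
    from shapely.geometry import box

    minx, _, maxx, _ = geom.bounds
    if minx >= -180 and maxx <= 180:
        return geom
    west = geom.intersection(box(-540, -90, -180, 90))
    east = geom.intersection(box(-180, -90, 540, 90))
    return shapely.unary_union([west, east])


def edge_usability(reg_a: EEZRegion, reg_b: EEZRegion) -> tuple[bool, str | None]:
    """Apply the country/territory collapsing rules to a touching pair."""
    if reg_a.grouping_country != reg_b.grouping_country:
        return True, None
    classes = {reg_a.territory_class, reg_b.territory_class}
    if "territory_same_nation" in classes:
        return False, UNUSABLE_SAME_NATION_TERRITORY
    return False, UNUSABLE_SAME_COUNTRY


def build_neighbor_graph(
    regions: RegionSet, adjacency_predicate: str = "touch"
) -> NeighborGraph:
    """Edges join regions whose polygons share at least one boundary point.

    ``adjacency_predicate='touch'`` counts corner-point contact as adjacency;
    ``'segment'`` requires a shared boundary segment of positive length.
    """
    if adjacency_predicate not in ("touch", "segment"):
        raise ValueError(f"unknown adjacency predicate {adjacency_predicate!r}")
    graph = NeighborGraph(nodes=regions.region_ids)
    geoms = {
        rid: _split_antimeridian(regions.polygons[rid]) for rid in regions.region_ids
    }
    for rid_a, rid_b in itertools.combinations(regions.region_ids, 2):
        ga, gb = geoms[rid_a], geoms[rid_b]
        if not ga.intersects(gb):
            continue
        inter = ga.intersection(gb)
        if inter.is_empty:
            continue
        if adjacency_predicate == "segment" and inter.length <= 0:
            continue
        usable, reason = edge_usability(regions.regions[rid_a], regions.regions[rid_b])
        graph.add_edge(NeighborEdge(rid_a, rid_b, usable, reason))
    return graph
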