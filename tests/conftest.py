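"""Shared fixtures: hand-built region mosaics and an independent brute-force
classification oracle used to cross-check the production path."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import shapely

from transbound.spatial import EEZRegion, RegionSet, build_grid, assign_cells


def make_regions(boxes: dict, meta: dict | None = None) -> RegionSet:
    """RegionSet from ``{region_id: (lon0, lat0, lon1, lat1)}`` plus overrides."""
    meta = meta or {}
    regions, polygons = [], {}
    for i, (rid, bounds) in enumerate(sorted(boxes.items())):
        m = {
            "name": rid,
            "country_id": f"C_{rid}",
            "country_name": f"Country {rid}",
            "un_subregion": "Northern America",
            "territory_class": "continental",
            "parent_country_for_grouping": None,
        }
        m.update(meta.get(rid, {}))
        regions.append(EEZRegion(region_id=rid, **m))
        polygons[rid] = shapely.box(*bounds)
    return RegionSet(regions, polygons)


@pytest.fixture
def two_rects():
    """Two abutting rectangles, different countries, sharing one meridian edge."""
    return make_regions({"A": (0, 0, 5, 10), "B": (5, 0, 10, 10)})


@pytest.fixture
def grid10(two_rects):
    grid = build_grid((0, 0, 10, 10), 0.5)
    assign_cells(grid, two_rects)
    return grid


@pytest.fixture
def strip3():
    """Chile | Peru | Ecuador analogue: three vertical strips, Peru central."""
    return make_regions(
        {
            "Chile": (0, 0, 2, 5),
            "Peru": (2, 0, 5, 5),
            "Ecuador": (5, 0, 10, 5),
        }
    )


@pytest.fixture
def strip3_grid(strip3):
    grid = build_grid((0, 0, 10, 5), 0.5)
    assign_cells(grid, strip3)
    return grid


def cells_in_region(grid, region_id, n=None, rows=None):
    """Pick cells of a region, optionally restricted to the first lat rows."""
    mask = grid.region_id == region_id
    ids = grid.cell_id[mask]
    lats = grid.lat[mask]
    order = np.lexsort((grid.lon[mask], lats))
    ids = ids[order]
    if rows is not None:
        unique_lats = np.unique(lats)
        keep = np.isin(lats[order], unique_lats[rows])
        ids = ids[keep]
    if n is not None:
        ids = ids[:n]
    return [int(c) for c in ids]


# ---------------------------------------------------------------------------
# brute-force oracle (kept deliberately naive and loop-based)


def oracle_adjacency(regions: RegionSet) -> dict:
    """Pairwise polygon-touch scan with the usability rules re-derived."""
    out = {}
    for ra, rb in itertools.combinations(sorted(regions.regions), 2):
        pa, pb = regions.polygons[ra], regions.polygons[rb]
        if not pa.intersects(pb):
            continue
        a, b = regions.regions[ra], regions.regions[rb]
        ga = a.parent_country_for_grouping if (
            a.territory_class == "associated_state" and a.parent_country_for_grouping
        ) else a.country_id
        gb = b.parent_country_for_grouping if (
            b.territory_class == "associated_state" and b.parent_country_for_grouping
        ) else b.country_id
        out[frozenset((ra, rb))] = ga != gb
    return out


def oracle_classify(cells, grid, regions: RegionSet, threshold=0.25):
    """Independent per-species classification by exhaustive pair enumeration.

    Returns (species_label, {region: stock_label}, {pair: (ai_a, ai_b)}).
    """
    region_of = {int(c): grid.region_id[c] for c in grid.cell_id}
    area_of = {int(c): float(grid.area_km2[c]) for c in grid.cell_id}
    areas: dict[str, float] = {}
    for c in cells:
        rid = region_of[c]
        if rid is not None:
            areas[rid] = areas.get(rid, 0.0) + area_of[c]
    adjacency = oracle_adjacency(regions)
    pair_ai, passing = {}, set()
    for pair, usable in adjacency.items():
        if not usable:
            continue
        a, b = sorted(pair)
        aa, ab = areas.get(a, 0.0), areas.get(b, 0.0)
        if aa + ab <= 0:
            continue
        ai_a, ai_b = aa / (aa + ab), ab / (aa + ab)
        pair_ai[(a, b)] = (ai_a, ai_b)
        if ai_a > threshold and ai_b > threshold:
            passing.update((a, b))
    species_label = "transboundary" if passing else "discrete"
    stock_labels = {}
    for rid in areas:
        if rid in passing:
            stock_labels[rid] = "transboundary"
        elif species_label == "transboundary":
            stock_labels[rid] = "excluded_stock"
        else:
            stock_labels[rid] = "discrete_stock"
    return species_label, stock_labels, pair_ai
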