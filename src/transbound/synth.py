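"""Synthetic world generator with recorded ground truth.

Builds an EEZ mosaic with known adjacency, species ranges with controllable
per-region share fractions, four presence sources with a tunable agreement
rate, and catch/price series constructed to realize chosen trend categories —
so that every downstream stage is testable without external data.

The ground-truth labels are computed here by self-contained brute-force loops
(mosaic-cell adjacency, direct area sums) rather than by calling the
classifier, keeping generator and pipeline independent.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import trends
from .spatial import EEZRegion, Grid, RegionSet, build_grid
from .trends import CatchSeries

UN_SUBREGIONS = (
    "Northern America",
    "Eastern Asia",
    "South America",
    "Northern Europe",
)

STOCK_TRANSBOUNDARY = "transboundary"
STOCK_EXCLUDED = "excluded_stock"
STOCK_DISCRETE = "discrete_stock"

TREND_CATEGORIES = ("A", "B", "C", "NoCategory")


@dataclass
class WorldSpec:
    """Parameters of a synthetic world; fully determines the output via seed."""

    seed: int = 0
    n_regions: int = 6
    bbox: tuple = (0.0, 0.0, 10.0, 10.0)
    grid_resolution: float = 0.5
    n_species: int = 10
    source_agreement_rate: float = 1.0
    # optional explicit per-species target shares: {species_id: {region_id: share}}
    share_fractions: dict | None = None
    # optional explicit trend categories: {(species_id, region_id): category}
    trend_categories: dict | None = None
    cells_per_species: int = 40
    years: tuple = (1951, 2014)
    window: tuple = (2005, 2014)
    ai_threshold: float = 0.25
    price_missing_rate: float = 0.0

    def __post_init__(self):
        lon_min, lat_min, lon_max, lat_max = self.bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError(f"degenerate bbox: {self.bbox!r}")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not 0.0 <= self.source_agreement_rate <= 1.0:
            raise ValueError("source_agreement_rate must be in [0, 1]")
        for extent in (lon_max - lon_min, lat_max - lat_min):
            n = extent / self.grid_resolution
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(
                    f"resolution {self.grid_resolution} does not divide bbox extent {extent}"
                )
        if self.share_fractions:
            for sid, shares in self.share_fractions.items():
                total = sum(shares.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"share_fractions for {sid!r} sum to {total}, expected 1"
                    )


@dataclass
class GroundTruth:
    """Intended labels recorded at generation time."""

    # species_id -> {frozenset({a, b}): passes}
    pair_labels: dict = field(default_factory=dict)
    # species_id -> {region_id: stock label}
    stock_labels: dict = field(default_factory=dict)
    # species_id -> "transboundary" | "discrete"
    species_labels: dict = field(default_factory=dict)
    # species_id -> {region_id: realized area share of total range}
    realized_shares: dict = field(default_factory=dict)
    # species_id -> frozenset of consensus cells (under the emitted layers)
    consensus_cells: dict = field(default_factory=dict)
    # (species_id, region_id) -> intended trend category
    trend_category: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "pair_labels": {
                sid: {"|".join(sorted(k)): v for k, v in pairs.items()}
                for sid, pairs in self.pair_labels.items()
            },
            "stock_labels": self.stock_labels,
            "species_labels": self.species_labels,
            "realized_shares": self.realized_shares,
            "consensus_cells": {
                sid: sorted(int(c) for c in cells)
                for sid, cells in self.consensus_cells.items()
            },
            "trend_category": {
                f"{sid}|{rid}": cat for (sid, rid), cat in self.trend_category.items()
            },
        }


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    regions: RegionSet
    grid: Grid
    mosaic_adjacency: dict  # frozenset pair -> usable bool
    ranges: dict  # species_id -> frozenset of cell_ids
    layers: dict  # species_id -> {source: frozenset}
    catch: pd.DataFrame  # species_id, region_id, year, tonnes
    spatial_catch: pd.DataFrame  # species_id, cell_id, year, tonnes
    prices: pd.DataFrame  # species_id, country_id, year, price
    cpi: pd.DataFrame  # year, cpi
    truth: GroundTruth

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.ranges)


# ---------------------------------------------------------------------------
# mosaic


def gen_eez_mosaic(
    spec: WorldSpec, metadata_overrides: dict | None = None
) -> tuple[RegionSet, Grid, dict]:
    """Discrete-Voronoi mosaic of the bbox, snapped to the grid.

    Every grid cell joins the nearest of ``n_regions`` seed cells (ties to the
    lowest seed index), and each region polygon is the union of its cells, so
    the mosaic partitions the bbox exactly and adjacency is well defined.

    Returns the region set, the grid with ``region_id`` filled, and the
    brute-force adjacency map ``frozenset({a,b}) -> usable`` derived from
    queen-neighboring mosaic cells (independent of the polygon overlay).
    """
    rng = np.random.default_rng(spec.seed)
    grid = build_grid(spec.bbox, spec.grid_resolution)
    if spec.n_regions > grid.n_cells:
        raise ValueError("more regions than grid cells")
    seed_cells = rng.choice(grid.n_cells, size=spec.n_regions, replace=False)
    dx = grid.lon[:, None] - grid.lon[seed_cells][None, :]
    dy = grid.lat[:, None] - grid.lat[seed_cells][None, :]
    owner = np.argmin(dx * dx + dy * dy, axis=1)  # first minimum wins ties

    res = spec.grid_resolution
    region_ids = [f"R{i:02d}" for i in range(spec.n_regions)]
    polygons = {}
    for i, rid in enumerate(region_ids):
        boxes = [
            shapely.box(lon - res / 2, lat - res / 2, lon + res / 2, lat + res / 2)
            for lon, lat in zip(grid.lon[owner == i], grid.lat[owner == i])
        ]
        polygons[rid] = shapely.normalize(shapely.unary_union(boxes))

    overrides = metadata_overrides or {}
    regions = []
    for i, rid in enumerate(region_ids):
        meta = {
            "name": f"Region {i}",
            "country_id": f"C{i:02d}",
            "country_name": f"Country {i}",
            "un_subregion": UN_SUBREGIONS[i % len(UN_SUBREGIONS)],
            "territory_class": "continental",
            "parent_country_for_grouping": None,
        }
        meta.update(overrides.get(rid, {}))
        regions.append(EEZRegion(region_id=rid, **meta))
    region_set = RegionSet(regions, polygons)

    grid.region_id = np.array([region_ids[o] for o in owner], dtype=object)
    adjacency = _mosaic_adjacency(grid, owner, region_ids, region_set)
    return region_set, grid, adjacency


def _mosaic_adjacency(
    grid: Grid, owner: np.ndarray, region_ids: list, region_set: RegionSet
) -> dict:
    """Queen-neighbor scan over mosaic cells; usability per the grouping rules."""
    nx = round((grid.bbox[2] - grid.bbox[0]) / grid.resolution)
    ny = round((grid.bbox[3] - grid.bbox[1]) / grid.resolution)
    own2d = owner.reshape(ny, nx)
    pairs = set()
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        if dx >= 0:
            a = own2d[: ny - dy, : nx - dx]
            b = own2d[dy:, dx:]
        else:
            a = own2d[: ny - dy, -dx:]
            b = own2d[dy:, :dx]
        diff = a != b
        pairs.update(
            (int(min(i, j)), int(max(i, j)))
            for i, j in zip(a[diff].ravel(), b[diff].ravel())
        )
    adjacency = {}
    for i, j in sorted(pairs):
        ra = region_set.regions[region_ids[i]]
        rb = region_set.regions[region_ids[j]]
        usable = ra.grouping_country != rb.grouping_country
        adjacency[frozenset((ra.region_id, rb.region_id))] = usable
    return adjacency


# ---------------------------------------------------------------------------
# species ranges


def gen_species_range(
    spec: WorldSpec,
    species_id: str,
    target_shares: dict,
    grid: Grid,
    rng: np.random.Generator,
) -> tuple[frozenset, dict]:
    """Draw a cell set whose per-region area shares match ``target_shares``
    within one cell-area; returns (cells, realized shares)."""
    total = sum(target_shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"target shares sum to {total}, expected 1")
    cells_by_region = {}
    for rid in target_shares:
        mask = grid.region_id == rid
        cells_by_region[rid] = grid.cell_id[mask]
        if not mask.any():
            raise ValueError(
                f"species {species_id!r}: region {rid!r} has no grid cells "
                "available for its target share"
            )

    # shrink the requested range so the tightest region can still fit its quota
    positive = [r for r, s in target_shares.items() if s > 0]
    n_max = min(int(cells_by_region[r].size / target_shares[r]) for r in positive)
    n_total = min(spec.cells_per_species, n_max)
    if n_total < len(positive):
        tight = min(positive, key=lambda r: cells_by_region[r].size / target_shares[r])
        raise ValueError(
            f"species {species_id!r}: region {tight!r} too small for target "
            f"share {target_shares[tight]}"
        )
    quotas = {rid: s * n_total for rid, s in target_shares.items()}
    counts = {rid: int(math.floor(q)) for rid, q in quotas.items()}
    for rid, s in target_shares.items():
        if s > 0 and counts[rid] == 0:
            counts[rid] = 1
    remainders = sorted(
        target_shares, key=lambda r: (quotas[r] - math.floor(quotas[r]), r), reverse=True
    )
    i = 0
    while sum(counts.values()) < n_total:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    while sum(counts.values()) > n_total:
        rid = max(counts, key=lambda r: (counts[r] - quotas[r], r))
        if counts[rid] <= 1:
            break
        counts[rid] -= 1

    chosen: dict[str, list] = {}
    for rid, n in sorted(counts.items()):
        avail = np.sort(cells_by_region[rid])
        if n > avail.size:
            raise ValueError(
                f"species {species_id!r}: region {rid!r} too small for target "
                f"share ({n} cells requested, {avail.size} available)"
            )
        chosen[rid] = list(rng.choice(avail, size=n, replace=False))

    area = {c: float(grid.area_km2[c]) for cells in chosen.values() for c in cells}
    max_cell_area = float(grid.area_km2.max())

    # corrective moves until every region is within one cell-area of target
    for _ in range(4 * n_total):
        tot = sum(area[c] for cells in chosen.values() for c in cells)
        realized = {rid: sum(area[c] for c in cells) for rid, cells in chosen.items()}
        dev = {rid: realized[rid] - target_shares[rid] * tot for rid in chosen}
        worst = max(dev, key=lambda r: (abs(dev[r]), r))
        if abs(dev[worst]) <= max_cell_area:
            break
        over = max(dev, key=lambda r: (dev[r], r))
        under = min(dev, key=lambda r: (dev[r], r))
        unused = np.setdiff1d(
            np.sort(cells_by_region[under]), np.array(chosen[under], dtype=np.int64)
        )
        if len(chosen[over]) <= 1 or unused.size == 0:
            break
        chosen[over].remove(sorted(chosen[over])[0])
        chosen[under].append(int(unused[0]))
        for c in chosen[under]:
            area[c] = float(grid.area_km2[c])

    cells = frozenset(int(c) for cs in chosen.values() for c in cs)
    tot = sum(area[c] for c in cells)
    realized_shares = {
        rid: sum(area[c] for c in cs) / tot for rid, cs in sorted(chosen.items())
    }
    return cells, realized_shares


def gen_presence_sources(
    range_cells: frozenset,
    agreement_rate: float,
    seed_or_rng,
    all_cells,
) -> dict:
    """Four binary layers; the catch layer mirrors the range, the other three
    independently drop range cells and add outside cells at rate 1-agreement."""
    if not 0.0 <= agreement_rate <= 1.0:
        raise ValueError("agreement_rate must be in [0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    noise = 1.0 - agreement_rate
    range_sorted = np.array(sorted(range_cells), dtype=np.int64)
    outside = np.setdiff1d(np.sort(np.asarray(list(all_cells), dtype=np.int64)), range_sorted)
    layers = {"catch": frozenset(int(c) for c in range_sorted)}
    for source in ("occurrence", "enm", "sdm"):
        keep = range_sorted[rng.random(range_sorted.size) >= noise]
        added = outside[rng.random(outside.size) < noise]
        layers[source] = frozenset(int(c) for c in np.concatenate([keep, added]))
    return layers


# ---------------------------------------------------------------------------
# catch, prices


def gen_catch_series(
    category: str,
    species_id: str = "S",
    region_id: str = "R",
    years: tuple = (1951, 2014),
    seed_or_rng=0,
    scale: float | None = None,
    window: tuple = (2005, 2014),
) -> CatchSeries:
    """A catch series whose predominant window category is ``category``.

    Shapes invert the per-year rules: B draws every year above 55% of the
    peak; C peaks mid-series and settles between 12% and 45% of the peak; A is
    either end-of-series growth or an early peak, collapse below 10% and
    rebuild; NoCategory emits eight scattered data years.
    """
    if category not in TREND_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    y0, y1 = years
    all_years = np.arange(y0, y1 + 1)
    m = scale if scale is not None else float(rng.uniform(1e3, 1e5))
    w0, w1 = window

    if category == "B":
        values = m * rng.uniform(0.55, 1.0, all_years.size)
        return CatchSeries(species_id, region_id, tuple(all_years), tuple(values))

    if category == "C":
        lo, hi = y0 + 19, min(y1 - 24, w0 - 15)
        peak = int(rng.integers(lo, max(lo, hi) + 1))
        values = np.empty(all_years.size)
        for i, y in enumerate(all_years):
            if y < peak:
                values[i] = m * (0.2 + 0.75 * (y - y0) / max(1, peak - y0))
            elif y == peak:
                values[i] = m
            elif y < w0:
                frac = min(1.0, (y - peak) / 15)
                values[i] = m - (m - 0.3 * m) * frac
            else:
                values[i] = m * rng.uniform(0.12, 0.45)
        return CatchSeries(species_id, region_id, tuple(all_years), tuple(values))

    if category == "A":
        if rng.random() < 0.5:  # growth to a final-year peak
            r = float(rng.uniform(0.60, 0.82))
            values = m * r ** (y1 - all_years).astype(float)
        else:  # early peak, collapse below 10%, rebuild into the window
            peak = int(rng.integers(y0 + 9, y0 + 20))
            trough = peak + 10
            cmin = float(rng.uniform(0.02, 0.08))
            values = np.empty(all_years.size)
            for i, y in enumerate(all_years):
                if y < peak:
                    values[i] = m * (0.2 + 0.75 * (y - y0) / max(1, peak - y0))
                elif y == peak:
                    values[i] = m
                elif y <= trough:
                    frac = (y - peak) / (trough - peak)
                    values[i] = m - (m - cmin * m) * frac
                else:
                    values[i] = m * rng.uniform(0.12, 0.45)
        return CatchSeries(species_id, region_id, tuple(all_years), tuple(values))

    # NoCategory: 8 scattered data years, a few inside the window
    in_window = rng.choice(np.arange(w0, w1 + 1), size=3, replace=False)
    before = rng.choice(np.arange(y0, w0 - 1), size=5, replace=False)
    yrs = np.sort(np.concatenate([before, in_window]))
    values = m * rng.uniform(0.1, 1.0, yrs.size)
    return CatchSeries(species_id, region_id, tuple(int(y) for y in yrs), tuple(values))


def gen_prices(
    species_ids,
    country_ids,
    years: tuple = (1951, 2014),
    seed_or_rng=0,
    missing_rate: float = 0.0,
    cpi_years: tuple = (1950, 2020),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strictly positive ex-vessel prices (2010 real USD) plus a CPI table."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    rows = []
    yr = np.arange(years[0], years[1] + 1)
    for sid in sorted(species_ids):
        for cid in sorted(country_ids):
            if missing_rate > 0 and rng.random() < missing_rate:
                continue
            base = float(rng.uniform(500.0, 3000.0))
            vals = base * rng.uniform(0.9, 1.1, yr.size)
            rows.extend(
                {"species_id": sid, "country_id": cid, "year": int(y), "price": float(p)}
                for y, p in zip(yr, vals)
            )
    prices = pd.DataFrame(rows, columns=["species_id", "country_id", "year", "price"])
    cy = np.arange(cpi_years[0], cpi_years[1] + 1)
    cpi = pd.DataFrame({"year": cy, "cpi": 100.0 * 1.025 ** (cy - 2010)})
    return prices, cpi


# ---------------------------------------------------------------------------
# ground truth + world assembly


def _brute_force_labels(
    realized_shares: dict, adjacency: dict, threshold: float
) -> tuple[dict, dict, str]:
    """Pairwise labels by direct enumeration over usable adjacent pairs."""
    regions = [r for r, s in realized_shares.items() if s > 0]
    pair_labels = {}
    passing_regions = set()
    for a, b in itertools.combinations(sorted(regions), 2):
        key = frozenset((a, b))
        if not adjacency.get(key, False):
            continue
        joint = realized_shares[a] + realized_shares[b]
        ai_a = realized_shares[a] / joint
        ai_b = realized_shares[b] / joint
        passes = min(ai_a, ai_b) > threshold
        pair_labels[key] = passes
        if passes:
            passing_regions.update(key)
    species_label = "transboundary" if passing_regions else "discrete"
    stock_labels = {}
    for r in regions:
        if r in passing_regions:
            stock_labels[r] = STOCK_TRANSBOUNDARY
        elif species_label == "transboundary":
            stock_labels[r] = STOCK_EXCLUDED
        else:
            stock_labels[r] = STOCK_DISCRETE
    return pair_labels, stock_labels, species_label


def _default_shares(
    spec: WorldSpec, adjacency: dict, rng: np.random.Generator
) -> dict:
    """Per-species target shares drawn from label-realizing templates."""
    usable_pairs = sorted(tuple(sorted(k)) for k, u in adjacency.items() if u)
    region_degree: dict[str, set] = {}
    for a, b in usable_pairs:
        region_degree.setdefault(a, set()).add(b)
        region_degree.setdefault(b, set()).add(a)
    all_regions = [f"R{i:02d}" for i in range(spec.n_regions)]
    shares = {}
    for i in range(spec.n_species):
        sid = f"S{i:03d}"
        kind = rng.integers(0, 4)
        if kind == 0 or not usable_pairs:  # single region -> discrete
            shares[sid] = {all_regions[rng.integers(len(all_regions))]: 1.0}
        elif kind == 1:  # balanced neighboring pair -> transboundary
            a, b = usable_pairs[rng.integers(len(usable_pairs))]
            u = float(rng.uniform(0.35, 0.6))
            shares[sid] = {a: u, b: round(1.0 - u, 12)}
        elif kind == 2:  # skewed neighboring pair -> fails the threshold
            a, b = usable_pairs[rng.integers(len(usable_pairs))]
            shares[sid] = {a: 0.93, b: 0.07}
        else:  # anchoveta-style triple when the graph allows it
            hubs = [r for r, nb in region_degree.items() if len(nb) >= 2]
            if hubs:
                hub = hubs[int(rng.integers(len(hubs)))]
                nb = sorted(region_degree[hub])
                b, c = nb[0], nb[1]
                shares[sid] = {hub: 0.55, b: 0.38, c: 0.07}
            else:
                a, b = usable_pairs[rng.integers(len(usable_pairs))]
                shares[sid] = {a: 0.55, b: 0.45}
    return shares


def generate_world(spec: WorldSpec, metadata_overrides: dict | None = None) -> SyntheticWorld:
    """Assemble the full synthetic world deterministically from the spec."""
    root = np.random.SeedSequence(spec.seed)
    s_mosaic, s_shares, s_range, s_sources, s_catch, s_price = root.spawn(6)

    regions, grid, adjacency = gen_eez_mosaic(spec, metadata_overrides)
    truth = GroundTruth()

    share_fractions = spec.share_fractions or _default_shares(
        spec, adjacency, np.random.default_rng(s_shares)
    )
    rng_range = np.random.default_rng(s_range)
    rng_sources = np.random.default_rng(s_sources)
    rng_catch = np.random.default_rng(s_catch)

    ranges, layers = {}, {}
    catch_rows, spatial_rows = [], []
    all_cells = grid.cell_id
    w0, w1 = spec.window
    for sid in sorted(share_fractions):
        cells, realized = gen_species_range(
            spec, sid, share_fractions[sid], grid, rng_range
        )
        ranges[sid] = cells
        truth.realized_shares[sid] = realized
        layers[sid] = gen_presence_sources(
            cells, spec.source_agreement_rate, rng_sources, all_cells
        )
        pair_labels, stock_labels, species_label = _brute_force_labels(
            realized, adjacency, spec.ai_threshold
        )
        truth.pair_labels[sid] = pair_labels
        truth.stock_labels[sid] = stock_labels
        truth.species_labels[sid] = species_label

        cells_by_region: dict[str, list] = {}
        for c in sorted(cells):
            cells_by_region.setdefault(str(grid.region_id[c]), []).append(c)
        species_window_cells: set = set()
        for rid in sorted(stock_labels):
            if spec.trend_categories is not None:
                category = spec.trend_categories.get((sid, rid), "B")
            else:
                category = TREND_CATEGORIES[int(rng_catch.integers(0, 4))]
            truth.trend_category[(sid, rid)] = category
            series = gen_catch_series(
                category, sid, rid, spec.years, rng_catch, window=spec.window
            )
            catch_rows.extend(
                {"species_id": sid, "region_id": rid, "year": int(y), "tonnes": float(t)}
                for y, t in zip(series.years, series.catch)
            )
            rcells = cells_by_region[rid]
            for y, t in zip(series.years, series.catch):
                if w0 <= y <= w1 and t > 0:
                    per_cell = t / len(rcells)
                    spatial_rows.extend(
                        {"species_id": sid, "cell_id": int(c), "year": int(y),
                         "tonnes": per_cell}
                        for c in rcells
                    )
                    species_window_cells.update(int(c) for c in rcells)
        # consensus under the emitted layers (brute-force intersection)
        truth.consensus_cells[sid] = (
            layers[sid]["occurrence"]
            & layers[sid]["enm"]
            & layers[sid]["sdm"]
            & layers[sid]["catch"]
            & frozenset(species_window_cells)
        )

    catch = pd.DataFrame(
        catch_rows, columns=["species_id", "region_id", "year", "tonnes"]
    )
    spatial_catch = pd.DataFrame(
        spatial_rows, columns=["species_id", "cell_id", "year", "tonnes"]
    )
    countries = sorted({r.grouping_country for r in regions})
    prices, cpi = gen_prices(
        sorted(share_fractions), countries, spec.years,
        np.random.default_rng(s_price), missing_rate=spec.price_missing_rate,
    )
    return SyntheticWorld(
        spec=spec, regions=regions, grid=grid, mosaic_adjacency=adjacency,
        ranges=ranges, layers=layers, catch=catch, spatial_catch=spatial_catch,
        prices=prices, cpi=cpi, truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization


def presence_frame(world: SyntheticWorld) -> pd.DataFrame:
    rows = [
        {"species_id": sid, "source": source, "cell_id": int(c)}
        for sid in world.species_ids
        for source, cells in sorted(world.layers[sid].items())
        for c in sorted(cells)
    ]
    return pd.DataFrame(rows, columns=["species_id", "source", "cell_id"])


def write_world(world: SyntheticWorld, outdir) -> dict:
    """Write every world artifact as plain text; returns path mapping."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "regions": out / "regions.geojson",
        "cells": out / "cells.csv",
        "presence": out / "presence.csv",
        "catch": out / "catch.csv",
        "spatial_catch": out / "spatial_catch.csv",
        "prices": out / "prices.csv",
        "cpi": out / "cpi.csv",
        "ground_truth": out / "ground_truth.json",
        "world_spec": out / "world_spec.json",
    }
    world.regions.write_geojson(paths["regions"])
    world.grid.to_frame().to_csv(paths["cells"], index=False)
    presence_frame(world).to_csv(paths["presence"], index=False)
    world.catch.to_csv(paths["catch"], index=False)
    world.spatial_catch.to_csv(paths["spatial_catch"], index=False)
    world.prices.to_csv(paths["prices"], index=False)
    world.cpi.to_csv(paths["cpi"], index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(world.truth.to_json(), fh, indent=1, sort_keys=True)
    spec_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(world.spec).items()
        if k not in ("share_fractions", "trend_categories")
    }
    with open(paths["world_spec"], "w") as fh:
        json.dump(spec_dict, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
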