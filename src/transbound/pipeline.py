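"""End-to-end orchestration: synth -> spatial -> consensus -> classify ->
trends -> accounting, with a config, manifest and deterministic outputs."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accounting, classifier, consensus, spatial, synth, trends


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    # either a directory with pre-generated world artifacts ...
    world_dir: str | None = None
    # ... or synthetic-world parameters
    n_regions: int = 6
    n_species: int = 10
    agreement: float = 1.0
    bbox: tuple = (0.0, 0.0, 10.0, 10.0)
    resolution: float = 0.5
    threshold: float = 0.25
    window: tuple = (2005, 2014)
    area_weighting: str = "km2"
    adjacency_predicate: str = "touch"
    usd_target_year: int = 2019
    sweep_thresholds: tuple = ()

    def __post_init__(self):
        if not 0 < self.threshold <= 0.5:
            raise ValueError(f"threshold must be in (0, 0.5], got {self.threshold}")
        if self.area_weighting not in ("km2", "count"):
            raise ValueError(f"unknown area_weighting {self.area_weighting!r}")
        if self.window[0] > self.window[1]:
            raise ValueError(f"bad window {self.window!r}")
        self.bbox = tuple(float(v) for v in self.bbox)
        self.window = (int(self.window[0]), int(self.window[1]))
        self.sweep_thresholds = tuple(float(t) for t in self.sweep_thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bbox"] = list(self.bbox)
        d["window"] = list(self.window)
        d["sweep_thresholds"] = list(self.sweep_thresholds)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _bbox_from_regions(regions: spatial.RegionSet, resolution: float) -> tuple:
    import shapely

    union = shapely.unary_union(list(regions.polygons.values()))
    minx, miny, maxx, maxy = union.bounds
    snap = lambda v: round(v / resolution) * resolution  # noqa: E731
    return (snap(minx), snap(miny), snap(maxx), snap(maxy))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write all artifacts under ``config.out_dir``, and
    return the manifest (also written as ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "inputs": {}, "stages": {}}

    # stage 0: obtain the world
    if config.world_dir is None:
        spec = synth.WorldSpec(
            seed=config.seed,
            n_regions=config.n_regions,
            bbox=config.bbox,
            grid_resolution=config.resolution,
            n_species=config.n_species,
            source_agreement_rate=config.agreement,
            window=config.window,
            ai_threshold=config.threshold,
        )
        world = synth.generate_world(spec)
        world_dir = out / "world"
        synth.write_world(world, world_dir)
    else:
        world_dir = Path(config.world_dir)
    for name in ("regions.geojson", "presence.csv", "catch.csv",
                 "spatial_catch.csv", "prices.csv", "cpi.csv"):
        p = world_dir / name
        if not p.exists():
            raise FileNotFoundError(f"stage input missing: {p}")
        manifest["inputs"][name] = _sha256(p)

    # stage 1: spatial model
    regions = spatial.RegionSet.from_geojson(world_dir / "regions.geojson")
    bbox = _bbox_from_regions(regions, config.resolution)
    grid = spatial.build_grid(bbox, config.resolution)
    spatial.assign_cells(grid, regions)
    graph = spatial.build_neighbor_graph(regions, config.adjacency_predicate)
    cells_df = grid.to_frame()
    cells_df.to_csv(out / "cell_assignment.csv", index=False)
    graph.to_frame().to_csv(out / "neighbor_edges.csv", index=False)
    manifest["stages"]["spatial"] = {
        "n_cells": grid.n_cells,
        "n_regions": len(regions),
        "n_edges": len(graph.edges),
        "n_usable_edges": len(graph.usable_edges()),
    }

    # stage 2: consensus
    presence = pd.read_csv(world_dir / "presence.csv")
    spatial_catch = pd.read_csv(world_dir / "spatial_catch.csv")
    layer_map = consensus.layers_from_frame(presence)
    ranges: dict[str, consensus.ConsensusRange] = {}
    empty_species = []
    for sid in sorted(layer_map):
        sub = spatial_catch[spatial_catch["species_id"] == sid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cr = consensus.consensus(sid, layer_map[sid], sub, config.window)
        if cr.cells:
            ranges[sid] = cr
        else:
            empty_species.append(sid)
    consensus.consensus_frame(ranges.values()).to_csv(
        out / "consensus.csv", index=False
    )
    manifest["stages"]["consensus"] = {
        "n_species": len(ranges),
        "n_empty_dropped": len(empty_species),
        "empty_species": empty_species,
    }

    # stage 3: classification
    assignment = classifier.CellAssignment.from_grid(grid)
    catch = pd.read_csv(world_dir / "catch.csv")
    catch_regions = catch.groupby("species_id")["region_id"].agg(set).to_dict()
    results = []
    for sid, cr in sorted(ranges.items()):
        results.append(
            classifier.classify(
                sid, cr, graph, assignment,
                threshold=config.threshold,
                area_weighting=config.area_weighting,
                extra_regions=catch_regions.get(sid, set()),
            )
        )
    cls_df = classifier.classification_frame(results)
    ai_df = classifier.area_index_frame(results)
    cls_df.to_csv(out / "classification.csv", index=False)
    ai_df.to_csv(out / "area_index.csv", index=False)
    n_trans = sum(r.species_label == classifier.TRANSBOUNDARY for r in results)
    manifest["stages"]["classification"] = {
        "n_species": len(results),
        "n_transboundary_species": n_trans,
        "n_discrete_species": len(results) - n_trans,
        "n_pairs_evaluated": len(ai_df),
    }
    if config.sweep_thresholds:
        sweep = classifier.threshold_sweep(
            {sid: cr for sid, cr in ranges.items()}, graph, assignment,
            sorted(config.sweep_thresholds), config.area_weighting,
        )
        sweep.to_csv(out / "threshold_sweep.csv", index=False)
        manifest["stages"]["threshold_sweep"] = sweep.to_dict("records")

    # stage 4: catch trends
    catch_analyzed = catch[catch["species_id"].isin(ranges)]
    trend_df = trends.assess_catch_table(catch_analyzed, config.window)
    trend_df.to_csv(out / "trend_assessment.csv", index=False)
    manifest["stages"]["trends"] = {
        "n_stocks": len(trend_df),
        "by_category": trend_df.groupby("predominant").size().to_dict(),
    }

    # stage 5: accounting
    prices = pd.read_csv(world_dir / "prices.csv")
    cpi_df = pd.read_csv(world_dir / "cpi.csv")
    cpi = accounting.cpi_table_from_frame(cpi_df)
    region_country = {
        r.region_id: r.grouping_country for r in regions
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rev_df, fill_report = accounting.revenue_table(
            catch_analyzed, prices, cpi, region_country,
            window=config.window, target_year=config.usd_target_year,
        )
    stock_table = accounting.stock_account_table(
        cls_df, catch_analyzed, rev_df, config.window
    )
    region_areas = (
        cells_df.dropna(subset=["region_id"])
        .groupby("region_id")["area_km2"].sum().to_dict()
    )
    class_totals = accounting.partition_by_stock_class(stock_table, region_areas)
    meta = regions.metadata_frame()
    meta["area_km2"] = pd.Series(region_areas)  # grid-consistent areas
    countries, subregions = accounting.regional_rollup(stock_table, meta)
    rev_df.to_csv(out / "revenue.csv", index=False)
    stock_table.to_csv(out / "stock_accounts.csv", index=False)
    class_totals.to_csv(out / "class_totals.csv", index=False)
    countries.to_csv(out / "country_accounts.csv", index=False)
    subregions.to_csv(out / "subregion_accounts.csv", index=False)
    report = accounting.summary_report(
        class_totals, countries, n_trans, len(results) - n_trans
    )
    (out / "summary.txt").write_text(report)
    manifest["stages"]["accounting"] = {
        "n_stock_rows": len(stock_table),
        "price_fill": vars(fill_report),
        "total_mean_catch": float(class_totals["mean_annual_catch"].sum()),
        "total_mean_revenue": float(class_totals["mean_annual_revenue"].sum()),
    }

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
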