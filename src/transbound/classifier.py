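"""Transboundary classification via pairwise Area Indices on the neighbor graph.

For every usable neighboring pair hosting part of a species' consensus range,
the Area Index of each region is its share of the pair's joint range area.  A
pair passes when both shares strictly exceed the threshold (default 25%); a
stock is transboundary when any incident pair passes, and a species when any
of its stocks is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusRange
from .spatial import Grid, NeighborGraph

DEFAULT_THRESHOLD = 0.25

TRANSBOUNDARY = "transboundary"
EXCLUDED_STOCK = "excluded_stock"
DISCRETE_STOCK = "discrete_stock"
DISCRETE = "discrete"


@dataclass(frozen=True)
class AreaIndexResult:
    species_id: str
    region_a: str
    region_b: str
    area_a_km2: float
    area_b_km2: float
    ai_a: float  # NaN when the joint area is zero
    ai_b: float
    passes: bool

    def mirrored(self) -> "AreaIndexResult":
        return AreaIndexResult(
            self.species_id,
            self.region_b,
            self.region_a,
            self.area_b_km2,
            self.area_a_km2,
            self.ai_b,
            self.ai_a,
            self.passes,
        )


@dataclass
class StockClassification:
    species_id: str
    region_id: str
    stock_label: str
    species_label: str
    supporting_pairs: list = field(default_factory=list)

    @property
    def best_min_ai(self) -> float:
        if not self.supporting_pairs:
            return float("nan")
        return max(min(p.ai_a, p.ai_b) for p in self.supporting_pairs)


@dataclass
class SpeciesClassification:
    species_id: str
    species_label: str
    stocks: dict  # region_id -> StockClassification
    pair_results: list  # AreaIndexResult per evaluated usable edge


class CellAssignment:
    """region_id and area per cell, the lookup the classifier works against."""

    def __init__(self, region_by_cell: Mapping, area_by_cell: Mapping):
        self.region_by_cell = dict(region_by_cell)
        self.area_by_cell = dict(area_by_cell)

    @classmethod
    def from_grid(cls, grid: Grid) -> "CellAssignment":
        return cls(
            dict(zip(grid.cell_id.tolist(), grid.region_id.tolist())),
            dict(zip(grid.cell_id.tolist(), grid.area_km2.tolist())),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellAssignment":
        region = df["region_id"].where(pd.notna(df["region_id"]), None)
        return cls(
            dict(zip(df["cell_id"], region)),
            dict(zip(df["cell_id"], df["area_km2"])),
        )

    def weight(self, cell_id, area_weighting: str) -> float:
        if area_weighting == "count":
            return 1.0
        return float(self.area_by_cell[cell_id])

    def region_areas(self, cells: Iterable, area_weighting: str = "km2") -> dict:
        """Range weight per region over the given cells; unassigned ignored."""
        out: dict = {}
        for c in cells:
            rid = self.region_by_cell.get(c)
            if rid is None:
                continue
            out[rid] = out.get(rid, 0.0) + self.weight(c, area_weighting)
        return out


def area_index(
    range_: ConsensusRange | Iterable,
    pair: tuple[str, str],
    assignment: CellAssignment,
    graph: NeighborGraph | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    area_weighting: str = "km2",
) -> AreaIndexResult:
    """Area Index of one usable neighboring pair for one species range.

    ``ai_a`` is the share of the joint (two-region) range area lying in region
    ``a``; the pair passes iff ``min(ai_a, ai_b) > threshold``.
    """
    rid_a, rid_b = pair
    if graph is not None:
        edge = graph.edge(rid_a, rid_b)
        if edge is None or not edge.usable:
            raise ValueError(
                f"pair ({rid_a}, {rid_b}) is not a usable neighboring edge"
                + (f" (reason: {edge.reason})" if edge is not None else "")
            )
    cells = range_.cells if isinstance(range_, ConsensusRange) else range_
    species_id = range_.species_id if isinstance(range_, ConsensusRange) else ""
    area_a = area_b = 0.0
    for c in cells:
        rid = assignment.region_by_cell.get(c)
        if rid == rid_a:
            area_a += assignment.weight(c, area_weighting)
        elif rid == rid_b:
            area_b += assignment.weight(c, area_weighting)
    joint = area_a + area_b
    if joint <= 0:
        return AreaIndexResult(
            species_id, rid_a, rid_b, area_a, area_b, math.nan, math.nan, False
        )
    ai_a = area_a / joint
    ai_b = area_b / joint
    passes = min(ai_a, ai_b) > threshold  # strictly over the threshold
    return AreaIndexResult(species_id, rid_a, rid_b, area_a, area_b, ai_a, ai_b, passes)


def classify(
    species_id: str,
    range_: ConsensusRange | Iterable,
    graph: NeighborGraph,
    assignment: CellAssignment,
    threshold: float = DEFAULT_THRESHOLD,
    area_weighting: str = "km2",
    extra_regions: Iterable = (),
) -> SpeciesClassification:
    """Label every stock (species x region) and the species itself.

    ``extra_regions`` lets callers include regions with recorded catch but no
    consensus cells (they become excluded or discrete stocks, never
    transboundary ones).
    """
    if not 0 < threshold <= 0.5:
        raise ValueError(f"threshold must be in (0, 0.5], got {threshold}")
    cells = range_.cells if isinstance(range_, ConsensusRange) else set(range_)
    cr = ConsensusRange(species_id=species_id, cells=frozenset(cells))
    per_region = assignment.region_areas(cells, area_weighting)
    occupied = set(per_region) | set(extra_regions)
    if not occupied:
        raise ValueError(f"species {species_id!r} is absent from all regions")

    pair_results: list[AreaIndexResult] = []
    passing_by_region: dict[str, list[AreaIndexResult]] = {}
    for edge in graph.usable_edges():
        a, b = sorted(edge.key)
        if per_region.get(a, 0.0) <= 0 and per_region.get(b, 0.0) <= 0:
            continue
        res = area_index(
            cr, (a, b), assignment, graph=graph,
            threshold=threshold, area_weighting=area_weighting,
        )
        pair_results.append(res)
        if res.passes:
            passing_by_region.setdefault(a, []).append(res)
            passing_by_region.setdefault(b, []).append(res.mirrored())

    species_label = TRANSBOUNDARY if passing_by_region else DISCRETE
    stocks = {}
    for rid in sorted(occupied):
        supporting = passing_by_region.get(rid, [])
        if supporting:
            label = TRANSBOUNDARY
        elif species_label == TRANSBOUNDARY:
            label = EXCLUDED_STOCK
        else:
            label = DISCRETE_STOCK
        stocks[rid] = StockClassification(
            species_id=species_id,
            region_id=rid,
            stock_label=label,
            species_label=species_label,
            supporting_pairs=supporting,
        )
    return SpeciesClassification(
        species_id=species_id,
        species_label=species_label,
        stocks=stocks,
        pair_results=pair_results,
    )


def classification_frame(results: Iterable[SpeciesClassification]) -> pd.DataFrame:
    rows = []
    for sc in results:
        for rid, stock in sorted(sc.stocks.items()):
            best = None
            if stock.supporting_pairs:
                best = max(
                    stock.supporting_pairs, key=lambda p: min(p.ai_a, p.ai_b)
                )
            rows.append(
                {
                    "species_id": sc.species_id,
                    "region_id": rid,
                    "stock_label": stock.stock_label,
                    "species_label": sc.species_label,
                    "best_pair": f"{best.region_a}|{best.region_b}" if best else "",
                    "best_min_ai": min(best.ai_a, best.ai_b) if best else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "region_id", "stock_label",
            "species_label", "best_pair", "best_min_ai",
        ],
    )


def area_index_frame(results: Iterable[SpeciesClassification]) -> pd.DataFrame:
    rows = [
        {
            "species_id": res.species_id,
            "region_a": res.region_a,
            "region_b": res.region_b,
            "area_a_km2": res.area_a_km2,
            "area_b_km2": res.area_b_km2,
            "ai_a": res.ai_a,
            "ai_b": res.ai_b,
            "passes": res.passes,
        }
        for sc in results
        for res in sc.pair_results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "region_a", "region_b", "area_a_km2",
            "area_b_km2", "ai_a", "ai_b", "passes",
        ],
    )


def threshold_sweep(
    ranges: Mapping[str, ConsensusRange | Iterable],
    graph: NeighborGraph,
    assignment: CellAssignment,
    thresholds: Sequence[float],
    area_weighting: str = "km2",
) -> pd.DataFrame:
    """Transboundary species counts per threshold (non-increasing by identity).

    ``thresholds`` must be sorted ascending within (0, 0.5].
    """
    ts = list(thresholds)
    if ts != sorted(ts):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in ts:
        n = 0
        for sid, rng in ranges.items():
            cells = rng.cells if isinstance(rng, ConsensusRange) else rng
            if not cells:
                continue
            sc = classify(
                sid, rng, graph, assignment,
                threshold=t, area_weighting=area_weighting,
            )
            n += sc.species_label == TRANSBOUNDARY
        rows.append({"threshold": t, "n_transboundary_species": n})
    return pd.DataFrame(rows)
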