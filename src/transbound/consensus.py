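"""Four-source presence consensus with the window catch-positivity filter.

A cell belongs to a species' consensus range only when every presence source
agrees and the cell recorded strictly positive catch in at least one year of
the reference window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

SOURCES = ("occurrence", "enm", "sdm", "catch")
DEFAULT_WINDOW = (2005, 2014)


class MissingSourceError(ValueError):
    """A species lacks one or more of the four required presence sources."""


@dataclass(frozen=True)
class PresenceLayer:
    species_id: str
    source: str
    cells: frozenset

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown presence source {self.source!r}")


@dataclass
class ConsensusRange:
    species_id: str
    cells: frozenset
    # supporting sources per consensus cell (always all four by construction)
    provenance: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.cells)


def _positive_catch_cells(
    catch_by_cell_year, window: Sequence[int]
) -> set:
    """Cells with strictly positive catch in >= 1 year inside the window."""
    lo, hi = int(window[0]), int(window[1])
    if isinstance(catch_by_cell_year, pd.DataFrame):
        df = catch_by_cell_year
        mask = (df["year"] >= lo) & (df["year"] <= hi) & (df["tonnes"] > 0)
        return set(df.loc[mask, "cell_id"])
    cells = set()
    for (cell_id, year), tonnes in catch_by_cell_year.items():
        if lo <= year <= hi and tonnes > 0:
            cells.add(cell_id)
    return cells


def consensus(
    species_id: str,
    layers: Iterable[PresenceLayer],
    catch_by_cell_year,
    window: Sequence[int] = DEFAULT_WINDOW,
) -> ConsensusRange:
    """Intersect the four presence layers and apply the catch filter.

    Parameters
    ----------
    layers
        Exactly one :class:`PresenceLayer` per source in :data:`SOURCES`.
    catch_by_cell_year
        Either a DataFrame with columns ``cell_id, year, tonnes`` (already
        restricted to this species) or a mapping ``(cell_id, year) -> tonnes``.
    window
        Inclusive year range for the catch-positivity rule.
    """
    by_source: dict[str, PresenceLayer] = {}
    for layer in layers:
        if layer.species_id != species_id:
            raise ValueError(
                f"layer for {layer.species_id!r} supplied to consensus of "
                f"{species_id!r}"
            )
        if layer.source in by_source:
            raise ValueError(f"duplicate source {layer.source!r}")
        by_source[layer.source] = layer
    missing = [s for s in SOURCES if s not in by_source]
    if missing:
        raise MissingSourceError(
            f"species {species_id!r} is missing presence sources {missing}; "
            "only species with data from all four sources are analyzed"
        )

    cells = frozenset.intersection(*(by_source[s].cells for s in SOURCES))
    cells &= _positive_catch_cells(catch_by_cell_year, window)
    if not cells:
        warnings.warn(
            f"species {species_id!r}: empty consensus range; "
            "species will be excluded downstream",
            stacklevel=2,
        )
    provenance = {c: SOURCES for c in cells}
    return ConsensusRange(species_id=species_id, cells=frozenset(cells), provenance=provenance)


def consensus_frame(ranges: Iterable[ConsensusRange]) -> pd.DataFrame:
    rows = [
        {"species_id": r.species_id, "cell_id": c, "n_supporting_sources": len(r.provenance[c])}
        for r in ranges
        for c in sorted(r.cells)
    ]
    return pd.DataFrame(rows, columns=["species_id", "cell_id", "n_supporting_sources"])


def layers_from_frame(df: pd.DataFrame) -> dict[str, list[PresenceLayer]]:
    """Group a long presence table (species_id, source, cell_id) into layers."""
    out: dict[str, list[PresenceLayer]] = {}
    for (species_id, source), sub in df.groupby(["species_id", "source"], sort=True):
        out.setdefault(species_id, []).append(
            PresenceLayer(species_id, source, frozenset(sub["cell_id"]))
        )
    return out
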