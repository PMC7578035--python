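"""Catch-trend categorization per species x EEZ.

Each data year is labeled A (increasing), B (constant), C (decreasing) or
unassigned from the series' historical maximum and post-maximum minimum, with
precedence B -> A -> C; the predominant label over the reference window
summarizes the stock.  Series with fewer than ten data years in 1951-2014 or
without five consecutive data years are ineligible ("No Category").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

YEAR_MIN, YEAR_MAX = 1951, 2014
DEFAULT_WINDOW = (2005, 2014)
MIN_YEARS = 10
MIN_CONSECUTIVE = 5

CAT_A, CAT_B, CAT_C = "A", "B", "C"
UNASSIGNED = "unassigned"
NO_CATEGORY = "NoCategory"

# reasons a series ends up without a category
REASON_INELIGIBLE = "ineligible"
REASON_NO_CATEGORIZED_YEARS = "no-categorized-window-years"


@dataclass(frozen=True)
class CatchSeries:
    species_id: str
    region_id: str
    years: tuple
    catch: tuple

    def __post_init__(self):
        years = np.asarray(self.years)
        if len(years) != len(self.catch):
            raise ValueError("years and catch must align")
        if len(years) and not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")
        if np.any(np.asarray(self.catch) < 0):
            raise ValueError("catches must be non-negative")

    @classmethod
    def from_mapping(cls, species_id, region_id, by_year) -> "CatchSeries":
        years = tuple(sorted(by_year))
        return cls(species_id, region_id, years, tuple(float(by_year[y]) for y in years))

    def as_dict(self) -> dict:
        return dict(zip(self.years, self.catch))


@dataclass
class TrendStats:
    max_catch: float
    year_of_max: int  # earliest year attaining the maximum
    last_year: int
    post_max_min: float | None  # over years strictly after year_of_max
    year_of_post_max_min: int | None
    degenerate: bool = False  # all-zero series


@dataclass
class TrendAssessment:
    series: CatchSeries
    stats: TrendStats | None
    eligible: bool
    per_year: dict = field(default_factory=dict)  # year -> A/B/C/unassigned
    predominant: str = NO_CATEGORY
    reason: str | None = None


def derive_stats(series: CatchSeries) -> TrendStats:
    """Max and post-max-min statistics by linear scan; ties take the earliest year."""
    if not series.years:
        raise ValueError("empty catch series")
    years = np.asarray(series.years)
    catch = np.asarray(series.catch, dtype=float)
    i_max = int(np.argmax(catch))  # argmax returns first occurrence
    max_catch = float(catch[i_max])
    year_of_max = int(years[i_max])
    after = years > year_of_max
    if after.any():
        j = int(np.argmin(catch[after]))
        post_max_min = float(catch[after][j])
        year_of_post_max_min = int(years[after][j])
    else:
        post_max_min = None
        year_of_post_max_min = None
    return TrendStats(
        max_catch=max_catch,
        year_of_max=year_of_max,
        last_year=int(years[-1]),
        post_max_min=post_max_min,
        year_of_post_max_min=year_of_post_max_min,
        degenerate=max_catch == 0.0,
    )


def categorize_year(year: int, catch: float, stats: TrendStats) -> str:
    """Label one data year; precedence B, then A, then C.

    B: catch above half the historical maximum.
    A: maximum in the final data year, or a pre-peak year at or below half the
       maximum, or rebuilding after a collapse below 10% of the maximum.
    C: post-peak year below half the maximum (no rebuilding clause applies).
    """
    if stats.degenerate:
        return UNASSIGNED
    m = stats.max_catch
    if catch > 0.5 * m:
        return CAT_B
    rebuilding = (
        stats.post_max_min is not None
        and year > stats.year_of_post_max_min
        and stats.post_max_min < 0.10 * m
        and 0.10 * m < catch < 0.50 * m
    )
    if (
        stats.year_of_max == stats.last_year
        or (year < stats.year_of_max and catch <= 0.50 * m)
        or rebuilding
    ):
        return CAT_A
    if year > stats.year_of_max and (
        catch < 0.10 * m or 0.10 * m < catch < 0.50 * m
    ):
        return CAT_C
    return UNASSIGNED


def is_eligible(series: CatchSeries) -> bool:
    years = [y for y in series.years if YEAR_MIN <= y <= YEAR_MAX]
    if len(years) < MIN_YEARS:
        return False
    longest = run = 1
    for prev, cur in zip(years, years[1:]):
        run = run + 1 if cur == prev + 1 else 1
        longest = max(longest, run)
    return longest >= MIN_CONSECUTIVE


def predominant_category(
    series: CatchSeries, window: Sequence[int] = DEFAULT_WINDOW
) -> TrendAssessment:
    """Modal per-year category over window data years; ties break to the
    category of the latest categorized window year among the tied leaders."""
    if not series.years:
        return TrendAssessment(series, None, False, predominant=NO_CATEGORY,
                               reason=REASON_INELIGIBLE)
    stats = derive_stats(series)
    eligible = is_eligible(series)
    per_year = {
        y: categorize_year(y, c, stats) for y, c in zip(series.years, series.catch)
    }
    if not eligible:
        return TrendAssessment(series, stats, False, per_year, NO_CATEGORY,
                               REASON_INELIGIBLE)
    lo, hi = int(window[0]), int(window[1])
    votes = [(y, per_year[y]) for y in series.years
             if lo <= y <= hi and per_year[y] != UNASSIGNED]
    if not votes:
        return TrendAssessment(series, stats, True, per_year, NO_CATEGORY,
                               REASON_NO_CATEGORIZED_YEARS)
    counts: dict[str, int] = {}
    for _, cat in votes:
        counts[cat] = counts.get(cat, 0) + 1
    top = max(counts.values())
    leaders = {cat for cat, n in counts.items() if n == top}
    if len(leaders) == 1:
        predominant = leaders.pop()
    else:
        predominant = next(cat for _, cat in reversed(votes) if cat in leaders)
    return TrendAssessment(series, stats, True, per_year, predominant)


def assess_catch_table(
    catch: pd.DataFrame, window: Sequence[int] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Run the assessment for every species x region in a long catch table.

    ``catch`` columns: species_id, region_id, year, tonnes.
    """
    rows = []
    for (sid, rid), sub in catch.groupby(["species_id", "region_id"], sort=True):
        by_year = dict(zip(sub["year"].astype(int), sub["tonnes"].astype(float)))
        series = CatchSeries.from_mapping(sid, rid, by_year)
        ta = predominant_category(series, window)
        rows.append(
            {
                "species_id": sid,
                "region_id": rid,
                "n_years": len(series.years),
                "eligible": ta.eligible,
                "max_catch": ta.stats.max_catch if ta.stats else np.nan,
                "year_of_max": ta.stats.year_of_max if ta.stats else np.nan,
                "post_max_min": (
                    ta.stats.post_max_min
                    if ta.stats and ta.stats.post_max_min is not None
                    else np.nan
                ),
                "predominant": ta.predominant,
                "per_year": ";".join(
                    f"{y}:{ta.per_year[y]}" for y in series.years
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "region_id", "n_years", "eligible", "max_catch",
            "year_of_max", "post_max_min", "predominant", "per_year",
        ],
    )
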