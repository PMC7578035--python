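"""Catch and ex-vessel revenue accounting by stock class, country and UN sub-region.

Revenue is catch times ex-vessel price (2010 real USD), standardized to a
target year with a CPI table.  Window means divide by the number of window
years, so missing years count as zero.  Price gaps are filled nearest-year
within species x country, then by the species' cross-country mean, and
otherwise dropped with a warning count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import DISCRETE_STOCK, EXCLUDED_STOCK, TRANSBOUNDARY
from .trends import CatchSeries

PRICE_BASE_YEAR = 2010
DEFAULT_TARGET_YEAR = 2019
DEFAULT_WINDOW = (2005, 2014)

STOCK_CLASSES = (TRANSBOUNDARY, EXCLUDED_STOCK, DISCRETE_STOCK)


def cpi_adjust(value: float, from_year: int, to_year: int, cpi: Mapping) -> float:
    """Re-express ``value`` (USD of ``from_year``) in USD of ``to_year``."""
    for y in (from_year, to_year):
        if y not in cpi:
            raise KeyError(f"CPI table is missing year {y}")
    return value * cpi[to_year] / cpi[from_year]


def cpi_table_from_frame(df: pd.DataFrame) -> dict[int, float]:
    """CPI mapping from a table with either annual or monthly rows.

    Annual index = mean of monthly values when a ``month`` column is present.
    """
    if "month" in df.columns:
        grouped = df.groupby("year")["cpi"].mean()
    else:
        grouped = df.set_index("year")["cpi"]
    return {int(y): float(v) for y, v in grouped.items()}


@dataclass
class PriceFillReport:
    n_exact: int = 0
    n_nearest_year: int = 0
    n_country_mean: int = 0
    n_dropped: int = 0


def fill_prices(
    prices: pd.DataFrame,
    needed: Iterable[tuple[str, str, int]],
) -> tuple[pd.DataFrame, PriceFillReport]:
    """Resolve a price for every needed (species_id, country_id, year).

    Fallback order: exact match, nearest year within the species x country,
    the species' cross-country mean at the (nearest) year, else dropped.
    Returns a table with a ``fill_method`` column and a fill report.
    """
    report = PriceFillReport()
    by_pair: dict[tuple[str, str], dict[int, float]] = {}
    for row in prices.itertuples(index=False):
        by_pair.setdefault((row.species_id, row.country_id), {})[int(row.year)] = float(row.price)
    by_species: dict[str, dict[int, list[float]]] = {}
    for (sid, _), years in by_pair.items():
        acc = by_species.setdefault(sid, {})
        for y, p in years.items():
            acc.setdefault(y, []).append(p)

    rows = []
    for sid, cid, year in needed:
        year = int(year)
        pair = by_pair.get((sid, cid), {})
        if year in pair:
            price, method = pair[year], "exact"
            report.n_exact += 1
        elif pair:
            nearest = min(pair, key=lambda y: (abs(y - year), y))
            price, method = pair[nearest], "nearest_year"
            report.n_nearest_year += 1
        elif sid in by_species:
            sp_years = by_species[sid]
            nearest = min(sp_years, key=lambda y: (abs(y - year), y))
            price, method = float(np.mean(sp_years[nearest])), "country_mean"
            report.n_country_mean += 1
        else:
            report.n_dropped += 1
            continue
        rows.append(
            {"species_id": sid, "country_id": cid, "year": year,
             "price": price, "fill_method": method}
        )
    if report.n_dropped:
        warnings.warn(
            f"{report.n_dropped} species x country x year rows had no "
            "resolvable ex-vessel price and were dropped",
            stacklevel=2,
        )
    return (
        pd.DataFrame(rows, columns=["species_id", "country_id", "year", "price", "fill_method"]),
        report,
    )


def revenue(
    catch: CatchSeries,
    price_by_year: Mapping[int, float],
    cpi: Mapping,
    window: Sequence[int] = DEFAULT_WINDOW,
    target_year: int = DEFAULT_TARGET_YEAR,
    price_base_year: int = PRICE_BASE_YEAR,
) -> tuple[dict[int, float], float]:
    """Annual revenue series (target-year USD) and its window mean.

    The mean divides by the number of window years; years without data count
    as zero revenue.
    """
    factor = cpi[target_year] / cpi[price_base_year]
    annual = {
        y: c * price_by_year[y] * factor for y, c in zip(catch.years, catch.catch)
    }
    lo, hi = int(window[0]), int(window[1])
    n_window = hi - lo + 1
    window_mean = sum(v for y, v in annual.items() if lo <= y <= hi) / n_window
    return annual, window_mean


def revenue_table(
    catch: pd.DataFrame,
    prices: pd.DataFrame,
    cpi: Mapping,
    region_country: Mapping[str, str],
    window: Sequence[int] = DEFAULT_WINDOW,
    target_year: int = DEFAULT_TARGET_YEAR,
    price_base_year: int = PRICE_BASE_YEAR,
) -> tuple[pd.DataFrame, PriceFillReport]:
    """Per species x region x year revenue in target-year USD.

    ``catch`` columns: species_id, region_id, year, tonnes.  Prices are per
    species x country, so regions are mapped to countries first.
    """
    catch = catch.copy()
    catch["country_id"] = catch["region_id"].map(lambda r: region_country[r])
    needed = sorted(
        {(r.species_id, r.country_id, int(r.year)) for r in catch.itertuples(index=False)}
    )
    filled, report = fill_prices(prices, needed)
    merged = catch.merge(filled, on=["species_id", "country_id", "year"], how="left")
    merged = merged.dropna(subset=["price"])
    factor = cpi[target_year] / cpi[price_base_year]
    merged["revenue"] = merged["tonnes"] * merged["price"] * factor
    cols = ["species_id", "region_id", "year", "tonnes", "revenue"]
    return merged[cols].reset_index(drop=True), report


@dataclass
class AccountRow:
    key: str
    mean_annual_catch: float
    mean_annual_revenue: float
    area_km2: float = np.nan
    n_members: int = 1
    sd_flag: bool = False  # True when sd is from a single member (reported 0)

    @property
    def catch_per_km2(self) -> float:
        return self.mean_annual_catch / self.area_km2

    @property
    def revenue_per_km2(self) -> float:
        return self.mean_annual_revenue / self.area_km2


def _window_mean(df: pd.DataFrame, col: str, window: Sequence[int]) -> pd.DataFrame:
    lo, hi = int(window[0]), int(window[1])
    n = hi - lo + 1
    sub = df[(df["year"] >= lo) & (df["year"] <= hi)]
    out = (
        sub.groupby(["species_id", "region_id"], sort=True)[col]
        .sum()
        .div(n)
        .rename(f"mean_{col}")
        .reset_index()
    )
    return out


def stock_account_table(
    classification: pd.DataFrame,
    catch: pd.DataFrame,
    revenue_df: pd.DataFrame,
    window: Sequence[int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Window-mean catch and revenue per stock, joined to its class label.

    Raises when a stock with catch has no classification row.
    """
    cm = _window_mean(catch, "tonnes", window)
    rm = _window_mean(revenue_df, "revenue", window)
    table = cm.merge(rm, on=["species_id", "region_id"], how="outer").fillna(0.0)
    cls = classification[["species_id", "region_id", "stock_label", "species_label"]]
    table = table.merge(cls, on=["species_id", "region_id"], how="left")
    missing = table[table["stock_label"].isna()]
    if len(missing):
        first = missing.iloc[0]
        raise ValueError(
            f"unclassified stock encountered: species {first['species_id']!r} "
            f"in region {first['region_id']!r} (+{len(missing) - 1} more)"
        )
    return table.rename(
        columns={"mean_tonnes": "mean_catch", "mean_revenue": "mean_revenue"}
    )


def partition_by_stock_class(
    stock_table: pd.DataFrame,
    region_areas: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Totals per stock class; classes are exhaustive so totals conserve."""
    rows = []
    for label in STOCK_CLASSES:
        sub = stock_table[stock_table["stock_label"] == label]
        area = np.nan
        if region_areas is not None:
            area = float(sum(region_areas[r] for r in sub["region_id"].unique()))
        rows.append(
            {
                "stock_class": label,
                "mean_annual_catch": float(sub["mean_catch"].sum()),
                "mean_annual_revenue": float(sub["mean_revenue"].sum()),
                "n_stocks": int(len(sub)),
                "area_km2": area,
            }
        )
    return pd.DataFrame(rows)


def regional_rollup(
    stock_table: pd.DataFrame,
    region_metadata: pd.DataFrame,
    stock_label: str = TRANSBOUNDARY,
    sd_ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Country and UN sub-region accounts for one stock class.

    Country rows sum their regions' window-mean catch and revenue; the per-km2
    denominator is the summed area of EEZ regions hosting at least one stock
    of the class.  Sub-region rows report mean and (sample) sd across member
    countries; a one-country group carries ``sd_flag`` and sd 0.
    """
    meta = region_metadata
    for col in ("grouping_country", "un_subregion", "area_km2"):
        if col not in meta.columns:
            raise ValueError(f"region metadata lacks column {col!r}")
    if (meta["un_subregion"].astype(str) == "").any():
        bad = meta.index[meta["un_subregion"].astype(str) == ""][0]
        raise ValueError(f"unknown sub-region label for region {bad!r}")

    sub = stock_table[stock_table["stock_label"] == stock_label].copy()
    sub["country_id"] = sub["region_id"].map(meta["grouping_country"])

    host_regions = sub.loc[:, ["region_id", "country_id"]].drop_duplicates()
    host_regions["area_km2"] = host_regions["region_id"].map(meta["area_km2"])

    country_rows = []
    for cid, grp in sub.groupby("country_id", sort=True):
        area = float(
            host_regions.loc[host_regions["country_id"] == cid, "area_km2"].sum()
        )
        # species present in several sub-regions of one country count once
        n_species = grp["species_id"].nunique()
        catch_total = float(grp["mean_catch"].sum())
        rev_total = float(grp["mean_revenue"].sum())
        country_rows.append(
            {
                "country_id": cid,
                "un_subregion": _country_subregion(meta, cid),
                "n_species": n_species,
                "mean_annual_catch": catch_total,
                "mean_annual_revenue": rev_total,
                "area_km2": area,
                "catch_per_km2": catch_total / area if area else np.nan,
                "revenue_per_km2": rev_total / area if area else np.nan,
            }
        )
    countries = pd.DataFrame(
        country_rows,
        columns=[
            "country_id", "un_subregion", "n_species", "mean_annual_catch",
            "mean_annual_revenue", "area_km2", "catch_per_km2", "revenue_per_km2",
        ],
    )

    sub_rows = []
    for name, grp in countries.groupby("un_subregion", sort=True):
        single = len(grp) < 2
        def _sd(col):
            return 0.0 if single else float(grp[col].std(ddof=sd_ddof))
        sub_rows.append(
            {
                "un_subregion": name,
                "n_countries": int(len(grp)),
                "mean_revenue": float(grp["mean_annual_revenue"].mean()),
                "sd_revenue": _sd("mean_annual_revenue"),
                "mean_catch": float(grp["mean_annual_catch"].mean()),
                "sd_catch": _sd("mean_annual_catch"),
                "mean_revenue_per_km2": float(grp["revenue_per_km2"].mean()),
                "sd_revenue_per_km2": _sd("revenue_per_km2"),
                "mean_catch_per_km2": float(grp["catch_per_km2"].mean()),
                "sd_catch_per_km2": _sd("catch_per_km2"),
                "area_km2": float(grp["area_km2"].sum()),
                "sd_flag": single,
            }
        )
    subregions = pd.DataFrame(
        sub_rows,
        columns=[
            "un_subregion", "n_countries", "mean_revenue", "sd_revenue",
            "mean_catch", "sd_catch", "mean_revenue_per_km2", "sd_revenue_per_km2",
            "mean_catch_per_km2", "sd_catch_per_km2", "area_km2", "sd_flag",
        ],
    )
    return countries, subregions


def _country_subregion(meta: pd.DataFrame, country_id: str) -> str:
    labels = meta.loc[meta["grouping_country"] == country_id, "un_subregion"].unique()
    if len(labels) == 0:
        raise ValueError(f"unknown sub-region label for country {country_id!r}")
    return str(labels[0])


def summary_report(
    class_totals: pd.DataFrame,
    countries: pd.DataFrame,
    n_transboundary: int,
    n_discrete: int,
) -> str:
    """Plain-text headline summary: totals, shares, top-5 countries."""
    total_catch = class_totals["mean_annual_catch"].sum()
    total_rev = class_totals["mean_annual_revenue"].sum()
    lines = [
        "Transboundary analysis summary",
        "==============================",
        f"transboundary species: {n_transboundary}",
        f"discrete species:      {n_discrete}",
        "",
        "Mean annual accounts by stock class (window mean):",
    ]
    for row in class_totals.itertuples(index=False):
        catch_share = 100 * row.mean_annual_catch / total_catch if total_catch else 0.0
        rev_share = 100 * row.mean_annual_revenue / total_rev if total_rev else 0.0
        lines.append(
            f"  {row.stock_class:<22s} catch {row.mean_annual_catch:14.2f} t "
            f"({catch_share:5.1f}%)  revenue {row.mean_annual_revenue:16.2f} USD "
            f"({rev_share:5.1f}%)"
        )
    top = countries.sort_values("mean_annual_revenue", ascending=False).head(5)
    lines += ["", "Top 5 countries by transboundary revenue:"]
    for row in top.itertuples(index=False):
        lines.append(
            f"  {row.country_id:<12s} {row.mean_annual_revenue:16.2f} USD "
            f"{row.mean_annual_catch:14.2f} t"
        )
    return "\n".join(lines) + "\n"
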