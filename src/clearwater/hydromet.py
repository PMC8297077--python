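"""Hydrological and meteorological summaries.

HRT from storage and outflow, season/year aggregation of daily hydrology,
summer precipitation share, and basin descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class HydroError(ValueError):
    pass


class UndefinedHRTError(HydroError):
    """Raised when HRT is undefined (non-positive outflow)."""


#: month -> season label; winter spans the year boundary
DEFAULT_SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

SECONDS_PER_DAY = 86400.0


def compute_hrt(storage: float, outflow: float) -> float:
    """Hydraulic retention time in days: storage / outflow.

    storage in m^3, outflow in m^3 s^-1. Non-positive outflow raises
    UndefinedHRTError (HRT is flagged undefined, never infinite).
    """
    if storage <= 0:
        raise HydroError("storage must be > 0")
    if outflow <= 0:
        raise UndefinedHRTError("HRT undefined for outflow <= 0")
    return storage / (outflow * SECONDS_PER_DAY)


def hrt_series(storage: np.ndarray, outflow: np.ndarray) -> np.ndarray:
    """Vectorized HRT with NaN where outflow <= 0 (undefined, excluded from
    means downstream)."""
    storage = np.asarray(storage, dtype=float)
    outflow = np.asarray(outflow, dtype=float)
    out = np.full(storage.shape, np.nan)
    ok = outflow > 0
    out[ok] = storage[ok] / (outflow[ok] * SECONDS_PER_DAY)
    return out


@dataclass
class HydroSummary:
    period: str            # e.g. "2015", "summer", "summer 2015", "all"
    mean_hrt: float        # d
    total_precip: float    # mm
    mean_inflow: float     # m^3 s^-1
    mean_outflow: float    # m^3 s^-1
    n_days: int


def _season_year(dates: pd.Series, seasons: dict[int, str]) -> tuple[pd.Series, pd.Series]:
    months = dates.dt.month
    season = months.map(seasons)
    # winter is attributed to the year containing its January
    year = dates.dt.year + ((season == "winter") & (months == 12)).astype(int)
    return season, year


def seasonal_summary(
    daily: pd.DataFrame,
    seasons: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Season-year, pooled-season, annual, and whole-period summaries.

    ``daily`` needs columns date, precipitation, inflow, outflow and either
    hrt or storage (from which HRT is derived). Means ignore undefined
    (NaN-flagged) HRT values.
    """
    if len(daily) == 0:
        raise HydroError("empty daily series")
    seasons = seasons or DEFAULT_SEASONS
    if set(seasons) != set(range(1, 13)):
        raise HydroError("season definition must cover all 12 months exactly once")
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "hrt" not in df.columns:
        df["hrt"] = hrt_series(df["storage"].to_numpy(), df["outflow"].to_numpy())
    season, year = _season_year(df["date"], seasons)
    df["season"], df["season_year"] = season, year

    def agg(sub: pd.DataFrame, label: str) -> HydroSummary:
        return HydroSummary(
            period=label,
            mean_hrt=float(sub["hrt"].mean()),
            total_precip=float(sub["precipitation"].sum()),
            mean_inflow=float(sub["inflow"].mean()),
            mean_outflow=float(sub["outflow"].mean()),
            n_days=len(sub),
        )

    rows = []
    for (sy, s), sub in df.groupby(["season_year", "season"], sort=True):
        rows.append(agg(sub, f"{s} {sy}"))
    for s, sub in df.groupby("season", sort=True):
        rows.append(agg(sub, s))
    for y, sub in df.groupby(df["date"].dt.year, sort=True):
        rows.append(agg(sub, str(y)))
    rows.append(agg(df, "all"))
    return pd.DataFrame([vars(r) for r in rows])


def summer_fraction(annual_totals: list[float], summer_total: float) -> float:
    """Summer share of total precipitation, percent, one decimal.

    100 * summer_total / sum(annual_totals).
    """
    denom = float(np.sum(annual_totals))
    if denom <= 0:
        raise HydroError("total precipitation must be positive")
    if summer_total < 0:
        raise HydroError("summer total must be >= 0")
    return round(100.0 * summer_total / denom, 1)


def area_ratio(basin_area: float, surface_area: float) -> int:
    """Basin-to-reservoir area ratio, nearest integer."""
    if surface_area <= 0:
        raise HydroError("surface area must be > 0")
    return int(round(basin_area / surface_area))
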