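"""Heat-stress metrics: degree heating weeks, Hotspot maxima, marine heatwaves.

Degree heating weeks (DHW) accumulate daily Hotspots (SST anomalies above the
MMM) over a trailing window of ``w`` weeks:

    DHW(t) = (1/7) * sum_{d in last 7w days} a(d) * 1[a(d) >= c]     [degC-weeks]

where ``c`` is the accumulation cutoff.  The heritage definition uses w=12 and
c=1 degC; both are configurable because shorter windows and a zero cutoff have
been found to verify better against bleaching observations.  A day at or above
the cutoff contributes its *full* anomaly (operational convention), so changing
c from 1 to 0 is a pure cutoff-removal experiment.

The marine heatwave (MHW) detector follows the standard definition: a
day-of-year 90th-percentile threshold built from an 11-day window across
baseline years, threshold and mean climatology smoothed with a 31-day moving
average, events lasting >= 5 consecutive days above threshold, with gaps of
<= 2 days between events merged.  Only the annual maximum intensity
(SST minus the day-of-year climatological mean over event days) is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .climatology import DEFAULT_BASELINE, Climatology, monthly_climatology, hotspot_series

__all__ = [
    "HeatStressConfig",
    "dhw_series",
    "annual_max_dhw",
    "annual_max_hotspot",
    "neighborhood_max",
    "mhw_annual_max_intensity",
    "annual_stress_table",
]


@dataclass(frozen=True)
class HeatStressConfig:
    """DHW accumulation parameters.

    window_weeks : trailing accumulation window w (weeks), >= 1
    cutoff       : accumulation cutoff c (degC above MMM), >= 0
    neighborhood : if True, gridded annual maxima take the 3x3 neighborhood max
    """

    window_weeks: int = 9
    cutoff: float = 0.0
    neighborhood: bool = False

    def __post_init__(self) -> None:
        if self.window_weeks < 1:
            raise ValueError("window_weeks must be >= 1")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")


def _require_daily_contiguous(series: pd.Series) -> None:
    idx = series.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise TypeError("series must be indexed by dates (DatetimeIndex)")
    if len(idx) > 1:
        deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if not np.all(deltas == 1):
            bad = idx[1:][deltas != 1]
            raise ValueError(f"series is not daily-contiguous (first gap before {bad[0].date()})")


def dhw_series(hotspots: pd.Series, config: HeatStressConfig = HeatStressConfig()) -> pd.Series:
    """Daily DHW in degC-weeks from a daily-contiguous Hotspot series.

    Days before the series start contribute zero, so the first 7w-1 values
    are partial accumulations.
    """
    _require_daily_contiguous(hotspots)
    a = hotspots.astype(float)
    contrib = a.where(a >= config.cutoff, 0.0)
    out = contrib.rolling(window=7 * config.window_weeks, min_periods=1).sum() / 7.0
    out.name = "dhw_cweeks"
    return out


def _year_slice(series: pd.Series, year: int) -> pd.Series:
    sel = series[series.index.year == year]
    if len(sel) == 0:
        raise ValueError(f"series has no observations in year {year}")
    return sel


def annual_max_dhw(dhw: pd.Series, year: int) -> float:
    """Maximum DHW over the calendar days of `year`."""
    return float(_year_slice(dhw, year).max())


def annual_max_hotspot(hotspots: pd.Series, year: int) -> float:
    """Maximum daily Hotspot within `year`, floored at zero."""
    return float(max(_year_slice(hotspots, year).max(), 0.0))


def neighborhood_max(
    annual_dhw_grid: "object",
    lat: float,
    lon: float,
) -> float:
    """Maximum over the grid cell nearest the site and its 8 neighbors.

    `annual_dhw_grid` is an xarray DataArray with ``lat``/``lon`` coordinate
    axes (regular grid); NaN cells (land) are ignored.  The nearest cell is
    chosen by great-circle distance to cell centers.  Raises if the site falls
    outside the grid (beyond half a cell spacing from the outermost centers)
    or if the whole 3x3 neighborhood is missing.
    """
    lats = np.asarray(annual_dhw_grid["lat"].values, dtype=float)
    lons = np.asarray(annual_dhw_grid["lon"].values, dtype=float)
    vals = np.asarray(annual_dhw_grid.transpose("lat", "lon").values, dtype=float)

    def _half_step(coords: np.ndarray) -> float:
        return float(np.abs(np.diff(coords)).max() / 2) if len(coords) > 1 else 90.0

    if not (lats.min() - _half_step(lats) <= lat <= lats.max() + _half_step(lats)):
        raise ValueError(f"site latitude {lat} outside grid bounds")
    if not (lons.min() - _half_step(lons) <= lon <= lons.max() + _half_step(lons)):
        raise ValueError(f"site longitude {lon} outside grid bounds")

    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    # haversine distance to every cell center (radius drops out of the argmin)
    phi1, phi2 = np.radians(lat), np.radians(glat)
    dphi, dlam = np.radians(glat - lat), np.radians(glon - lon)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    i, j = np.unravel_index(np.argmin(h), h.shape)

    block = vals[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
    if np.all(np.isnan(block)):
        raise ValueError("all cells in the 3x3 neighborhood are missing")
    return float(np.nanmax(block))


# ---------------------------------------------------------------------------
# Marine heatwaves
# ---------------------------------------------------------------------------

def _pseudo_doy(index: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year 1..365 with Feb 29 mapped onto Feb 28's slot."""
    doy = index.dayofyear.to_numpy().copy()
    leap = index.is_leap_year & (doy >= 60)
    doy[leap] -= 1
    return doy


def _circular_smooth(x: np.ndarray, window: int) -> np.ndarray:
    k = window // 2
    ext = np.concatenate([x[-k:], x, x[:k]])
    kernel = np.ones(window) / window
    return np.convolve(ext, kernel, mode="valid")


def _mhw_climatology(
    sst: pd.Series, baseline: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Smoothed day-of-year mean and 90th-percentile threshold (length 365)."""
    y0, y1 = baseline
    sel = sst[(sst.index.year >= y0) & (sst.index.year <= y1)].dropna()
    if len(sel) == 0:
        raise ValueError(f"no SST observations within baseline {y0}-{y1}")
    doy = _pseudo_doy(sel.index)
    vals = sel.to_numpy(dtype=float)
    pooled: list[list[float]] = [[] for _ in range(365)]
    for d, v in zip(doy, vals):
        pooled[d - 1].append(v)
    mean = np.empty(365)
    p90 = np.empty(365)
    for d in range(365):
        # 11-day window centered on d, circular in day-of-year
        window_vals = np.concatenate(
            [pooled[(d + off) % 365] for off in range(-5, 6)]
        )
        if len(window_vals) == 0:
            raise ValueError(f"no baseline observations near day-of-year {d + 1}")
        mean[d] = window_vals.mean()
        p90[d] = np.percentile(window_vals, 90)
    return _circular_smooth(mean, 31), _circular_smooth(p90, 31)


def _mhw_event_mask(above: np.ndarray, min_duration: int = 5, max_gap: int = 2) -> np.ndarray:
    """Boolean mask of MHW days: runs >= min_duration, gaps <= max_gap merged."""
    above = np.asarray(above, dtype=bool)
    n = len(above)
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_duration:
                runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= max_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    mask = np.zeros(n, dtype=bool)
    for a, b in merged:
        mask[a:b] = True
    return mask


def mhw_annual_max_intensity(
    sst: pd.Series,
    baseline: Tuple[int, int] = DEFAULT_BASELINE,
    year: Optional[int] = None,
) -> "float | pd.Series":
    """Annual maximum marine-heatwave intensity in degC (0 if no event).

    Intensity is SST minus the smoothed day-of-year climatological mean, taken
    over detected event days.  With ``year=None`` a per-year Series covering
    the whole record is returned.
    """
    _require_daily_contiguous(sst.dropna())
    clim_mean, thresh = _mhw_climatology(sst, baseline)
    doy = _pseudo_doy(sst.index) - 1
    vals = sst.to_numpy(dtype=float)
    above = vals > thresh[doy]
    mask = _mhw_event_mask(above)
    intensity = np.where(mask, vals - clim_mean[doy], 0.0)
    per_day = pd.Series(intensity, index=sst.index)
    annual = per_day.groupby(per_day.index.year).max().clip(lower=0.0)
    annual.index.name = "year"
    if year is None:
        return annual
    if year not in annual.index:
        raise ValueError(f"series has no observations in year {year}")
    return float(annual.loc[year])


# ---------------------------------------------------------------------------
# The per-site-year predictor table
# ---------------------------------------------------------------------------

def annual_stress_table(
    sst_by_site: Dict[str, pd.Series],
    config: HeatStressConfig = HeatStressConfig(),
    baseline: Tuple[int, int] = DEFAULT_BASELINE,
    site_meta: Optional[pd.DataFrame] = None,
    include_mhw: bool = False,
    climatologies: Optional[Dict[str, Climatology]] = None,
) -> pd.DataFrame:
    """Per site-year maxima of DHW, Hotspot and (optionally) MHW intensity.

    `site_meta`, if given, is indexed by site_id and its columns (lat, lon,
    region, ...) are joined onto the output.  Returns a DataFrame with columns
    site_id, year, max_dhw, max_hotspot [, max_mhw] plus any metadata.
    """
    rows = []
    for site_id, sst in sst_by_site.items():
        clim = (
            climatologies[site_id]
            if climatologies is not None
            else monthly_climatology(sst, baseline=baseline, site_id=site_id)
        )
        hs = hotspot_series(sst, clim)
        dhw = dhw_series(hs, config)
        hs_max = hs.groupby(hs.index.year).max().clip(lower=0.0)
        dhw_max = dhw.groupby(dhw.index.year).max()
        mhw = (
            mhw_annual_max_intensity(sst, baseline=baseline) if include_mhw else None
        )
        for year in dhw_max.index:
            row = {
                "site_id": site_id,
                "year": int(year),
                "max_dhw": float(dhw_max.loc[year]),
                "max_hotspot": float(hs_max.loc[year]),
            }
            if mhw is not None:
                row["max_mhw"] = float(mhw.loc[year])
            rows.append(row)
    out = pd.DataFrame(rows)
    if site_meta is not None:
        out = out.merge(site_meta, left_on="site_id", right_index=True, how="left")
    return out
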