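"""Monthly climatologies, the maximum monthly mean (MMM), and Hotspots.

The MMM is the warmest of the twelve climatological monthly mean temperatures
at a site, computed over a fixed baseline (default 1982-2012).  It is the
reference above which heat stress accrues: the daily "Hotspot" is simply
SST(t) - MMM, unclamped here (consumers decide whether negative anomalies
matter).

Monthly means are two-stage: days are averaged within each month-of-a-year,
then month-years are averaged across the baseline.  This keeps the estimate
unbiased when months have different day counts or missing days.  No
operational-style recentering or bias adjustment is applied to the MMM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Climatology",
    "monthly_climatology",
    "hotspot_series",
    "write_climatologies_csv",
    "read_climatologies_csv",
]

DEFAULT_BASELINE: Tuple[int, int] = (1982, 2012)

_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]


@dataclass(frozen=True)
class Climatology:
    """Twelve monthly means plus their maximum (MMM) for one site."""

    site_id: str
    monthly_means: np.ndarray  # 12 values, degC, Jan..Dec
    baseline: Tuple[int, int]

    def __post_init__(self) -> None:
        mm = np.asarray(self.monthly_means, dtype=float)
        if mm.shape != (12,):
            raise ValueError("monthly_means must have exactly 12 entries")
        if not np.all(np.isfinite(mm)):
            raise ValueError("monthly_means must all be finite")
        object.__setattr__(self, "monthly_means", mm)

    @property
    def mmm(self) -> float:
        return float(np.max(self.monthly_means))


def _check_daily_series(sst: pd.Series) -> pd.Series:
    if not isinstance(sst.index, pd.DatetimeIndex):
        raise TypeError("SST series must be indexed by dates (DatetimeIndex)")
    return sst


def monthly_climatology(
    sst: pd.Series,
    baseline: Tuple[int, int] = DEFAULT_BASELINE,
    site_id: str = "",
) -> Climatology:
    """Climatological monthly means over `baseline` (inclusive year range).

    Raises a coverage error naming the first calendar month with zero
    observations inside the baseline.
    """
    sst = _check_daily_series(sst)
    y0, y1 = baseline
    sel = sst[(sst.index.year >= y0) & (sst.index.year <= y1)].dropna()
    # two-stage: days -> month-of-year mean, month-years -> climatological month
    by_month_year = sel.groupby([sel.index.year, sel.index.month]).mean()
    monthly = by_month_year.groupby(level=1).mean()
    for m in range(1, 13):
        if m not in monthly.index:
            raise ValueError(
                f"no SST observations for {_MONTH_NAMES[m - 1]} within baseline {y0}-{y1}"
            )
    return Climatology(site_id=site_id, monthly_means=monthly.sort_index().to_numpy(), baseline=(y0, y1))


def hotspot_series(sst: pd.Series, clim: Climatology, site_id: Optional[str] = None) -> pd.Series:
    """Daily SST anomaly above the MMM; negative values are preserved."""
    if site_id is not None and clim.site_id and site_id != clim.site_id:
        raise ValueError(f"climatology is for site {clim.site_id!r}, not {site_id!r}")
    out = sst - clim.mmm
    out.name = "hotspot_c"
    return out


def write_climatologies_csv(clims: list[Climatology], path: str | Path) -> None:
    rows = []
    for c in clims:
        for m in range(12):
            rows.append(
                {
                    "site_id": c.site_id,
                    "month": m + 1,
                    "monthly_mean_c": c.monthly_means[m],
                    "mmm_c": c.mmm,
                    "baseline_start": c.baseline[0],
                    "baseline_end": c.baseline[1],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_climatologies_csv(path: str | Path) -> list[Climatology]:
    df = pd.read_csv(path)
    out = []
    for site, g in df.groupby("site_id", sort=False):
        g = g.sort_values("month")
        out.append(
            Climatology(
                site_id=str(site),
                monthly_means=g["monthly_mean_c"].to_numpy(),
                baseline=(int(g["baseline_start"].iloc[0]), int(g["baseline_end"].iloc[0])),
            )
        )
    return out
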