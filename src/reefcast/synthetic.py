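"""Synthetic reef SST, ENSO index, bleaching labels, and verification fixtures.

Every downstream stage of the package — climatology, DHW, skill metrics,
threshold optimization — is testable end-to-end against these generators
because the generative truth (the DHW threshold, the El Niño gate, the
threshold trend) is known exactly.

The default fixture mirrors the shape of the global bleaching database the
framework targets: 100 reef sites observed annually over 1982-2016, i.e.
n = 3,500 site-year presence/absence records.

Site SST is a sinusoidal seasonal cycle (365.25-day period) plus a linear
warming trend, an ENSO-coupled term (the monthly Nino3.4 anomaly linearly
interpolated to days times a per-site coupling coefficient), and AR(1) noise
initialized at its stationary distribution.  Sites are conditionally
independent given the ENSO index; no attempt is made to emulate spatial
covariance of real SST fields.

The ENSO generator produces boreal-winter-peaking positive excursions: forced
to ``event_peak`` in designated El Niño years and drawn uniformly from
[0, background_max] otherwise, so that the annual-maximum index has a
continuous amplitude spectrum (this is what makes a generative El Niño gate
identifiable by the ETS surface).

Bleaching labels follow a threshold rule on the site-year maximum DHW:
severe at ``theta_severe``, moderate at ``theta_true``, optionally gated on
the annual maximum El Niño index and optionally drifting linearly in time.
Label noise flips none<->moderate only, never fabricating "severe" events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .climatology import DEFAULT_BASELINE, monthly_climatology
from .metrics import ContingencyTable
from .stress import HeatStressConfig, annual_stress_table

__all__ = [
    "SiteSpec",
    "TruthConfig",
    "gen_sst_series",
    "gen_nino_series",
    "nino_annual_max",
    "gen_bleaching_events",
    "gen_contingency_tables",
    "gen_product_ensemble",
    "random_site_specs",
    "simulate_dataset",
    "SimulationResult",
    "DEFAULT_EVENT_YEARS",
]

YearRange = Tuple[int, int]

#: El Niño event years used by the default fixture (intersected with the
#: simulated year range).
DEFAULT_EVENT_YEARS = (1957, 1965, 1972, 1982, 1987, 1991, 1997, 2002, 2009, 2015)


@dataclass(frozen=True)
class SiteSpec:
    """Generative parameters for one reef site's daily SST."""

    site_id: str
    lat: float
    lon: float
    region: str
    mean_sst: float  # degC
    seasonal_amplitude: float  # degC, >= 0
    seasonal_peak_doy: int  # day-of-year of the seasonal maximum
    warming_trend: float  # degC per decade
    enso_coupling: float  # degC local SST per degC Nino3.4 anomaly
    noise_sd: float  # degC, >= 0
    noise_ar1: float  # in [0, 1)

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must be in [0, 1)")


@dataclass(frozen=True)
class TruthConfig:
    """Generative bleaching rule: the ground truth recovery targets."""

    theta_true: float = 5.4  # degC-weeks
    window_weeks: int = 9
    cutoff: float = 0.0  # degC
    nino_gate: Optional[float] = None  # degC; event needs annual max index >= gate
    theta_severe: float = 8.0  # degC-weeks, >= theta_true
    label_flip_prob: float = 0.0
    theta_trend: Optional[float] = None  # degC-weeks per year, anchored at trend_ref_year
    trend_ref_year: int = 1999

    def __post_init__(self) -> None:
        if self.theta_true <= 0:
            raise ValueError("theta_true must be > 0")
        if self.theta_severe < self.theta_true:
            raise ValueError("theta_severe must be >= theta_true")
        if not 0 <= self.label_flip_prob <= 1:
            raise ValueError("label_flip_prob must be in [0, 1]")

    def threshold_at(self, year: "int | np.ndarray") -> "float | np.ndarray":
        if self.theta_trend is None:
            return self.theta_true
        return self.theta_true + self.theta_trend * (np.asarray(year) - self.trend_ref_year)


def _year_list(years: YearRange) -> range:
    y0, y1 = years
    if y1 < y0:
        raise ValueError(f"empty year range {years}")
    return range(y0, y1 + 1)


# ---------------------------------------------------------------------------
# ENSO index
# ---------------------------------------------------------------------------

def gen_nino_series(
    years: YearRange,
    event_years: Iterable[int] = (),
    event_peak: float = 2.5,
    seed: int = 0,
    background_max: float = 1.2,
    noise_sd: float = 0.1,
) -> pd.Series:
    """Monthly Nino3.4-style anomaly series with winter-peaking excursions.

    Each year y gets a Gaussian excursion (sigma = 1 month) centered on its
    December, of amplitude ``event_peak`` if y is an event year and
    U(0, background_max) otherwise, plus iid monthly noise.  With
    background_max = 0 and noise_sd = 0 the series is zero outside event
    excursions; an event year's calendar maximum is exactly ``event_peak``.
    """
    yrs = _year_list(years)
    event_years = set(event_years)
    if not event_years <= set(yrs):
        raise ValueError(f"event years {sorted(event_years - set(yrs))} outside {years}")
    rng = np.random.default_rng(seed)
    n_years = len(yrs)
    amps = rng.uniform(0.0, background_max, size=n_years)
    for i, y in enumerate(yrs):
        if y in event_years:
            amps[i] = event_peak
    idx = pd.period_range(start=f"{years[0]}-01", end=f"{years[1]}-12", freq="M")
    m = np.arange(len(idx), dtype=float)  # months since Jan of first year
    centers = np.arange(n_years) * 12.0 + 11.0  # December of each year
    dist = m[None, :] - centers[:, None]
    bumps = amps[:, None] * np.exp(-0.5 * dist**2)  # sigma = 1 month
    values = bumps.sum(axis=0) + rng.normal(0.0, noise_sd, size=len(idx)) * (noise_sd > 0)
    out = pd.Series(values, index=idx, name="nino34_anom_c")
    return out


def nino_annual_max(nino: pd.Series) -> pd.Series:
    """Per-calendar-year maximum of the monthly index (the El Niño predictor)."""
    out = nino.groupby(nino.index.year).max()
    out.index.name = "year"
    out.name = "nino_max"
    return out


# ---------------------------------------------------------------------------
# Daily SST
# ---------------------------------------------------------------------------

def _nino_to_daily(nino: pd.Series, dates: pd.DatetimeIndex) -> np.ndarray:
    """Linear interpolation of monthly anomalies (anchored mid-month) to days."""
    anchors = nino.index.to_timestamp() + pd.Timedelta(days=14)
    s = pd.Series(nino.to_numpy(), index=anchors)
    union = s.index.union(dates)
    daily = s.reindex(union).interpolate(method="time").ffill().bfill()
    return daily.reindex(dates).to_numpy()


def gen_sst_series(
    spec: SiteSpec,
    years: YearRange,
    nino: Optional[pd.Series] = None,
    seed: int = 0,
) -> pd.Series:
    """Daily SST for one site; bit-reproducible under a fixed seed.

    SST(t) = mean + A*cos(2*pi*(doy - peak)/365.25) + trend*(elapsed years)
             + coupling*nino_daily(t) + AR(1) noise.

    `nino` must cover every month of `years` unless the site's coupling is 0.
    """
    yrs = _year_list(years)
    dates = pd.date_range(f"{yrs[0]}-01-01", f"{yrs[-1]}-12-31", freq="D")

    if spec.enso_coupling != 0.0 or nino is not None:
        if nino is None:
            raise ValueError("nino series required when enso_coupling != 0")
        needed = pd.period_range(f"{yrs[0]}-01", f"{yrs[-1]}-12", freq="M")
        missing = needed.difference(nino.index)
        if len(missing) > 0:
            raise ValueError(f"nino series does not cover {missing[0]}..{missing[-1]}")

    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = spec.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - spec.seasonal_peak_doy) / 365.25
    )
    elapsed = (dates - dates[0]).days.to_numpy(dtype=float) / 365.25
    trend = (spec.warming_trend / 10.0) * elapsed
    enso = (
        spec.enso_coupling * _nino_to_daily(nino, dates)
        if (nino is not None and spec.enso_coupling != 0.0)
        else 0.0
    )

    noise = np.zeros(len(dates))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        rho, sd = spec.noise_ar1, spec.noise_sd
        innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=len(dates))
        noise[0] = rng.normal(0.0, sd)
        for t in range(1, len(dates)):
            noise[t] = rho * noise[t - 1] + innov[t]

    out = pd.Series(spec.mean_sst + seasonal + trend + enso + noise, index=dates, name="sst_c")
    return out


# ---------------------------------------------------------------------------
# Bleaching labels
# ---------------------------------------------------------------------------

def gen_bleaching_events(
    stress: pd.DataFrame,
    truth: TruthConfig,
    nino_annual: Optional[pd.Series] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Label every site-year of `stress` from the generative threshold rule.

    severity = severe   if max_dhw >= theta_severe(+trend shift)
             = moderate if theta_true(+shift) <= max_dhw < theta_severe(+shift)
             = none     otherwise
    with events additionally requiring annual-max Niño >= nino_gate when a
    gate is configured; each none/moderate label is then independently flipped
    with probability label_flip_prob (severe labels are never touched).
    """
    missing = stress[stress["max_dhw"].isna()]
    if len(missing) > 0:
        pairs = list(missing[["site_id", "year"]].itertuples(index=False, name=None))[:10]
        raise ValueError(f"missing DHW for site-years: {pairs}")

    years = stress["year"].to_numpy()
    dhw = stress["max_dhw"].to_numpy(dtype=float)
    shift = 0.0 if truth.theta_trend is None else truth.theta_trend * (years - truth.trend_ref_year)
    thr = truth.theta_true + shift
    thr_sev = truth.theta_severe + shift

    if truth.nino_gate is not None:
        if nino_annual is None:
            raise ValueError("nino_annual required when truth.nino_gate is set")
        absent = sorted(set(years) - set(nino_annual.index))
        if absent:
            raise ValueError(f"nino_annual missing years {absent[:10]}")
        gated = nino_annual.reindex(years).to_numpy() >= truth.nino_gate
    else:
        gated = np.ones(len(stress), dtype=bool)

    severity = np.where(
        gated & (dhw >= thr_sev), "severe", np.where(gated & (dhw >= thr), "moderate", "none")
    )

    if truth.label_flip_prob > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(len(severity)) < truth.label_flip_prob
        flipped = severity.copy()
        flipped[flip & (severity == "none")] = "moderate"
        flipped[flip & (severity == "moderate")] = "none"
        severity = flipped

    out = stress[["site_id", "year"]].copy()
    for col in ("lat", "lon", "region"):
        if col in stress.columns:
            out[col] = stress[col].to_numpy()
    out["severity"] = severity
    return out


# ---------------------------------------------------------------------------
# Verification fixtures
# ---------------------------------------------------------------------------

def gen_contingency_tables(count: int, n_total: int, seed: int = 0) -> list[ContingencyTable]:
    """Uniformly random 4-cell tables summing exactly to n_total (stars & bars)."""
    if n_total < 4:
        raise ValueError("n_total must be >= 4")
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(count):
        bars = np.sort(rng.choice(n_total + 3, size=3, replace=False))
        h = int(bars[0])
        fa = int(bars[1] - bars[0] - 1)
        m = int(bars[2] - bars[1] - 1)
        cn = int(n_total + 2 - bars[2])
        tables.append(ContingencyTable(h, fa, m, cn))
    return tables


def gen_product_ensemble(
    n_products: int = 6,
    years: YearRange = (1982, 2016),
    outlier_index: int = 0,
    outlier_bias: Optional[Sequence[float]] = None,
    seed: int = 0,
    noise_sd: float = 0.005,
    latent_trend: float = 0.015,
    latent_sd: float = 0.08,
    latent_ar1: float = 0.5,
) -> pd.DataFrame:
    """Synthetic SST-product ensemble of global-mean annual anomalies.

    All products share one latent anomaly series (warming trend plus AR(1)
    interannual variability) plus small independent noise; the product at
    ``outlier_index`` additionally receives the per-year ``outlier_bias``
    offsets (degC).  Returns a DataFrame indexed by year with one column per
    product (the outlier column is named ``product_<i>``).
    """
    yrs = np.array(list(_year_list(years)))
    if not 0 <= outlier_index < n_products:
        raise ValueError("outlier_index out of range")
    bias = np.zeros(len(yrs)) if outlier_bias is None else np.asarray(outlier_bias, dtype=float)
    if len(bias) != len(yrs):
        raise ValueError("outlier_bias must have one value per year")
    rng = np.random.default_rng(seed)
    latent = np.zeros(len(yrs))
    if latent_sd > 0:
        innov = rng.normal(0.0, latent_sd * np.sqrt(1 - latent_ar1**2), size=len(yrs))
        latent[0] = rng.normal(0.0, latent_sd)
        for t in range(1, len(yrs)):
            latent[t] = latent_ar1 * latent[t - 1] + innov[t]
    latent = latent + latent_trend * (yrs - yrs.mean())
    data = {}
    for i in range(n_products):
        noise = rng.normal(0.0, noise_sd, size=len(yrs)) if noise_sd > 0 else 0.0
        series = latent + noise
        if i == outlier_index:
            series = series + bias
        data[f"product_{i}"] = series
    return pd.DataFrame(data, index=pd.Index(yrs, name="year"))


# ---------------------------------------------------------------------------
# Site populations and the end-to-end fixture
# ---------------------------------------------------------------------------

_REGION_BANDS = {
    # region: (lon_lo, lon_hi, lat_lo, lat_hi) - coarse reef-province boxes
    "Western Atlantic": (-90.0, -60.0, 8.0, 27.0),
    "Middle East": (32.0, 60.0, 12.0, 28.0),
    "Indian Ocean": (45.0, 100.0, -20.0, 5.0),
    "Southeast Asia": (95.0, 130.0, -10.0, 20.0),
    "Australasia": (140.0, 165.0, -25.0, -10.0),
    "Pacific": (150.0, 210.0, -20.0, 20.0),
}


def random_site_specs(
    n_sites: int = 100,
    seed: int = 0,
    noise_sd_range: Tuple[float, float] = (0.25, 0.5),
    noise_ar1_range: Tuple[float, float] = (0.75, 0.92),
    trend_range: Tuple[float, float] = (0.05, 0.35),
    coupling_range: Tuple[float, float] = (-0.3, 1.2),
) -> list[SiteSpec]:
    """Draw a population of heterogeneous reef sites across six regions.

    Defaults give tropical mean SSTs, seasonal amplitudes of 1-3.5 degC,
    warming trends spanning typical tropical values, ENSO couplings allowing
    both warm- and cool-phase responses, and red daily noise (AR1 ~ 0.8).
    """
    rng = np.random.default_rng(seed)
    regions = list(_REGION_BANDS)
    specs = []
    for i in range(n_sites):
        region = regions[int(rng.integers(len(regions)))]
        lon_lo, lon_hi, lat_lo, lat_hi = _REGION_BANDS[region]
        lon = float(rng.uniform(lon_lo, lon_hi))
        lon = lon - 360.0 if lon > 180.0 else lon
        lat = float(rng.uniform(lat_lo, lat_hi))
        peak = 227 if lat >= 0 else 45  # Aug 15 (NH) / Feb 14 (SH) summer peak
        specs.append(
            SiteSpec(
                site_id=f"site_{i:03d}",
                lat=lat,
                lon=lon,
                region=region,
                mean_sst=float(rng.uniform(25.5, 28.5)),
                seasonal_amplitude=float(rng.uniform(1.0, 3.5)),
                seasonal_peak_doy=int(np.round(peak + rng.normal(0, 10)) % 365) or 365,
                warming_trend=float(rng.uniform(*trend_range)),
                enso_coupling=float(rng.uniform(*coupling_range)),
                noise_sd=float(rng.uniform(*noise_sd_range)),
                noise_ar1=float(rng.uniform(*noise_ar1_range)),
            )
        )
    return specs


@dataclass
class SimulationResult:
    """Everything the synthetic study produces, with its generative truth."""

    specs: list[SiteSpec]
    sites: pd.DataFrame  # site metadata indexed by site_id
    nino: pd.Series  # monthly index
    nino_annual: pd.Series  # per-year maximum
    sst: Dict[str, pd.Series]  # site_id -> daily series
    stress: pd.DataFrame  # site-year predictor table
    records: pd.DataFrame  # bleaching observation table
    truth: TruthConfig
    years: YearRange


def simulate_dataset(
    n_sites: int = 100,
    years: YearRange = (1982, 2016),
    truth: Optional[TruthConfig] = None,
    seed: int = 0,
    specs: Optional[list[SiteSpec]] = None,
    baseline: Tuple[int, int] = DEFAULT_BASELINE,
    event_years: Optional[Iterable[int]] = None,
    nino_kwargs: Optional[dict] = None,
    noise_free: bool = False,
    include_mhw: bool = False,
) -> SimulationResult:
    """Run the full synthetic study: sites -> ENSO -> SST -> stress -> labels.

    ``noise_free=True`` zeroes the SST noise of every site (the seasonal,
    trend and ENSO structure remains), which makes the labels an exact
    deterministic function of the generative rule.  The default fixture
    (100 sites x 1982-2016) yields n = 3,500 site-year records.
    """
    truth = truth or TruthConfig()
    master = np.random.default_rng(seed)
    s_nino, s_sites, s_sst, s_labels = (int(master.integers(2**31)) for _ in range(4))

    if event_years is None:
        event_years = [y for y in DEFAULT_EVENT_YEARS if years[0] <= y <= years[1]]
    nino = gen_nino_series(years, event_years=event_years, seed=s_nino, **(nino_kwargs or {}))
    nino_ann = nino_annual_max(nino)

    if specs is None:
        specs = random_site_specs(n_sites, seed=s_sites)
    if noise_free:
        specs = [
            SiteSpec(**{**s.__dict__, "noise_sd": 0.0}) for s in specs
        ]

    sst_rng = np.random.default_rng(s_sst)
    sst = {
        s.site_id: gen_sst_series(s, years, nino, seed=int(sst_rng.integers(2**31)))
        for s in specs
    }

    sites = pd.DataFrame(
        {"lat": [s.lat for s in specs], "lon": [s.lon for s in specs],
         "region": [s.region for s in specs]},
        index=pd.Index([s.site_id for s in specs], name="site_id"),
    )
    config = HeatStressConfig(window_weeks=truth.window_weeks, cutoff=truth.cutoff)
    stress = annual_stress_table(
        sst, config=config, baseline=baseline, site_meta=sites, include_mhw=include_mhw
    )
    records = gen_bleaching_events(stress, truth, nino_annual=nino_ann, seed=s_labels)
    return SimulationResult(
        specs=specs, sites=sites, nino=nino, nino_annual=nino_ann, sst=sst,
        stress=stress, records=records, truth=truth, years=years,
    )


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_sst_csv(sst_by_site: Dict[str, pd.Series], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"site_id": sid, "date": s.index.strftime("%Y-%m-%d"), "sst_c": s.to_numpy()})
        for sid, s in sst_by_site.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sst_csv(path: str | Path) -> Dict[str, pd.Series]:
    df = pd.read_csv(path, parse_dates=["date"])
    return {
        str(sid): pd.Series(g["sst_c"].to_numpy(), index=pd.DatetimeIndex(g["date"]), name="sst_c")
        for sid, g in df.groupby("site_id", sort=False)
    }


def write_nino_csv(nino: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {"year": nino.index.year, "month": nino.index.month, "anomaly_c": nino.to_numpy()}
    ).to_csv(path, index=False)


def read_nino_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    idx = pd.PeriodIndex(
        [f"{y}-{m:02d}" for y, m in zip(df["year"], df["month"])], freq="M"
    )
    return pd.Series(df["anomaly_c"].to_numpy(), index=idx, name="nino34_anom_c")


def write_bleaching_csv(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("site_id", "lat", "lon", "region", "year", "severity") if c in records]
    records[cols].to_csv(path, index=False)


def read_bleaching_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    bad = set(df["severity"].unique()) - {"none", "moderate", "severe"}
    if bad:
        raise ValueError(f"unknown severity labels: {sorted(bad)}")
    return df
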