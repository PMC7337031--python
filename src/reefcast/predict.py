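"""Operation-level interface: events, predictions, sweeps, surfaces, diagnostics.

These functions are thin wrappers over the estimators in
:mod:`reefcast.estimators`, expressed in terms of the domain tables — the
per-site-year stress table (`annual_stress_table`), the bleaching observation
table, and the per-year maximum El Niño index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    BivariateDhwThresholdClassifier,
    DhwThresholdClassifier,
    EtsSurface,
    RegionalDhwThresholdClassifier,
)
from .metrics import ContingencyTable, SkillReport, build_contingency, compute_skill

__all__ = [
    "PredictorConfig",
    "observed_events",
    "predict_events",
    "make_features",
    "ets_curve",
    "optimal_threshold",
    "regional_optimize",
    "RegionalResult",
    "ets_surface",
    "zero_slope_in_top",
    "temporal_diagnostics",
    "TemporalDiagnostics",
    "EtsSurface",
]

_SEVERITIES = {"none", "moderate", "severe"}


@dataclass(frozen=True)
class PredictorConfig:
    """A fully specified prediction rule.

    Exactly one of `theta` (global threshold, degC-weeks) and
    `regional_thetas` must be set.  Optional terms: an El Niño conjunction
    threshold `nino_threshold` (degC), and a linear threshold trend
    `trend_slope` (degC-weeks/yr) anchored at `trend_ref_year`.
    `event_scope` selects which observed severities count as events.
    """

    theta: Optional[float] = None
    regional_thetas: Optional[Dict[str, float]] = None
    nino_threshold: Optional[float] = None
    trend_slope: Optional[float] = None
    trend_ref_year: int = 1999
    event_scope: str = "all"

    def __post_init__(self) -> None:
        if (self.theta is None) == (self.regional_thetas is None):
            raise ValueError("exactly one of theta / regional_thetas must be set")
        if self.event_scope not in ("all", "severe_only"):
            raise ValueError("event_scope must be 'all' or 'severe_only'")


def observed_events(records: pd.DataFrame, scope: str = "all") -> pd.Series:
    """Boolean site-year outcomes from the observation table.

    scope="all": moderate and severe both count as bleaching; "severe_only":
    moderate site-years are kept in the sample as non-events.
    """
    bad = set(records["severity"].unique()) - _SEVERITIES
    if bad:
        raise ValueError(f"unknown severity labels: {sorted(bad)}")
    if scope == "all":
        ev = records["severity"].isin(["moderate", "severe"])
    elif scope == "severe_only":
        ev = records["severity"] == "severe"
    else:
        raise ValueError("scope must be 'all' or 'severe_only'")
    out = pd.Series(
        ev.to_numpy(),
        index=pd.MultiIndex.from_frame(records[["site_id", "year"]]),
        name="event",
    )
    return out


def make_features(stress: pd.DataFrame, nino_annual: Optional[pd.Series] = None) -> pd.DataFrame:
    """Site-year feature table for the classifiers, indexed by (site_id, year)."""
    cols = [c for c in ("max_dhw", "max_hotspot", "max_mhw", "region") if c in stress.columns]
    X = stress[["site_id", "year"] + cols].copy()
    if nino_annual is not None:
        X["nino_max"] = nino_annual.reindex(X["year"]).to_numpy()
    X.index = pd.MultiIndex.from_frame(X[["site_id", "year"]])
    return X


def _aligned(stress, records, nino_annual, scope):
    X = make_features(stress, nino_annual)
    y = observed_events(records, scope)
    if len(X) != len(y) or not X.index.sort_values().equals(y.index.sort_values()):
        raise ValueError("stress and records cover different site-year sets")
    return X, y.reindex(X.index)


def _report_for_predictions(pred: np.ndarray, obs: np.ndarray) -> SkillReport:
    p, o = np.asarray(pred, dtype=bool), np.asarray(obs, dtype=bool)
    return compute_skill(
        ContingencyTable(
            int(np.sum(p & o)), int(np.sum(p & ~o)), int(np.sum(~p & o)), int(np.sum(~p & ~o))
        )
    )


def predict_events(
    stress: pd.DataFrame,
    nino_annual: Optional[pd.Series],
    config: PredictorConfig,
) -> pd.Series:
    """Boolean site-year predictions under a fixed rule (inclusive thresholds)."""
    X = make_features(stress, nino_annual)
    if config.nino_threshold is not None and "nino_max" not in X.columns:
        raise ValueError("nino_annual is required when config.nino_threshold is set")
    if config.regional_thetas is not None:
        missing = sorted(set(X["region"]) - set(config.regional_thetas))
        if missing:
            raise ValueError(f"regions missing from regional_thetas: {missing}")
        theta_eff = X["region"].map(config.regional_thetas).to_numpy(dtype=float)
    else:
        theta_eff = np.full(len(X), float(config.theta))
    if config.trend_slope is not None:
        theta_eff = theta_eff + config.trend_slope * (
            X["year"].to_numpy(dtype=float) - config.trend_ref_year
        )
    pred = X["max_dhw"].to_numpy(dtype=float) >= theta_eff
    if config.nino_threshold is not None:
        pred &= X["nino_max"].to_numpy(dtype=float) >= config.nino_threshold
    return pd.Series(pred, index=X.index, name="predicted")


def ets_curve(
    stress: pd.DataFrame,
    records: pd.DataFrame,
    nino_annual: Optional[pd.Series] = None,
    theta_grid: Optional[Sequence[float]] = None,
    base_config: Optional[PredictorConfig] = None,
    predictor: str = "max_dhw",
) -> pd.DataFrame:
    """Sweep the threshold grid; one row per theta with counts and all metrics.

    `base_config` supplies the fixed parts of the rule (El Niño threshold,
    trend, event scope); its own theta is ignored.
    """
    cfg = base_config or PredictorConfig(theta=0.0)
    X, y = _aligned(stress, records, nino_annual, cfg.event_scope)
    clf = DhwThresholdClassifier(
        theta_grid=theta_grid,
        nino_threshold=cfg.nino_threshold,
        trend_slope=cfg.trend_slope,
        trend_ref_year=cfg.trend_ref_year,
        predictor=predictor,
    ).fit(X, y.to_numpy())
    return clf.curve_


def optimal_threshold(curve: pd.DataFrame) -> tuple[float, SkillReport]:
    """Smallest grid theta attaining the maximum defined ETS, with its report."""
    ets = curve["ets"].to_numpy(dtype=float)
    if np.all(np.isnan(ets)):
        raise ValueError("ETS is undefined at every grid point")
    i = int(np.flatnonzero(ets == np.nanmax(ets))[0])
    row = curve.iloc[i]
    report = compute_skill(
        ContingencyTable(int(row["H"]), int(row["FA"]), int(row["M"]), int(row["CN"]))
    )
    return float(row["theta"]), report


@dataclass
class RegionalResult:
    regional_thetas: Dict[str, Optional[float]]
    pooled_report: SkillReport
    curves: Dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)


def regional_optimize(
    stress: pd.DataFrame,
    records: pd.DataFrame,
    theta_grid: Optional[Sequence[float]] = None,
    nino_annual: Optional[pd.Series] = None,
    nino_threshold: Optional[float] = None,
    scope: str = "all",
) -> RegionalResult:
    """Optimize a DHW threshold independently within each region.

    The pooled report combines every defined region's predictions at its own
    optimum; regions without observed events are flagged (theta None) and
    excluded from the pooling.
    """
    X, y = _aligned(stress, records, nino_annual, scope)
    clf = RegionalDhwThresholdClassifier(
        theta_grid=theta_grid, nino_threshold=nino_threshold
    ).fit(X, y.to_numpy())
    return RegionalResult(
        regional_thetas=dict(clf.regional_thetas_),
        pooled_report=clf.report_,
        curves=dict(clf.curves_),
    )


def ets_surface(
    stress: pd.DataFrame,
    records: pd.DataFrame,
    nino_annual: Optional[pd.Series] = None,
    theta_grid: Optional[Sequence[float]] = None,
    second_axis: str = "nino_threshold",
    second_grid: Optional[Sequence[float]] = None,
    top_fraction: float = 0.02,
    trend_ref_year: int = 1999,
    scope: str = "all",
) -> EtsSurface:
    """ETS at every (theta, second-predictor) grid pair, with top-2% mask."""
    X, y = _aligned(stress, records, nino_annual, scope)
    clf = BivariateDhwThresholdClassifier(
        theta_grid=theta_grid,
        second_axis=second_axis,
        second_grid=second_grid,
        top_fraction=top_fraction,
        trend_ref_year=trend_ref_year,
    ).fit(X, y.to_numpy())
    return clf.surface_


def zero_slope_in_top(surface: EtsSurface) -> bool:
    """Does the constant-threshold (slope = 0) column reach the top ETS cells?

    The forecasting reading: if yes, the hypothesis that the bleaching
    threshold has remained constant cannot be rejected by the ETS analysis.
    """
    if surface.second_axis != "trend_slope":
        raise ValueError("surface's second axis must be trend_slope")
    j = np.flatnonzero(np.isclose(surface.second_grid, 0.0))
    if len(j) == 0:
        raise ValueError("slope 0 is not on the surface grid")
    return bool(surface.mask[:, j[0]].any())


@dataclass
class TemporalDiagnostics:
    """Era false-alarm counts and the annual-ETS trend test."""

    false_alarms_by_era: Dict[str, int]
    annual: pd.DataFrame  # year, H, FA, M, CN, ets (NaN when undefined)
    ets_trend_slope: float
    ets_trend_pvalue: float
    split_year: int


def temporal_diagnostics(
    stress: pd.DataFrame,
    records: pd.DataFrame,
    config: PredictorConfig,
    nino_annual: Optional[pd.Series] = None,
    split_year: int = 1999,
) -> TemporalDiagnostics:
    """False alarms per era (first era runs through split_year inclusive) and
    the OLS trend of annual ETS with its two-sided slope test.

    Years with undefined ETS are excluded from the trend fit.  A perfectly
    constant annual ETS series has slope 0 and p-value 1 by convention.
    """
    pred = predict_events(stress, nino_annual, config)
    obs = observed_events(records, config.event_scope).reindex(pred.index)
    years = pred.index.get_level_values("year").to_numpy()
    if not (years.min() <= split_year < years.max()):
        raise ValueError("data must span both sides of split_year")

    p, o = pred.to_numpy(), obs.to_numpy(dtype=bool)
    fa = p & ~o
    era1 = years <= split_year
    fa_by_era = {
        f"{years.min()}-{split_year}": int(fa[era1].sum()),
        f"{split_year + 1}-{years.max()}": int(fa[~era1].sum()),
    }

    rows = []
    for year in np.unique(years):
        sel = years == year
        rep = _report_for_predictions(p[sel], o[sel])
        t = rep.table
        rows.append(
            {"year": int(year), "H": t.hits, "FA": t.false_alarms, "M": t.misses,
             "CN": t.correct_negatives, "ets": np.nan if rep.ets is None else rep.ets}
        )
    annual = pd.DataFrame(rows)

    ok = annual["ets"].notna()
    yy = annual.loc[ok, "year"].to_numpy(dtype=float)
    ee = annual.loc[ok, "ets"].to_numpy(dtype=float)
    if len(yy) < 3:
        slope, pval = np.nan, np.nan
    elif np.allclose(ee, ee[0]):
        slope, pval = 0.0, 1.0
    else:
        fit = stats.linregress(yy, ee)
        slope, pval = float(fit.slope), float(fit.pvalue)
    return TemporalDiagnostics(
        false_alarms_by_era=fa_by_era,
        annual=annual,
        ets_trend_slope=slope,
        ets_trend_pvalue=pval,
        split_year=split_year,
    )
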