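"""Scikit-learn style classifiers that optimize bleaching thresholds by ETS.

The predictor is a feature table ``X`` (a pandas DataFrame) with one row per
site-year and columns

    max_dhw   : annual maximum DHW in degC-weeks (or another stress metric,
                via the ``predictor`` parameter),
    nino_max  : annual maximum El Niño index (needed when an El Niño threshold
                is part of the rule),
    year      : needed when a threshold trend is part of the rule,
    region    : needed by the regional classifier,

and ``y`` is the boolean site-year bleaching outcome.  A site-year is
predicted to bleach when the stress metric is at or above the (possibly
regional and/or time-varying) threshold and, if configured, the El Niño index
is at or above its threshold; all comparisons are inclusive.

Fitting is an exhaustive sweep of the threshold grid(s) scoring each candidate
by the Equitable Threat Score; ties are broken toward the smallest threshold
(then the smallest second-axis value), which favors sensitivity and is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .metrics import ContingencyTable, SkillReport, compute_skill

__all__ = [
    "DEFAULT_THETA_GRID",
    "DEFAULT_NINO_GRID",
    "DEFAULT_SLOPE_GRID",
    "EtsSurface",
    "DhwThresholdClassifier",
    "RegionalDhwThresholdClassifier",
    "BivariateDhwThresholdClassifier",
]

# Threshold grids: theta spans the 1-15 degC-weeks sweep at 0.1 resolution
# (reported optima like 5.4 and 6.3 live on this grid); the El Niño and
# trend grids cover the plausible span of each second predictor.
DEFAULT_THETA_GRID = np.round(np.arange(1.0, 15.0 + 1e-9, 0.1), 1)
DEFAULT_NINO_GRID = np.round(np.arange(-1.0, 3.5 + 1e-9, 0.05), 2)
DEFAULT_SLOPE_GRID = np.round(np.arange(-0.2, 0.2 + 1e-9, 0.005), 3)


def _counts_for_grid(x: np.ndarray, y: np.ndarray, grid: np.ndarray, gate: np.ndarray):
    """H/FA/M/CN for `pred = (x >= theta) & gate` at every theta in one shot."""
    pred = (x[None, :] >= grid[:, None]) & gate[None, :]
    yb = y[None, :]
    h = (pred & yb).sum(axis=1)
    fa = (pred & ~yb).sum(axis=1)
    m = ((~pred) & yb).sum(axis=1)
    cn = ((~pred) & ~yb).sum(axis=1)
    return h, fa, m, cn


def _ets_from_counts(h, fa, m, cn):
    """Vectorized ETS with NaN for an exactly-zero (integer) denominator."""
    h = h.astype(np.int64)
    fa = fa.astype(np.int64)
    m = m.astype(np.int64)
    n = h + fa + m + cn.astype(np.int64)
    num = h * n - (h + fa) * (h + m)
    den = (h + fa + m) * n - (h + fa) * (h + m)
    out = np.full(h.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def _curve_frame(grid: np.ndarray, h, fa, m, cn) -> pd.DataFrame:
    rows = []
    for i, theta in enumerate(grid):
        rep = compute_skill(ContingencyTable(int(h[i]), int(fa[i]), int(m[i]), int(cn[i])))
        row = {"theta": float(theta)}
        row.update(rep.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _best_theta(grid: np.ndarray, ets: np.ndarray) -> int:
    """Index of the smallest theta attaining the maximum defined ETS."""
    if np.all(np.isnan(ets)):
        raise ValueError("ETS is undefined at every grid point")
    best = np.nanmax(ets)
    return int(np.flatnonzero(ets == best)[0])


@dataclass
class EtsSurface:
    """ETS over a (theta x second-predictor) grid with its top-fraction mask."""

    theta_grid: np.ndarray
    second_grid: np.ndarray
    second_axis: str  # "nino_threshold" or "trend_slope"
    ets: np.ndarray  # shape (len(theta_grid), len(second_grid)); NaN = undefined
    mask: np.ndarray  # boolean, cells at or above the (1 - top_fraction) quantile
    top_fraction: float

    def argmax(self) -> tuple[int, int]:
        """Grid indices of the maximum ETS; ties -> smallest theta, then
        smallest second-axis value."""
        if np.all(np.isnan(self.ets)):
            raise ValueError("ETS is undefined over the whole surface")
        best = np.nanmax(self.ets)
        ti, si = np.nonzero(self.ets == best)
        order = np.lexsort((si, ti))
        k = order[0]
        return int(ti[k]), int(si[k])


def _validate_Xy(X: pd.DataFrame, y, predictor: str, need_nino: bool, need_year: bool):
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame of site-year features")
    required = [predictor] + (["nino_max"] if need_nino else []) + (["year"] if need_year else [])
    missing = [c for c in required if c not in X.columns]
    if missing:
        raise ValueError(f"X is missing required columns {missing}")
    x = X[predictor].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError(f"non-finite values in X[{predictor!r}]")
    if y is None:
        return x, None
    yarr = np.asarray(y)
    if yarr.dtype != bool:
        uniq = set(np.unique(yarr).tolist())
        if not uniq <= {0, 1, True, False}:
            raise ValueError("y must be boolean (bleaching event presence/absence)")
        yarr = yarr.astype(bool)
    if len(yarr) != len(X):
        raise ValueError("X and y lengths differ")
    return x, yarr


class DhwThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Bleaching classifier: stress >= theta (AND El Niño index >= threshold).

    Parameters
    ----------
    theta : float, optional
        Fixed DHW threshold in degC-weeks.  If None (default), `fit` selects
        the smallest grid value maximizing ETS and stores the full sweep in
        ``curve_``.
    theta_grid : array-like, optional
        Candidate thresholds; defaults to 1..15 degC-weeks, step 0.1.
    nino_threshold : float, optional
        El Niño conjunction threshold on the ``nino_max`` feature.
    trend_slope : float, optional
        Linear drift of the threshold in degC-weeks/yr, anchored at
        ``trend_ref_year`` (the effective threshold in year y is
        theta + slope*(y - ref)).
    trend_ref_year : int, default 1999
    predictor : str, default "max_dhw"
        Feature column holding the stress metric to threshold.

    Attributes
    ----------
    theta_ : float
        The threshold in effect after fitting.
    report_ : SkillReport
        Verification metrics of the fitted rule on the training data.
    ets_ : float or None
    curve_ : DataFrame or None
        The per-theta sweep (theta, H, FA, M, CN and all nine metrics),
        populated when the threshold was optimized.
    """

    def __init__(
        self,
        theta: Optional[float] = None,
        theta_grid: Optional[Sequence[float]] = None,
        nino_threshold: Optional[float] = None,
        trend_slope: Optional[float] = None,
        trend_ref_year: int = 1999,
        predictor: str = "max_dhw",
    ):
        self.theta = theta
        self.theta_grid = theta_grid
        self.nino_threshold = nino_threshold
        self.trend_slope = trend_slope
        self.trend_ref_year = trend_ref_year
        self.predictor = predictor

    def _adjusted_predictor(self, X: pd.DataFrame, x: np.ndarray) -> np.ndarray:
        if self.trend_slope is None:
            return x
        # x >= theta + s*(year-ref)  <=>  x - s*(year-ref) >= theta
        years = X["year"].to_numpy(dtype=float)
        return x - self.trend_slope * (years - self.trend_ref_year)

    def _gate(self, X: pd.DataFrame) -> np.ndarray:
        if self.nino_threshold is None:
            return np.ones(len(X), dtype=bool)
        return X["nino_max"].to_numpy(dtype=float) >= self.nino_threshold

    def fit(self, X: pd.DataFrame, y) -> "DhwThresholdClassifier":
        x, yarr = _validate_Xy(
            X, y, self.predictor, self.nino_threshold is not None, self.trend_slope is not None
        )
        xa = self._adjusted_predictor(X, x)
        gate = self._gate(X)
        self.classes_ = np.array([False, True])
        if self.theta is None:
            grid = np.asarray(
                DEFAULT_THETA_GRID if self.theta_grid is None else self.theta_grid, dtype=float
            )
            if len(grid) == 0 or np.any(np.diff(grid) <= 0):
                raise ValueError("theta_grid must be non-empty and strictly ascending")
            h, fa, m, cn = _counts_for_grid(xa, yarr, grid, gate)
            ets = _ets_from_counts(h, fa, m, cn)
            i = _best_theta(grid, ets)
            self.curve_ = _curve_frame(grid, h, fa, m, cn)
            self.theta_ = float(grid[i])
            self.report_ = compute_skill(
                ContingencyTable(int(h[i]), int(fa[i]), int(m[i]), int(cn[i]))
            )
        else:
            self.curve_ = None
            self.theta_ = float(self.theta)
            pred = (xa >= self.theta_) & gate
            self.report_ = compute_skill(
                ContingencyTable(
                    int(np.sum(pred & yarr)),
                    int(np.sum(pred & ~yarr)),
                    int(np.sum(~pred & yarr)),
                    int(np.sum(~pred & ~yarr)),
                )
            )
        self.ets_ = self.report_.ets
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "theta_"):
            raise ValueError("classifier is not fitted")
        x, _ = _validate_Xy(
            X, None, self.predictor, self.nino_threshold is not None, self.trend_slope is not None
        )
        return (self._adjusted_predictor(X, x) >= self.theta_) & self._gate(X)

    def score(self, X: pd.DataFrame, y) -> float:
        """ETS of the fitted rule on (X, y); NaN when undefined."""
        from .predict import _report_for_predictions  # local import, avoids cycle

        rep = _report_for_predictions(self.predict(X), np.asarray(y, dtype=bool))
        return np.nan if rep.ets is None else rep.ets


class RegionalDhwThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Per-region DHW thresholds, each optimized independently by ETS.

    Regions with no observed events get an undefined threshold (``None`` in
    ``regional_thetas_``): their site-years are excluded from the pooled
    training report and predicted as non-events.  Fitting fails only if every
    region is undefined.

    Attributes: ``regional_thetas_`` (dict region -> float | None),
    ``report_`` (pooled over defined regions at their optima), ``ets_``,
    ``curves_`` (dict region -> sweep DataFrame).
    """

    def __init__(
        self,
        theta_grid: Optional[Sequence[float]] = None,
        nino_threshold: Optional[float] = None,
        predictor: str = "max_dhw",
    ):
        self.theta_grid = theta_grid
        self.nino_threshold = nino_threshold
        self.predictor = predictor

    def fit(self, X: pd.DataFrame, y) -> "RegionalDhwThresholdClassifier":
        if "region" not in X.columns:
            raise ValueError("X must carry a 'region' column")
        x, yarr = _validate_Xy(X, y, self.predictor, self.nino_threshold is not None, False)
        grid = np.asarray(
            DEFAULT_THETA_GRID if self.theta_grid is None else self.theta_grid, dtype=float
        )
        regions = X["region"].to_numpy()
        self.regional_thetas_ = {}
        self.curves_ = {}
        pooled_pred = np.zeros(len(X), dtype=bool)
        pooled_mask = np.zeros(len(X), dtype=bool)
        base = DhwThresholdClassifier(
            theta_grid=grid, nino_threshold=self.nino_threshold, predictor=self.predictor
        )
        for region in pd.unique(regions):
            sel = regions == region
            if not np.any(yarr[sel]):
                self.regional_thetas_[region] = None
                continue
            sub = base.__class__(**base.get_params()).fit(X.loc[sel], yarr[sel])
            self.regional_thetas_[region] = sub.theta_
            self.curves_[region] = sub.curve_
            pooled_pred[sel] = sub.predict(X.loc[sel])
            pooled_mask[sel] = True
        if not np.any(pooled_mask):
            raise ValueError("no region has observed events; nothing to optimize")
        p, o = pooled_pred[pooled_mask], yarr[pooled_mask]
        self.report_ = compute_skill(
            ContingencyTable(
                int(np.sum(p & o)), int(np.sum(p & ~o)), int(np.sum(~p & o)), int(np.sum(~p & ~o))
            )
        )
        self.ets_ = self.report_.ets
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "regional_thetas_"):
            raise ValueError("classifier is not fitted")
        regions = X["region"].to_numpy()
        unknown = sorted(set(regions) - set(self.regional_thetas_))
        if unknown:
            raise ValueError(f"regions missing from fitted thresholds: {unknown}")
        x, _ = _validate_Xy(X, None, self.predictor, self.nino_threshold is not None, False)
        gate = (
            X["nino_max"].to_numpy(dtype=float) >= self.nino_threshold
            if self.nino_threshold is not None
            else np.ones(len(X), dtype=bool)
        )
        thetas = np.array(
            [np.inf if self.regional_thetas_[r] is None else self.regional_thetas_[r] for r in regions]
        )
        return (x >= thetas) & gate


class BivariateDhwThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Joint sweep of the DHW threshold with a second predictor axis.

    ``second_axis`` is ``"nino_threshold"`` (an El Niño conjunction threshold,
    swept over ``second_grid``, default -1..3.5 degC step 0.05) or
    ``"trend_slope"`` (a linear threshold drift in degC-weeks/yr anchored at
    ``trend_ref_year``, default grid -0.2..0.2 step 0.005).  ``fit`` evaluates
    ETS at every grid pair, stores the full ``surface_`` (with its
    top-fraction mask), and adopts the argmax pair.
    """

    def __init__(
        self,
        theta_grid: Optional[Sequence[float]] = None,
        second_axis: str = "nino_threshold",
        second_grid: Optional[Sequence[float]] = None,
        top_fraction: float = 0.02,
        trend_ref_year: int = 1999,
        predictor: str = "max_dhw",
    ):
        self.theta_grid = theta_grid
        self.second_axis = second_axis
        self.second_grid = second_grid
        self.top_fraction = top_fraction
        self.trend_ref_year = trend_ref_year
        self.predictor = predictor

    def _grids(self):
        grid = np.asarray(
            DEFAULT_THETA_GRID if self.theta_grid is None else self.theta_grid, dtype=float
        )
        if self.second_axis == "nino_threshold":
            second = DEFAULT_NINO_GRID if self.second_grid is None else self.second_grid
        elif self.second_axis == "trend_slope":
            second = DEFAULT_SLOPE_GRID if self.second_grid is None else self.second_grid
        else:
            raise ValueError("second_axis must be 'nino_threshold' or 'trend_slope'")
        return grid, np.asarray(second, dtype=float)

    def fit(self, X: pd.DataFrame, y) -> "BivariateDhwThresholdClassifier":
        grid, second = self._grids()
        need_nino = self.second_axis == "nino_threshold"
        need_year = self.second_axis == "trend_slope"
        x, yarr = _validate_Xy(X, y, self.predictor, need_nino, need_year)
        ets = np.empty((len(grid), len(second)))
        counts = np.empty((len(grid), len(second), 4), dtype=np.int64)
        ones = np.ones(len(X), dtype=bool)
        for j, s in enumerate(second):
            if need_nino:
                xa, gate = x, X["nino_max"].to_numpy(dtype=float) >= s
            else:
                years = X["year"].to_numpy(dtype=float)
                xa, gate = x - s * (years - self.trend_ref_year), ones
            h, fa, m, cn = _counts_for_grid(xa, yarr, grid, gate)
            counts[:, j, 0], counts[:, j, 1], counts[:, j, 2], counts[:, j, 3] = h, fa, m, cn
            ets[:, j] = _ets_from_counts(h, fa, m, cn)
        defined = ~np.isnan(ets)
        if not np.any(defined):
            raise ValueError("ETS is undefined over the whole surface")
        q = np.quantile(ets[defined], 1.0 - self.top_fraction)
        mask = defined & (ets >= q)
        self.surface_ = EtsSurface(
            theta_grid=grid, second_grid=second, second_axis=self.second_axis,
            ets=ets, mask=mask, top_fraction=self.top_fraction,
        )
        ti, si = self.surface_.argmax()
        self.theta_ = float(grid[ti])
        self.second_value_ = float(second[si])
        self.report_ = compute_skill(ContingencyTable(*counts[ti, si]))
        self.ets_ = self.report_.ets
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "theta_"):
            raise ValueError("classifier is not fitted")
        if self.second_axis == "nino_threshold":
            clf = DhwThresholdClassifier(
                theta=self.theta_, nino_threshold=self.second_value_, predictor=self.predictor
            )
        else:
            clf = DhwThresholdClassifier(
                theta=self.theta_, trend_slope=self.second_value_,
                trend_ref_year=self.trend_ref_year, predictor=self.predictor,
            )
        clf.theta_ = self.theta_  # fixed-threshold predict needs no refit
        return clf.predict(X)
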