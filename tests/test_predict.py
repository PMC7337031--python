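"""Prediction rules, threshold sweeps, surfaces, and temporal diagnostics."""

import numpy as np
import pandas as pd
import pytest

import reefcast as rc
from reefcast import PredictorConfig
from reefcast.synthetic import TruthConfig, gen_bleaching_events


def _stress(dhw, years, regions=None, site_ids=None):
    n = len(dhw)
    return pd.DataFrame({
        "site_id": site_ids or [f"s{i}" for i in range(n)],
        "year": years,
        "max_dhw": dhw,
        "region": regions or ["R"] * n,
    })


def _records(stress, severities):
    out = stress[["site_id", "year", "region"]].copy()
    out["severity"] = severities
    return out


def test_observed_events_scope_mapping():
    stress = _stress([1, 2, 3], [2000, 2000, 2000])
    recs = _records(stress, ["none", "moderate", "severe"])
    assert list(rc.observed_events(recs, "all")) == [False, True, True]
    assert list(rc.observed_events(recs, "severe_only")) == [False, False, True]
    recs_bad = _records(stress, ["none", "mild", "severe"])
    with pytest.raises(ValueError, match="unknown severity"):
        rc.observed_events(recs_bad)


def test_predict_inclusive_boundary_conjunction_and_trend():
    stress = _stress([5.4, 5.39, 10.0], [2000, 2000, 2000])
    pred = rc.predict_events(stress, None, PredictorConfig(theta=5.4))
    assert list(pred) == [True, False, True]

    nino = pd.Series({2000: 0.0})
    pred = rc.predict_events(stress, nino, PredictorConfig(theta=5.4, nino_threshold=0.5))
    assert list(pred) == [False, False, False]

    # s=0.1 anchored 1999: effective threshold in 2009 is theta + 1.0
    stress10 = _stress([6.3, 6.5], [2009, 2009])
    pred = rc.predict_events(stress10, None,
                             PredictorConfig(theta=5.4, trend_slope=0.1, trend_ref_year=1999))
    assert list(pred) == [False, True]


def test_predictor_config_validation():
    with pytest.raises(ValueError, match="exactly one"):
        PredictorConfig(theta=5.4, regional_thetas={"R": 4.0})
    with pytest.raises(ValueError, match="exactly one"):
        PredictorConfig()
    stress = _stress([5.0], [2000], regions=["unknown"])
    with pytest.raises(ValueError, match="missing from regional_thetas"):
        rc.predict_events(stress, None, PredictorConfig(regional_thetas={"R": 4.0}))


def test_curve_matches_pointwise_recomputation(bench_noisy):
    res = bench_noisy
    grid = np.round(np.arange(2.0, 9.0, 0.5), 1)
    curve = rc.ets_curve(res.stress, res.records, theta_grid=grid)
    obs = rc.observed_events(res.records)
    for _, row in curve.iloc[::3].iterrows():
        pred = rc.predict_events(res.stress, None, PredictorConfig(theta=row["theta"]))
        rep = rc.compute_skill(rc.build_contingency(pred, obs))
        assert row["H"] == rep.table.hits and row["FA"] == rep.table.false_alarms
        assert row["ets"] == pytest.approx(rep.ets, abs=1e-12)


def test_sweep_monotone_in_threshold(bench_noisy):
    """Ascending theta: H and FA non-increasing, M and CN non-decreasing."""
    curve = rc.ets_curve(bench_noisy.stress, bench_noisy.records)
    assert (np.diff(curve["H"]) <= 0).all()
    assert (np.diff(curve["FA"]) <= 0).all()
    assert (np.diff(curve["M"]) >= 0).all()
    assert (np.diff(curve["CN"]) >= 0).all()


def test_optimal_threshold_tie_breaks_to_smallest():
    curve = pd.DataFrame({
        "theta": [1.0, 2.0, 3.0, 4.0],
        "ets": [0.1, 0.4, 0.4, 0.2],
        "H": [5, 4, 4, 2], "FA": [3, 1, 1, 1], "M": [0, 1, 1, 3], "CN": [12, 14, 14, 14],
    })
    theta, rep = rc.optimal_threshold(curve)
    assert theta == 2.0
    assert rep.table.hits == 4
    empty = curve.assign(ets=np.nan)
    with pytest.raises(ValueError, match="undefined"):
        rc.optimal_threshold(empty)


def test_noise_free_truth_recovered_exactly(bench_noise_free):
    curve = rc.ets_curve(bench_noise_free.stress, bench_noise_free.records)
    theta, rep = rc.optimal_threshold(curve)
    assert theta == 5.4
    assert rep.ets == 1.0
    assert rep.table.false_alarms == 0 and rep.table.misses == 0


def test_severe_only_scope_raises_recovered_threshold(bench_noise_free):
    """Severe events require more heat: the severe-only optimum sits higher."""
    res = bench_noise_free
    cfg = PredictorConfig(theta=0.0, event_scope="severe_only")
    curve = rc.ets_curve(res.stress, res.records, base_config=cfg)
    theta_severe, rep = rc.optimal_threshold(curve)
    assert theta_severe == 8.0  # generative severe threshold
    assert rep.ets == 1.0
    assert theta_severe > 5.4


def test_regional_optimize_recovers_heterogeneous_truth():
    rng = np.random.default_rng(0)
    n = 600
    dhw = np.round(rng.uniform(0, 12, size=n), 3)
    regions = np.repeat(["A", "B"], n // 2)
    stress = _stress(dhw, [2000] * n, regions=list(regions))
    theta_by_region = {"A": 4.0, "B": 8.0}
    thr = np.array([theta_by_region[r] for r in regions])
    sev = np.where(dhw >= thr, "moderate", "none")
    recs = _records(stress, sev)

    res = rc.regional_optimize(stress, recs)
    assert res.regional_thetas["A"] == pytest.approx(4.0, abs=0.1)
    assert res.regional_thetas["B"] == pytest.approx(8.0, abs=0.1)
    assert res.pooled_report.ets == 1.0

    # pooled regional skill beats any single global threshold here
    curve = rc.ets_curve(stress, recs)
    _, best_global = rc.optimal_threshold(curve)
    assert res.pooled_report.ets >= best_global.ets


def test_regional_single_region_reduces_to_global(bench_noisy):
    res = bench_noisy
    stress = res.stress.copy()
    stress["region"] = "ALL"
    recs = res.records.copy()
    recs["region"] = "ALL"
    regional = rc.regional_optimize(stress, recs)
    curve = rc.ets_curve(stress, recs)
    theta, rep = rc.optimal_threshold(curve)
    assert regional.regional_thetas == {"ALL": theta}
    assert regional.pooled_report.ets == pytest.approx(rep.ets)


def test_region_without_events_is_flagged_not_fatal():
    stress = _stress([2.0, 9.0, 3.0, 9.0], [2000] * 4, regions=["A", "A", "B", "B"])
    recs = _records(stress, ["none", "moderate", "none", "none"])
    res = rc.regional_optimize(stress, recs)
    assert res.regional_thetas["B"] is None
    assert res.regional_thetas["A"] is not None
    assert res.pooled_report.table.n == 2  # region B excluded from pooling
    recs_none = _records(stress, ["none"] * 4)
    with pytest.raises(ValueError, match="no region"):
        rc.regional_optimize(stress, recs_none)


def test_surface_mask_covers_top_two_percent(bench_noisy):
    res = bench_noisy
    surf = rc.ets_surface(res.stress, res.records, res.nino_annual,
                          second_axis="nino_threshold")
    defined = ~np.isnan(surf.ets)
    frac = surf.mask.sum() / defined.sum()
    assert surf.mask.sum() >= 1
    assert 0.0 < frac <= 0.05
    q = np.quantile(surf.ets[defined], 0.98)
    assert (surf.ets[surf.mask] >= q).all()


def test_zero_slope_in_top_requires_trend_surface(bench_noisy):
    surf = rc.ets_surface(bench_noisy.stress, bench_noisy.records,
                          bench_noisy.nino_annual, second_axis="nino_threshold")
    with pytest.raises(ValueError, match="trend_slope"):
        rc.zero_slope_in_top(surf)
    tr = rc.ets_surface(bench_noisy.stress, bench_noisy.records,
                        second_axis="trend_slope", second_grid=[-0.1, 0.05, 0.1])
    with pytest.raises(ValueError, match="slope 0"):
        rc.zero_slope_in_top(tr)


def test_temporal_diagnostics_perfect_forecast(bench_noise_free):
    res = bench_noise_free
    diag = rc.temporal_diagnostics(res.stress, res.records, PredictorConfig(theta=5.4))
    assert diag.false_alarms_by_era == {"1982-1999": 0, "2000-2016": 0}
    defined = diag.annual["ets"].dropna()
    assert (defined == 1.0).all()
    assert diag.ets_trend_slope == 0.0
    assert diag.ets_trend_pvalue == 1.0


def test_temporal_diagnostics_era_counts_match_recount(bench_noisy):
    res = bench_noisy
    cfg = PredictorConfig(theta=4.0)
    diag = rc.temporal_diagnostics(res.stress, res.records, cfg, split_year=1999)
    pred = rc.predict_events(res.stress, None, cfg)
    obs = rc.observed_events(res.records).reindex(pred.index)
    years = pred.index.get_level_values("year")
    fa = (pred & ~obs)
    assert diag.false_alarms_by_era["1982-1999"] == int(fa[years <= 1999].sum())
    assert diag.false_alarms_by_era["2000-2016"] == int(fa[years > 1999].sum())
    assert diag.annual["FA"].sum() == int(fa.sum())


def test_ets_trend_null_calibration(bench_noisy):
    """Time-homogeneous truth: the annual-ETS trend test rarely rejects."""
    res = bench_noisy
    truth = TruthConfig(label_flip_prob=0.05)
    cfg = PredictorConfig(theta=5.4)
    rejections = 0
    n_rep = 20
    for k in range(n_rep):
        recs = gen_bleaching_events(res.stress, truth, res.nino_annual, seed=900 + k)
        diag = rc.temporal_diagnostics(res.stress, recs, cfg)
        if diag.ets_trend_pvalue <= 0.05:
            rejections += 1
    assert rejections <= 0.1 * n_rep + 1
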