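"""Generators: SST template, ENSO index, bleaching labels, fixtures, ensemble."""

import numpy as np
import pandas as pd
import pytest

import reefcast as rc
from reefcast.synthetic import (
    SiteSpec,
    TruthConfig,
    gen_bleaching_events,
    gen_nino_series,
    gen_product_ensemble,
    gen_sst_series,
    nino_annual_max,
    read_bleaching_csv,
    read_nino_csv,
    read_sst_csv,
    write_bleaching_csv,
    write_nino_csv,
    write_sst_csv,
)
from test_climatology import template_spec


def test_noise_free_series_equals_closed_form_template():
    spec = template_spec(mean_sst=26.0, seasonal_amplitude=1.5, seasonal_peak_doy=45)
    sst = gen_sst_series(spec, (1990, 1992))
    doy = sst.index.dayofyear.to_numpy()
    expected = 26.0 + 1.5 * np.cos(2 * np.pi * (doy - 45) / 365.25)
    assert np.allclose(sst.to_numpy(), expected, atol=1e-9)
    # within a non-leap year the maximum falls on the peak day-of-year
    year = sst["1991"]
    assert year.idxmax().dayofyear == 45


def test_seeded_series_bit_identical():
    spec = template_spec(noise_sd=0.3, noise_ar1=0.8)
    a = gen_sst_series(spec, (1990, 1994), seed=7)
    b = gen_sst_series(spec, (1990, 1994), seed=7)
    assert (a.to_numpy() == b.to_numpy()).all()
    c = gen_sst_series(spec, (1990, 1994), seed=8)
    assert not (a.to_numpy() == c.to_numpy()).all()


def test_trend_closed_form_first_vs_last_year():
    spec = template_spec(warming_trend=0.2)
    sst = gen_sst_series(spec, (1982, 2016))
    first = sst[sst.index.year == 1982].mean()
    last = sst[sst.index.year == 2016].mean()
    assert last - first == pytest.approx(0.2 * 34 / 10, abs=0.01)


def test_enso_coupling_requires_covering_index():
    nino = gen_nino_series((1990, 1993), background_max=0.0, noise_sd=0.0)
    spec = template_spec(enso_coupling=0.8)
    with pytest.raises(ValueError, match="cover"):
        gen_sst_series(spec, (1990, 1995), nino)
    sst = gen_sst_series(spec, (1990, 1993), nino)
    assert len(sst) == (pd.Timestamp("1993-12-31") - pd.Timestamp("1990-01-01")).days + 1


def test_nino_series_construction():
    # no events, noise off -> identically zero
    quiet = gen_nino_series((1990, 1999), background_max=0.0, noise_sd=0.0)
    assert np.allclose(quiet.to_numpy(), 0.0)
    # a single event year peaks at exactly event_peak in that calendar year
    one = gen_nino_series((1990, 1999), event_years=[1995], event_peak=2.5,
                          background_max=0.0, noise_sd=0.0)
    ann = nino_annual_max(one)
    assert ann.loc[1995] == pytest.approx(2.5)
    assert ann.drop(1995).max() < 2.5
    # default background: non-event years stay below the event peak
    noisy = gen_nino_series((1950, 2016), event_years=[1997], seed=3)
    ann = nino_annual_max(noisy)
    assert ann.loc[1997] == ann.max()
    assert ann.drop(1997).max() < 2.5
    with pytest.raises(ValueError, match="outside"):
        gen_nino_series((1990, 1999), event_years=[1980])


def _stress_frame(dhw, years=None, region="Pacific"):
    years = years or [2000] * len(dhw)
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(len(dhw))],
        "year": years,
        "max_dhw": dhw,
        "region": region,
    })


def test_label_rule_boundaries_and_gate():
    truth = TruthConfig(theta_true=5.4, theta_severe=8.0)
    stress = _stress_frame([0.0, 5.39, 5.4, 7.99, 8.0, 12.0])
    recs = gen_bleaching_events(stress, truth)
    assert list(recs["severity"]) == ["none", "none", "moderate", "moderate", "severe", "severe"]

    # all-zero DHW -> all none
    recs0 = gen_bleaching_events(_stress_frame([0.0] * 5), truth)
    assert (recs0["severity"] == "none").all()

    # the El Niño gate vetoes high-DHW years
    gated = TruthConfig(theta_true=5.4, nino_gate=0.5)
    nino_annual = pd.Series({2000: 0.1})
    recs_g = gen_bleaching_events(_stress_frame([8.0]), gated, nino_annual)
    assert list(recs_g["severity"]) == ["none"]
    nino_annual = pd.Series({2000: 0.6})
    recs_g = gen_bleaching_events(_stress_frame([8.0]), gated, nino_annual)
    assert list(recs_g["severity"]) == ["severe"]


def test_label_noise_flips_none_moderate_only():
    truth = TruthConfig(theta_true=5.4, theta_severe=8.0, label_flip_prob=0.3)
    dhw = [0.0] * 400 + [6.0] * 400 + [9.0] * 200
    stress = _stress_frame(dhw)
    stress["site_id"] = [f"s{i}" for i in range(1000)]
    recs = gen_bleaching_events(stress, truth, seed=5)
    sev = recs["severity"].to_numpy()
    assert (sev[800:] == "severe").all()  # severe labels never flipped
    flipped_up = (sev[:400] == "moderate").mean()
    flipped_down = (sev[400:800] == "none").mean()
    assert 0.2 < flipped_up < 0.4 and 0.2 < flipped_down < 0.4


def test_missing_stress_rows_reported():
    stress = _stress_frame([5.0, np.nan])
    with pytest.raises(ValueError, match="missing DHW"):
        gen_bleaching_events(stress, TruthConfig())


def test_contingency_fixtures_conserve_totals_and_are_seeded():
    tables = rc.gen_contingency_tables(1000, 3500, seed=4)
    assert all(t.n == 3500 for t in tables)
    again = rc.gen_contingency_tables(1000, 3500, seed=4)
    assert tables == again
    mean_h = np.mean([t.hits for t in tables])
    # uniform compositions: each cell has mean n/4, sd ~ n*sqrt(3/80)
    se = 3500 * np.sqrt(3 / 80) / np.sqrt(1000)
    assert abs(mean_h - 3500 / 4) < 3 * se
    with pytest.raises(ValueError):
        rc.gen_contingency_tables(10, 3)


def test_product_ensemble_bias_injection():
    years = (1982, 2016)
    n_years = 35
    # noise off, zero bias -> all products identical
    flat = gen_product_ensemble(4, years, 0, None, seed=1, noise_sd=0.0, latent_sd=0.1)
    assert np.allclose(flat.std(axis=1), 0.0)
    # constant bias band appears in pairwise differences
    bias = np.zeros(n_years)
    bias[10:21] = -0.05
    ens = gen_product_ensemble(4, years, 2, bias, seed=1, noise_sd=0.0)
    diff = ens["product_2"] - ens["product_0"]
    assert np.allclose(diff.iloc[10:21], -0.05)
    assert np.allclose(diff.iloc[:10], 0.0)
    # with default noise the outlier's RMSE dominates
    ens = gen_product_ensemble(4, years, 2, bias, seed=1)
    d = ens.to_numpy()
    rmse = lambda i, j: np.sqrt(np.mean((d[:, i] - d[:, j]) ** 2))
    outlier_rmse = min(rmse(2, j) for j in [0, 1, 3])
    other_rmse = max(rmse(i, j) for i in [0, 1, 3] for j in [0, 1, 3] if i < j)
    assert outlier_rmse > other_rmse


def test_default_fixture_shape_and_determinism(bench_noise_free):
    res = bench_noise_free
    assert len(res.stress) == 100 * 35 == 3500
    assert set(res.records["severity"]) <= {"none", "moderate", "severe"}
    assert res.stress["max_dhw"].min() >= 0.0
    # labels are exactly the thresholded-DHW indicator (no noise, no gate)
    ev = rc.observed_events(res.records)
    want = res.stress.set_index(["site_id", "year"])["max_dhw"] >= 5.4
    assert (ev.sort_index() == want.sort_index()).all()


def test_spec_validation():
    with pytest.raises(ValueError):
        template_spec(noise_ar1=1.0)
    with pytest.raises(ValueError):
        template_spec(seasonal_amplitude=-1.0)
    with pytest.raises(ValueError):
        TruthConfig(theta_true=5.4, theta_severe=4.0)
    with pytest.raises(ValueError):
        TruthConfig(label_flip_prob=1.5)


def test_csv_roundtrips(tmp_path, bench_noise_free):
    res = bench_noise_free
    sub = {k: res.sst[k] for k in list(res.sst)[:2]}
    write_sst_csv(sub, tmp_path / "sst.csv")
    back = read_sst_csv(tmp_path / "sst.csv")
    assert set(back) == set(sub)
    pd.testing.assert_series_equal(back[list(sub)[0]], sub[list(sub)[0]],
                                   check_freq=False, check_names=False, atol=1e-9)

    write_nino_csv(res.nino, tmp_path / "nino.csv")
    nback = read_nino_csv(tmp_path / "nino.csv")
    assert np.allclose(nback.to_numpy(), res.nino.to_numpy())

    write_bleaching_csv(res.records, tmp_path / "bleach.csv")
    rback = read_bleaching_csv(tmp_path / "bleach.csv")
    assert len(rback) == len(res.records)
    assert (rback["severity"].to_numpy() == res.records["severity"].to_numpy()).all()
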