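"""Drought events, composites, the stress curve and GPP-loss accounting."""

import numpy as np
import pandas as pd
import pytest

import fluepart as fp
from fluepart.events import (align_and_composite, annual_gpp_loss,
                             cumulative_deficit, detect_events,
                             estimate_stress_curve, site_flue_threshold)


def flue_series(values, start="2001-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(np.asarray(values, dtype=float), index=idx, name="flue")


def brute_force_events(x, threshold, min_duration):
    """Independent run-length scan used as the oracle."""
    events, run = [], []
    for i, v in enumerate(x):
        if np.isfinite(v) and v < threshold:
            run.append(i)
        else:
            if len(run) >= min_duration:
                events.append((run[0], len(run)))
            run = []
    if len(run) >= min_duration:
        events.append((run[0], len(run)))
    return events


class TestSiteThreshold:
    def test_flat_series_threshold_below_one(self):
        flue = flue_series(np.ones(400))
        thr = site_flue_threshold(flue, np.ones(400, bool))
        assert thr < 1.0
        assert len(detect_events(flue, thr)) == 0

    def test_depends_only_on_moist_days(self):
        rng = np.random.default_rng(0)
        moist = rng.random(400) < 0.6
        base = np.where(moist, 1.0 + rng.normal(0, 0.02, 400), 0.5)
        altered = np.where(moist, base, 0.1)
        t1 = site_flue_threshold(flue_series(base), moist)
        t2 = site_flue_threshold(flue_series(altered), moist)
        assert t1 == pytest.approx(t2)

    def test_too_few_moist_days_raises(self):
        with pytest.raises(ValueError):
            site_flue_threshold(flue_series(np.ones(50)), np.ones(50, bool))

    def test_onsets_near_truth_on_synthetic(self, stressed_site,
                                            stressed_result):
        # events should begin close to where the true stress factor crosses
        # the same threshold; the bucket drains ~2% of capacity per day and
        # the network prediction smooths the crossing, so onsets lag the
        # truth by up to about two weeks
        thr = stressed_result.site_threshold
        beta_runs = brute_force_events(stressed_site["beta_truth"], thr, 5)
        if not len(stressed_result.events) or not beta_runs:
            pytest.skip("no events on this realisation")
        onsets = stressed_result.events["onset_idx"].to_numpy()
        for s, _ in beta_runs[:3]:
            assert np.min(np.abs(onsets - s)) <= 14


class TestDetectEvents:
    def test_flat_series_no_events(self):
        assert len(detect_events(flue_series(np.ones(100)), 0.9)) == 0

    def test_constructed_run(self):
        x = np.ones(60)
        x[10:21] = 0.5
        events = detect_events(flue_series(x), 0.9)
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev["onset_idx"] == 10
        assert ev["length"] == 11
        assert ev["min_flue"] == pytest.approx(0.5)
        assert ev["cum_deficit"] == pytest.approx(11 * 0.5)

    def test_short_runs_discarded(self):
        x = np.ones(60)
        x[10:13] = 0.5
        assert len(detect_events(flue_series(x), 0.9, min_duration=5)) == 0

    def test_short_gaps_bridged(self):
        x = np.ones(60)
        x[10:30] = 0.5
        x[15:17] = np.nan  # 2-day hole inside the event
        events = detect_events(flue_series(x), 0.9, max_gap=3)
        assert len(events) == 1
        assert events.iloc[0]["length"] == 20

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.4, 1.2, 300)
        events = detect_events(flue_series(x), 0.8, min_duration=3,
                               max_gap=0)
        expected = brute_force_events(x, 0.8, 3)
        assert [(int(e["onset_idx"]), int(e["length"]))
                for _, e in events.iterrows()] == expected


class TestComposites:
    def test_constant_variable_normalises_to_one(self):
        series = {"x": flue_series(np.full(200, 5.0))}
        events = pd.DataFrame({"onset_idx": [100], "length": [10]})
        out = align_and_composite(series, events, normalize={"x"})
        np.testing.assert_allclose(out.matrices["x"].iloc[0], 1.0)

    def test_median_across_two_events(self):
        x = np.zeros(300)
        x[100], x[200] = 2.0, 6.0
        events = pd.DataFrame({"onset_idx": [100, 200], "length": [5, 5]})
        out = align_and_composite({"x": flue_series(x)}, events)
        assert out.bands["x"]["median"].loc[0] == pytest.approx(4.0)

    def test_bands_match_brute_force_quantiles(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 500)
        events = pd.DataFrame({"onset_idx": [60, 180, 320, 430],
                               "length": [10] * 4})
        out = align_and_composite({"x": flue_series(x)}, events,
                                  window=(-20, 40))
        mat = out.matrices["x"].to_numpy()
        for j, col in enumerate(out.matrices["x"].columns):
            vals = mat[:, j]
            vals = vals[np.isfinite(vals)]
            assert out.bands["x"]["median"].loc[col] == pytest.approx(
                np.median(vals))
            assert out.bands["x"]["q10"].loc[col] == pytest.approx(
                np.quantile(vals, 0.10))

    def test_inverse_relative_change(self):
        x = np.full(200, 2.0)
        x[100:120] = 4.0  # doubles after onset
        events = pd.DataFrame({"onset_idx": [100], "length": [20]})
        out = align_and_composite({"vpd": flue_series(x)}, events,
                                  invert={"vpd"})
        assert out.matrices["vpd"].iloc[0][10] == pytest.approx(0.5)

    def test_event_near_series_start_padded(self):
        events = pd.DataFrame({"onset_idx": [5], "length": [10]})
        out = align_and_composite({"x": flue_series(np.ones(100))}, events,
                                  window=(-20, 20))
        row = out.matrices["x"].iloc[0]
        assert row.loc[-20:-6].isna().all()
        assert row.loc[-5:20].notna().all()


class TestStressCurve:
    def test_unstressed_site_flat_at_one(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 1, 2000)
        flue = flue_series(np.ones(2000) + rng.normal(0, 0.01, 2000))
        curve = estimate_stress_curve(flue, theta)
        assert curve.flue0 == pytest.approx(1.0, abs=0.05)
        assert curve.flue1 == pytest.approx(1.0, abs=0.05)

    def test_known_intercept_recovered(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, 1, 3000)
        truth = fp.TruthParams(flue0=0.4, theta_crit=0.5)
        beta = fp.synthetic.beta_truth(theta, truth)
        curve = estimate_stress_curve(
            flue_series(beta + rng.normal(0, 0.05, 3000)), theta)
        assert 0.3 <= curve.flue0 <= 0.5
        assert curve.flue0_method == "dry_median"

    def test_fit_fallback_without_very_dry_days(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0.15, 1.0, 3000)
        truth = fp.TruthParams(flue0=0.4, theta_crit=0.5)
        beta = fp.synthetic.beta_truth(theta, truth)
        curve = estimate_stress_curve(flue_series(beta), theta)
        assert curve.flue0_method == "piecewise_fit"
        assert curve.flue0 == pytest.approx(0.4, abs=0.1)

    def test_never_dry_site_flagged(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0.6, 1.0, 1000)
        curve = estimate_stress_curve(flue_series(np.ones(1000)), theta)
        assert curve.no_dry_days
        assert np.isnan(curve.flue0)

    def test_ordering_preserved_across_sites(self):
        rng = np.random.default_rng(4)
        theta = rng.uniform(0, 1, 3000)
        ests = []
        for f0 in (0.4, 0.7, 0.9):
            beta = fp.synthetic.beta_truth(
                theta, fp.TruthParams(flue0=f0, theta_crit=0.5))
            c = estimate_stress_curve(
                flue_series(beta + rng.normal(0, 0.05, 3000)), theta)
            ests.append(c.flue0)
        assert ests[0] < ests[1] < ests[2]

    def test_median_monotone_below_threshold(self):
        rng = np.random.default_rng(5)
        theta = rng.uniform(0, 1, 5000)
        beta = fp.synthetic.beta_truth(
            theta, fp.TruthParams(flue0=0.4, theta_crit=0.5))
        curve = estimate_stress_curve(
            flue_series(beta + rng.normal(0, 0.03, 5000)), theta)
        med = curve.bins["flue_median"].to_numpy()[:10]  # bins below 0.5
        assert (np.diff(med) >= -0.02).all()


class TestGppLoss:
    @staticmethod
    def full_year_series(values_by_day):
        idx = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        return idx, len(idx)

    def test_no_stress_no_loss(self):
        idx = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        gpp_pot = pd.Series(5.0, index=idx)
        flue = pd.Series(1.0, index=idx)
        out = annual_gpp_loss(gpp_pot, flue)
        np.testing.assert_allclose(out["loss"], 0.0)
        assert list(out["year"]) == [2001, 2002]

    def test_half_loss_on_half_the_production(self):
        idx = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        gpp_pot = pd.Series(0.0, index=idx)
        flue = pd.Series(1.0, index=idx)
        # half the annual potential carried by days at flue 0.5
        gpp_pot.iloc[:100] = 10.0
        gpp_pot.iloc[100:200] = 10.0
        flue.iloc[:100] = 0.5
        out = annual_gpp_loss(gpp_pot, flue)
        assert out["loss"].iloc[0] == pytest.approx(0.25)

    def test_partial_years_excluded(self):
        idx = pd.date_range("2001-06-01", "2002-12-31", freq="D")
        out = annual_gpp_loss(pd.Series(5.0, index=idx),
                              pd.Series(1.0, index=idx))
        assert list(out["year"]) == [2002]

    def test_matches_generator_truth(self, stressed_site, stressed_result):
        site, res = stressed_site, stressed_result
        clean = site["clean_series"]
        beta = site["beta_truth"]
        unstressed = (clean["par"] * clean["evi_true_daily"]
                      * fp.synthetic.lue_unstressed(
                          clean["ta"], clean["vpd"], site["truth"]))
        true_loss = 1 - float((unstressed * beta).sum() / unstressed.sum())
        est = res.annual_loss.attrs["mean_loss"]
        assert est == pytest.approx(true_loss, abs=0.05)


class TestCumulativeDeficit:
    def test_event_arithmetic(self):
        x = np.ones(400)
        x[50:60] = 0.6
        flue = flue_series(x)
        events = detect_events(flue, 0.9)
        assert events.iloc[0]["cum_deficit"] == pytest.approx(4.0)
        per_year = cumulative_deficit(flue, events)
        assert per_year["cum_deficit"].sum() == pytest.approx(4.0)

    def test_no_events_zero_deficit(self):
        flue = flue_series(np.ones(400))
        events = detect_events(flue, 0.9)
        per_year = cumulative_deficit(flue, events)
        assert (per_year["cum_deficit"] == 0).all()

    def test_sum_matches_masked_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 1.1, 600)
        flue = flue_series(x)
        events = detect_events(flue, 0.8, min_duration=3)
        mask = np.zeros(600, bool)
        for _, e in events.iterrows():
            mask[int(e["onset_idx"]):int(e["onset_idx"] + e["length"])] = True
        expected = np.sum(1 - x[mask])
        per_year = cumulative_deficit(flue, events)
        assert per_year["cum_deficit"].sum() == pytest.approx(expected)
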