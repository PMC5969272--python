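"""LUE networks, the moist/dry split, fLUE and its diagnostics."""

import numpy as np
import pandas as pd
import pytest

import fluepart as fp
from fluepart.flue import (LUEPredictions, compute_flue, ensemble_flue,
                           optimize_moist_threshold, site_performance_gate,
                           regime_bias, vpd_sensitivity_profile)
from fluepart.nn import (InsufficientDataError, scale_predictors, train_lue_nn,
                         unscale)

HYPER = fp.NNHyper(cv_repeats=1, hidden_nodes_grid=(8, 12), outer_repeats=2,
                   max_iter=300, seed=0)


def feature_frame(n=800, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2001-01-01", periods=n, freq="D")
    return pd.DataFrame({
        "ta": rng.uniform(0, 30, n),
        "vpd": rng.uniform(100, 2500, n),
        "par": rng.uniform(5, 60, n),
    }, index=idx)


class TestScaling:
    def test_min_max_mapping(self):
        f = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        scaled, record = scale_predictors(f)
        np.testing.assert_allclose(scaled["x"], [0.0, 0.5, 1.0])
        assert record["x"] == (2.0, 6.0)

    def test_constant_feature_rejected_by_name(self):
        f = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            scale_predictors(f)

    def test_roundtrip(self):
        f = feature_frame(100)
        scaled, record = scale_predictors(f)
        pd.testing.assert_frame_equal(unscale(scaled, record), f)

    def test_record_fitted_on_training_days_only(self):
        f = pd.DataFrame({"x": [0.0, 1.0, 2.0, 100.0]})
        _, record = scale_predictors(f, train_mask=np.array(
            [True, True, True, False]))
        assert record["x"] == (0.0, 2.0)


class TestTrainLueNN:
    def test_linear_target_recovered(self):
        f = feature_frame()
        y = pd.Series(0.02 * f["ta"] + 3e-4 * f["vpd"] + 0.01 * f["par"],
                      index=f.index)
        model = train_lue_nn(f, y, HYPER, min_days=100)
        pred = model.predict(f)
        ss = 1 - np.sum((pred - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss > 0.99

    def test_constant_target_reproduced(self):
        f = feature_frame()
        y = pd.Series(np.full(len(f), 0.7), index=f.index)
        model = train_lue_nn(f, y, HYPER, min_days=100)
        np.testing.assert_allclose(model.predict(f), 0.7, atol=0.02)

    def test_permuted_target_has_no_skill(self):
        rng = np.random.default_rng(0)
        f = feature_frame()
        y_struct = 0.02 * f["ta"] + 0.01 * f["par"]
        y = pd.Series(rng.permutation(y_struct.to_numpy()), index=f.index)
        # null oracle: out-of-sample R2 near zero on held-out half
        train = np.arange(len(f)) < 400
        model = train_lue_nn(f.iloc[:400], y.iloc[:400], HYPER, min_days=100)
        pred = model.predict(f.iloc[400:])
        obs = y.iloc[400:].to_numpy()
        r2 = 1 - np.sum((pred - obs) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert abs(r2) < 0.1

    def test_too_few_days_raises(self):
        f = feature_frame(50)
        y = pd.Series(np.ones(50), index=f.index)
        with pytest.raises(InsufficientDataError, match="insufficient"):
            train_lue_nn(f, y, HYPER)

    def test_selection_log_records_each_repeat(self):
        f = feature_frame()
        y = pd.Series(0.02 * f["ta"], index=f.index)
        model = train_lue_nn(f, y, HYPER, min_days=100)
        assert len(model.selection_log) == HYPER.outer_repeats
        assert set(model.selection_log["nodes"]) <= set(HYPER.hidden_nodes_grid)


def _toy_predictions(n=10, act=1.0, pot=1.0, obs=1.0):
    idx = pd.date_range("2001-01-01", periods=n, freq="D")
    frame = pd.DataFrame({
        "lue_obs": np.full(n, obs), "lue_act": np.full(n, act),
        "lue_pot": np.full(n, pot), "lue_vpd": np.full(n, act),
        "moist_flag": np.ones(n, dtype=bool),
    }, index=idx)
    return LUEPredictions(frame=frame, threshold=0.5)


class TestComputeFlue:
    def test_equal_models_give_unity(self):
        flue = compute_flue(_toy_predictions(), floor=0.01)
        np.testing.assert_allclose(flue, 1.0)

    def test_ratio_arithmetic(self):
        flue = compute_flue(_toy_predictions(act=0.35, pot=0.7), floor=0.01)
        np.testing.assert_allclose(flue, 0.5)

    def test_clip_ceiling_and_logging(self):
        flue = compute_flue(_toy_predictions(act=2.0, pot=1.0), floor=0.01)
        assert (flue == 1.5).all()
        assert flue.attrs["n_clip_events"] == len(flue)

    def test_floor_stabilises_ratio(self):
        flue = compute_flue(_toy_predictions(act=0.5, pot=1e-9), floor=0.25)
        np.testing.assert_allclose(flue, 1.5)  # 0.5/0.25 clipped
        assert flue.attrs["n_floor_events"] == len(flue)


class TestEnsembleFlue:
    def test_single_source_collapses(self):
        s = pd.Series([0.5, 1.0])
        out = ensemble_flue({"a": s})
        assert (out["flue_mean"] == out["flue_min"]).all()
        assert (out["flue_mean"] == out["flue_max"]).all()

    def test_two_source_envelope(self):
        out = ensemble_flue({"a": pd.Series([0.4]), "b": pd.Series([0.6])})
        assert out["flue_mean"].iloc[0] == pytest.approx(0.5)
        assert out["flue_min"].iloc[0] == pytest.approx(0.4)
        assert out["flue_max"].iloc[0] == pytest.approx(0.6)
        assert out["n_sources"].iloc[0] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_flue({})


class TestThresholdSearch:
    def test_single_candidate_returned(self, cleaned_series, stressed_site):
        res = optimize_moist_threshold(
            cleaned_series, stressed_site["theta_rel_truth"],
            cleaned_series["lue_obs"], candidate_grid=(0.5,),
            hyper=fp.SEARCH_HYPER.with_(outer_repeats=1))
        assert res.threshold == 0.5

    def test_no_stress_site_flagged(self):
        cfg = fp.SyntheticConfig(n_days=1462, seed=5,
                                 dry_spell_blocks=fp.synthetic.yearly_dry_season(5))
        site = fp.synthetic.generate_site(cfg, fp.TruthParams(flue0=1.0))
        cleaned = fp.qc.build_cleaned_series(site["series"],
                                             site["evi_samples"])
        res = optimize_moist_threshold(
            cleaned, site["theta_rel_truth"], cleaned["lue_obs"],
            candidate_grid=(0.35, 0.5, 0.65),
            hyper=fp.SEARCH_HYPER.with_(outer_repeats=1))
        assert res.no_limitation

    def test_all_candidates_skipped_raises(self, cleaned_series,
                                           stressed_site):
        with pytest.raises(InsufficientDataError):
            optimize_moist_threshold(
                cleaned_series, stressed_site["theta_rel_truth"],
                cleaned_series["lue_obs"], candidate_grid=(0.999,),
                hyper=fp.SEARCH_HYPER.with_(outer_repeats=1))


class TestTripletAndGate:
    def test_moist_day_agreement_and_dry_gap(self, stressed_result):
        pred = stressed_result.predictions["splash150"]
        f = pred.frame
        moist = f["moist_flag"]
        act, pot = f["lue_act"][moist], f["lue_pot"][moist]
        r2 = 1 - np.sum((act - pot) ** 2) / np.sum((pot - pot.mean()) ** 2)
        assert r2 > 0.9
        assert f["lue_pot"][~moist].mean() > f["lue_act"][~moist].mean()

    def test_gate_passes_on_clean_synthetic(self, stressed_result):
        assert stressed_result.gate.passed, stressed_result.gate.checks

    def test_gate_fails_on_shuffled_observations(self, stressed_result):
        pred = stressed_result.predictions["splash150"]
        rng = np.random.default_rng(0)
        frame = pred.frame.copy()
        obs = frame["lue_obs"].to_numpy().copy()
        finite = np.isfinite(obs)
        obs[finite] = rng.permutation(obs[finite])
        frame["lue_obs"] = obs
        shuffled = LUEPredictions(frame=frame, threshold=pred.threshold)
        gate = site_performance_gate(shuffled,
                                     stressed_result.flue["splash150"],
                                     stressed_result.events)
        assert not gate.checks["r2_act"]

    def test_gate_fails_on_short_record(self, stressed_result):
        pred = stressed_result.predictions["splash150"]
        short = LUEPredictions(frame=pred.frame.iloc[:400],
                               threshold=pred.threshold)
        gate = site_performance_gate(short,
                                     stressed_result.flue["splash150"].iloc[:400],
                                     stressed_result.events.iloc[:0])
        assert not gate.checks["enough_days"]


class TestVpdProfile:
    def test_normalised_to_one_at_zero_vpd(self, stressed_result):
        pred = stressed_result.predictions["splash150"]
        prof = vpd_sensitivity_profile(pred.nn_pot, stressed_result.cleaned,
                                       stressed_result.events)
        assert prof["lue_norm"].iloc[0] == pytest.approx(1.0)

    def test_vpd_independent_model_is_flat(self):
        f = feature_frame()
        y = pd.Series(0.02 * f["ta"] + 0.005 * f["par"], index=f.index)
        model = train_lue_nn(f, y, HYPER, min_days=100)
        events = pd.DataFrame({"onset_idx": [100], "length": [10]})
        prof = vpd_sensitivity_profile(model, f, events)
        assert np.abs(prof["lue_norm"] - 1.0).max() < 0.05

    def test_exponential_decay_recovered(self):
        # regression oracle: truth exp(-k vpd) gives fitted k within 20%
        k = 4e-4
        f = feature_frame(1200, seed=2)
        y = pd.Series(0.8 * np.exp(-k * f["vpd"]), index=f.index)
        model = train_lue_nn(f, y, HYPER, min_days=100)
        events = pd.DataFrame({"onset_idx": [600], "length": [10]})
        prof = vpd_sensitivity_profile(model, f, events,
                                       vpd_grid=np.linspace(0, 2000, 40))
        fit = np.polyfit(prof["vpd"], np.log(prof["lue_norm"]), 1)[0]
        assert fit == pytest.approx(-k, rel=0.2)

    def test_no_events_empty_profile(self, stressed_result):
        pred = stressed_result.predictions["splash150"]
        prof = vpd_sensitivity_profile(pred.nn_pot, stressed_result.cleaned,
                                       stressed_result.events.iloc[:0])
        assert prof.empty


class TestRegimeBias:
    def test_perfect_predictions_have_zero_bias(self):
        n = 400
        rng = np.random.default_rng(0)
        idx = pd.date_range("2001-01-01", periods=n, freq="D")
        obs = rng.uniform(0.2, 0.8, n)
        frame = pd.DataFrame({"lue_obs": obs, "lue_act": obs,
                              "lue_pot": obs, "lue_vpd": obs,
                              "moist_flag": np.ones(n, bool)}, index=idx)
        pred = LUEPredictions(frame=frame, threshold=0.5)
        theta = rng.uniform(0, 1, n)
        vpd = rng.uniform(0, 3000, n)
        out = regime_bias(pred, theta, vpd)
        for regime in out.values():
            for model in ("lue_act", "lue_pot", "lue_vpd"):
                assert regime[model]["median"] == pytest.approx(0.0, abs=1e-12)

    def test_day_counts_match_brute_force(self, stressed_result):
        pred = stressed_result.predictions["splash150"]
        theta = stressed_result.ensemble.members["splash150"][
            "theta_rel"].to_numpy()
        vpd = stressed_result.cleaned["vpd"].to_numpy()
        out = regime_bias(pred, theta, vpd)
        obs = pred.frame["lue_obs"].to_numpy()
        q10, q90 = np.nanquantile(vpd, [0.10, 0.90])
        usable = np.isfinite(obs) & (obs > 0)
        assert out["dry_soil_low_vpd"]["n"] == int(
            (usable & (theta < 0.25) & (vpd < q10)).sum())
        assert out["moist_soil_high_vpd"]["n"] == int(
            (usable & (theta > 0.75) & (vpd > q90)).sum())
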