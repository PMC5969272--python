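"""Reference study conditions: the synthetic experiments that characterise
the pipeline.

Each function here sets up a fixed synthetic experiment — stress-function
recovery across nine sites, the four-archetype classification cohort, the
drought-index contrast on a seasonally dry site, determinism and
bookkeeping checks — runs the package on it, and returns the measured
quantities. The example scripts and the test suite both consume these.
"""

from __future__ import annotations

import io as _io
import time

import numpy as np
import pandas as pd

from . import events as ev
from . import flue as fl
from . import indices, io, pipeline, qc, synthetic, water
from .types import FAST_HYPER, SEARCH_HYPER, BucketParams, SyntheticConfig, TruthParams

RECOVERY_FLUE0 = (0.4, 0.7, 0.9)
RECOVERY_THETA_CRIT = 0.5
RECOVERY_YEARS = 6
#: Strong and moderate stress levels: the regimes where a moist/dry split is
#: statistically identifiable (the 0.9 level is the low-sensitivity class).
DETECTABLE_FLUE0 = (0.4, 0.7)


def stressed_site_config(seed: int, n_years: int = RECOVERY_YEARS,
                         **kw) -> SyntheticConfig:
    """Standard seasonally dry site: one ~4-month dry season per year."""
    n_days = int(365.25 * n_years) + 1
    return SyntheticConfig(
        n_days=n_days, seed=seed,
        dry_spell_blocks=synthetic.yearly_dry_season(n_years + 1), **kw)


def run_recovery_site(flue0: float, seed: int, hyper=None,
                      n_years: int = RECOVERY_YEARS) -> dict:
    """Generate one stressed site, run the pipeline, measure recovery.

    The soil-moisture ensemble is the two Priestley-Taylor bucket
    capacities; recovery quantities are measured against the driving
    bucket's relative soil water (where the generative truth is defined).
    """
    if hyper is None:
        hyper = FAST_HYPER.with_(outer_repeats=3)
    cfg = stressed_site_config(seed)
    truth = TruthParams(flue0=flue0, theta_crit=RECOVERY_THETA_CRIT)
    site = synthetic.generate_site(cfg, truth)
    t0 = time.time()
    res = pipeline.process_site(site["series"], site["evi_samples"],
                                sources=("splash150", "splash220"),
                                hyper=hyper, seed=seed + 3)
    runtime = time.time() - t0

    beta = site["beta_truth"]
    flue = res.flue_ensemble["flue_mean"]
    theta150 = res.ensemble.members["splash150"]["theta_rel"].to_numpy()
    curve = ev.estimate_stress_curve(flue, theta150)
    pred150 = res.predictions["splash150"]
    bias_vals = fl.regime_bias_values(pred150, theta150,
                                      res.cleaned["vpd"].to_numpy())
    return {
        "flue0_true": flue0,
        "seed": seed,
        "flue0_est": curve.flue0,
        "threshold": res.thresholds["splash150"].threshold,
        "threshold_err": res.thresholds["splash150"].threshold
        - RECOVERY_THETA_CRIT,
        "flue_rmse_vs_truth": float(
            np.sqrt(np.nanmean((flue.to_numpy() - beta) ** 2))),
        "moist_day_median_flue": float(
            np.nanmedian(flue.to_numpy()[res.moist_flag])),
        "runtime_s": runtime,
        "regime_bias_values": bias_vals,
        "result": res,
        "site": site,
    }


def recovery_study(seeds=(1, 2, 3), flue0_levels=RECOVERY_FLUE0,
                   hyper=None) -> list[dict]:
    """The nine-site stress-function recovery experiment."""
    return [run_recovery_site(f0, s, hyper=hyper)
            for f0 in flue0_levels for s in seeds]


def pooled_regime_bias(rows: list[dict],
                       flue0_levels=DETECTABLE_FLUE0) -> dict:
    """Median log-bias per model and regime, pooled across stressed sites."""
    pools: dict[str, dict[str, list]] = {}
    for row in rows:
        if row["flue0_true"] not in flue0_levels:
            continue
        for regime, entry in row["regime_bias_values"].items():
            for model, vals in entry.items():
                pools.setdefault(regime, {}).setdefault(model, []).append(vals)
    out = {}
    for regime, models in pools.items():
        out[regime] = {m: float(np.median(np.concatenate(v)))
                       for m, v in models.items()}
        out[regime]["n"] = int(sum(len(a) for a in
                                   models["lue_act"]))
    return out


# ---------------------------------------------------------------------------
# Water-balance closure

def water_closure_study(seed: int = 0, n_days: int = 400) -> dict:
    """Mass-balance residuals of every bucket model on random forcing."""
    rng = np.random.default_rng(seed)
    precip = np.where(rng.random(n_days) < 0.3,
                      rng.exponential(5.0, n_days), 0.0)
    pet = rng.uniform(0.0, 6.0, n_days)
    le = rng.uniform(0.0, 6e6, n_days)
    residuals = {}
    runs = {
        "splash150": water.run_splash(precip, pet,
                                      BucketParams(capacity=150.0)),
        "splash220": water.run_splash(precip, pet,
                                      BucketParams(capacity=220.0)),
        "swbm": water.run_swbm(precip, np.clip(pet, 0, None)),
        "etbucket_norunoff": water.run_et_bucket(
            precip, le, BucketParams(runoff_mode="at_capacity")),
        "etbucket_runoff": water.run_et_bucket(
            precip, le, BucketParams(runoff_mode="pre_capacity")),
    }
    for name, sm in runs.items():
        residuals[name] = abs(water.mass_balance_residual(sm))
    return {
        "max_abs_residual_mm": max(residuals.values()),
        "residuals": residuals,
        "et_conversion_mm": float(water.le_to_mm(2.26476e6)),
    }


# ---------------------------------------------------------------------------
# Filter bookkeeping

def filter_bookkeeping_study(seed: int = 0) -> dict:
    """Known-defect injection vs what the GPP filters remove.

    Uses a warm, low-noise configuration so the injected negative-GPP days
    are the only negative days, making the bookkeeping exact; a second,
    outlier-free table measures the two-sided 5% consistency removal.
    """
    cfg = SyntheticConfig(
        n_days=2192, seed=seed, temp_mean=18.0, temp_amplitude=5.0,
        noise_sd_gpp=0.3, negative_gpp_prob=0.01, nt_dt_outlier_prob=0.0,
        gapfill_frac_prob=0.05)
    truth = TruthParams(flue0=0.6)
    site = synthetic.generate_site(cfg, truth)
    cleaned = qc.clean_gpp(site["series"])
    counts = qc.removal_counts(cleaned).to_dict()
    defects = site["defects"]
    n_retained_after_gapfill = len(cleaned) - counts.get("gapfill", 0)
    return {
        "injected_gapfill": int(defects["gapfill_days"].size),
        "removed_gapfill": int(counts.get("gapfill", 0)),
        "injected_negative": int(defects["negative_days"].size),
        "removed_negative": int(counts.get("negative", 0)),
        "removed_inconsistent": int(counts.get("nt_dt_inconsistent", 0)),
        "expected_inconsistent": 0.05 * n_retained_after_gapfill,
    }


# ---------------------------------------------------------------------------
# Event-detection equivalence

def _brute_force_runs(x: np.ndarray, threshold: float, min_duration: int
                      ) -> list[tuple[int, int]]:
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


def event_equivalence_study(n_series: int = 1000, n_days: int = 400,
                            seed: int = 0) -> dict:
    """Run-length scan vs the vectorised detector on random fLUE series."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_series):
        x = rng.uniform(0.3, 1.3, n_days)
        idx = pd.date_range("2001-01-01", periods=n_days, freq="D")
        events = ev.detect_events(pd.Series(x, index=idx), 0.8,
                                  min_duration=4, max_gap=0)
        got = [(int(e["onset_idx"]), int(e["length"]))
               for _, e in events.iterrows()]
        if got == _brute_force_runs(x, 0.8, 4):
            matches += 1
    return {"n_series": n_series, "match_fraction": matches / n_series}


# ---------------------------------------------------------------------------
# Archetype cohorts

def cohort_study(seed: int = 0, noisy: bool = True) -> dict:
    cohort = pipeline.generate_cohort(n_per_archetype=5, seed=seed,
                                      noisy=noisy)
    table = pipeline.classify_cohort(cohort, seed=seed)
    accuracy = float((table["label"] == table["expected"]).mean())
    return {"accuracy": accuracy, "table": table}


# ---------------------------------------------------------------------------
# Drought indices

def index_standardisation_study(seed: int = 0, n_years: int = 100) -> dict:
    """SPI/SPEI of a stationary century-long synthetic climate."""
    cfg = SyntheticConfig(n_days=int(365.25 * n_years) + 1, seed=seed)
    forcing = synthetic.generate_forcing(cfg)
    pet = water.priestley_taylor_pet(forcing["netrad"].to_numpy(),
                                     forcing["ta"].to_numpy())
    monthly = indices.monthly_climate(forcing, pet_daily=pet)
    spi = indices.compute_spi(monthly["precip_total"])
    spei = indices.compute_spei(monthly["precip_total"]
                                - monthly["pet_total"])
    return {
        "spi_mean": float(spi.mean()), "spi_sd": float(spi.std()),
        "spei_mean": float(spei.mean()), "spei_sd": float(spei.std()),
        "n_months": int(len(monthly)),
    }


def drought_contrast_study(seed: int = 0, n_years: int = 20,
                           hyper=None) -> dict:
    """Index behaviour inside vs outside fLUE droughts on a seasonally dry
    site.

    The dry season recurs every year (a small in-season wet probability
    keeps the SPI defined), so the monthly anomaly indices score near zero
    during physiological drought while the daily AET/PET ratio separates
    the two regimes.
    """
    if hyper is None:
        hyper = FAST_HYPER.with_(hidden_nodes_grid=(12,), outer_repeats=2)
    cfg = stressed_site_config(seed, n_years=n_years,
                               dry_spell_wet_prob=0.08)
    truth = TruthParams(flue0=0.4, theta_crit=RECOVERY_THETA_CRIT)
    site = synthetic.generate_site(cfg, truth)
    res = pipeline.process_site(site["series"], site["evi_samples"],
                                sources=("splash150",), hyper=hyper,
                                search_hyper=SEARCH_HYPER.with_(
                                    outer_repeats=2, seed=seed),
                                seed=seed + 7)
    drought_mask = np.zeros(len(site["series"]), dtype=bool)
    for _, e in res.events.iterrows():
        drought_mask[int(e["onset_idx"]):int(e["onset_idx"] + e["length"])] = True

    sm = res.ensemble.members["splash150"]
    monthly = indices.monthly_climate(site["series"],
                                      pet_daily=sm["pet"].to_numpy())
    spi = indices.compute_spi(monthly["precip_total"])
    spei = indices.compute_spei(monthly["precip_total"]
                                - monthly["pet_total"])
    dates = site["series"].index
    ok_pet = sm["pet"].to_numpy() > 0
    aet_pet = np.where(ok_pet, sm["aet"].to_numpy()
                       / np.where(ok_pet, sm["pet"].to_numpy(), 1.0), np.nan)
    daily = pd.DataFrame({
        "spi": indices.broadcast_monthly(spi, dates),
        "spei": indices.broadcast_monthly(spei, dates),
        "aet_over_pet": np.clip(aet_pet, 0, 1),
    }, index=dates)
    contrast = indices.contrast_by_drought(daily, drought_mask)
    tests = contrast.tests.set_index("variable")
    return {
        "contrast": contrast,
        "n_drought_days": int(drought_mask.sum()),
        "separation_aet_pet": float(tests.loc["aet_over_pet",
                                              "median_separation"]),
        "separation_spi": float(tests.loc["spi", "median_separation"]),
        "separation_spei": float(tests.loc["spei", "median_separation"]),
        "p_aet_pet": float(tests.loc["aet_over_pet", "p"]),
    }


# ---------------------------------------------------------------------------
# Determinism

def determinism_study(seed: int = 0) -> dict:
    """Byte-identity of all written outputs across two identically seeded
    end-to-end runs."""
    def one_run() -> bytes:
        cfg = stressed_site_config(seed, n_years=4)
        truth = TruthParams(flue0=0.5, theta_crit=RECOVERY_THETA_CRIT)
        site = synthetic.generate_site(cfg, truth)
        res = pipeline.process_site(
            site["series"], site["evi_samples"], sources=("splash150",),
            hyper=FAST_HYPER.with_(hidden_nodes_grid=(12,), outer_repeats=2),
            search_hyper=SEARCH_HYPER.with_(outer_repeats=2, seed=seed),
            seed=seed + 7)
        buf = _io.StringIO()
        io.write_site_table(site["series"], buf)
        io.write_flue_table(res.flue_ensemble, buf)
        io.write_soil_moisture_table(res.ensemble.members["splash150"], buf)
        res.events.to_csv(buf)
        return buf.getvalue().encode()

    first, second = one_run(), one_run()
    return {"byte_identical": first == second, "n_bytes": len(first)}
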