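"""Synthetic flux-site generator with a known soil-moisture stress on LUE.

Builds daily site tables with the statistical structure the downstream
analysis assumes: stochastic weather with seasonal cycles and dry spells,
GPP produced as ``PAR * fAPAR * LUE`` with a multiplicative, piecewise-linear
soil-moisture stress ``beta`` on LUE, latent heat proportional to bucket-model
AET, a seasonal (optionally drought-deciduous) greenness curve, and an
observation-degradation step that injects the defects the quality-control
filters are designed to remove.

All generators are pure functions of (config, truth, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import BucketParams, SyntheticConfig, TruthParams
from . import water

LATENT_HEAT_J_PER_MM = 2.26476e6  # J per mm water, latent heat flux conversion

FORCING_COLUMNS = ["ta", "sw_in", "par", "vpd", "precip", "netrad"]


def _seasonal(doy: np.ndarray, peak_doy: float = 200.0) -> np.ndarray:
    """Unit-amplitude seasonal cycle peaking at ``peak_doy`` (northern summer)."""
    return np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def generate_forcing(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the daily meteorological forcing for one site.

    Returns a DataFrame indexed by date with columns ``ta`` (degC),
    ``sw_in`` (MJ m-2 d-1), ``par`` (mol m-2 d-1), ``vpd`` (Pa),
    ``precip`` (mm d-1) and ``netrad`` (MJ m-2 d-1). Precipitation is
    suppressed inside the configured dry-spell blocks and VPD carries a
    positive antecedent-dryness component, so that dry spells are also
    atmospherically dry (while day-to-day noise keeps the two partly
    decoupled).
    """
    n = config.n_days
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range("2001-01-01", periods=n, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    season = _seasonal(doy)
    if config.latitude < 0:  # southern hemisphere: shift peak by half a year
        season = -season

    ta = config.temp_mean + config.temp_amplitude * season + _ar1(rng, n, 0.7, 2.0)
    sw = config.sw_mean + config.sw_amplitude * season + rng.normal(0.0, 1.5, n)
    sw = np.clip(sw, 0.5, None)

    wet_prob = np.full(n, config.precip_wet_prob)
    for start, length in config.dry_spell_blocks:
        lo = max(0, int(start))
        hi = min(n, int(start) + int(length))
        wet_prob[lo:hi] = config.dry_spell_wet_prob
    wet = rng.random(n) < wet_prob
    depth = rng.exponential(config.precip_mean_depth, n)
    precip = np.where(wet, depth, 0.0)

    # antecedent wetness: exponential moving average of precipitation
    wetness = np.empty(n)
    w = config.precip_wet_prob * config.precip_mean_depth
    lam = 1.0 / 20.0  # 20-day memory
    for i in range(n):
        w = (1.0 - lam) * w + lam * precip[i]
        wetness[i] = w
    dryness = 1.0 / (1.0 + wetness)  # 0 (wet) .. 1 (prolonged dry)

    # day-to-day multiplicative variability (advection, entrainment) keeps
    # VPD and soil moisture partly decoupled: some dry-soil days have moist
    # air and some moist-soil days have very dry air
    c_temp, c_dry = config.vpd_coupling
    core = config.vpd_base + c_temp * (ta - config.temp_mean) + c_dry * dryness
    sigma = config.vpd_lognorm_sd
    advect = rng.lognormal(-0.5 * sigma**2, sigma, n)
    vpd = np.clip(core, 50.0, None) * advect + \
        rng.normal(0.0, config.vpd_noise_sd, n)
    # synoptic decoupling events: moist-air intrusions collapse VPD even over
    # dry soil; dry-air advection spikes VPD even over moist soil
    intrusion = rng.random(n) < config.vpd_intrusion_prob
    vpd[intrusion] = rng.uniform(60.0, 300.0, int(intrusion.sum()))
    spike = (~intrusion) & (rng.random(n) < config.vpd_spike_prob)
    vpd[spike] *= rng.uniform(2.2, 3.5, int(spike.sum()))
    vpd = np.clip(vpd, 30.0, None)

    netrad = config.netrad_slope * sw + config.netrad_intercept
    par = sw * config.par_conversion

    return pd.DataFrame(
        {"ta": ta, "sw_in": sw, "par": par, "vpd": vpd, "precip": precip,
         "netrad": netrad},
        index=pd.Index(dates, name="date"),
    )


def beta_truth(theta_rel, truth: TruthParams):
    """Piecewise-linear soil-moisture stress factor on LUE.

    ``beta = 1`` for relative soil water at or above ``theta_crit`` and
    declines linearly to ``flue0`` at zero; continuous at the breakpoint.
    """
    theta = np.asarray(theta_rel, dtype=float)
    if np.any((theta < 0.0) | (theta > 1.0)):
        raise ValueError("theta_rel must lie in [0, 1]")
    below = truth.flue0 + (1.0 - truth.flue0) * theta / truth.theta_crit
    out = np.where(theta >= truth.theta_crit, 1.0, below)
    if np.isscalar(theta_rel):
        return float(out)
    return out


def _fapar_seasonal(dates: pd.DatetimeIndex, truth: TruthParams,
                    latitude: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy().astype(float)
    season = _seasonal(doy)
    if latitude < 0:
        season = -season
    # map the unit cosine onto [base, base + amplitude]
    return truth.fapar_base + truth.fapar_amplitude * 0.5 * (1.0 + season)


def _greenness_multiplier(beta: np.ndarray, truth: TruthParams) -> np.ndarray:
    """Lagged multiplicative greenness response to soil-moisture stress.

    Greenness relaxes towards ``1 - sensitivity * (1 - beta)`` with an
    e-folding time of ``greenness_lag`` days, emulating drought-deciduous
    canopies shedding (and regrowing) leaf area with a delay.
    """
    n = beta.size
    m = np.empty(n)
    state = 1.0
    k = 1.0 / max(truth.greenness_lag, 1.0)
    for i in range(n):
        target = max(0.05, 1.0 - truth.greenness_sensitivity * (1.0 - beta[i]))
        state += k * (target - state)
        m[i] = state
    return m


def lue_unstressed(ta, vpd, truth: TruthParams):
    """True LUE without the soil-moisture factor: lue_max * g(T) * exp(-k VPD)."""
    g_t = np.exp(-((np.asarray(ta) - truth.temp_opt) ** 2)
                 / (2.0 * truth.temp_width**2))
    return truth.lue_max * g_t * np.exp(-truth.vpd_k * np.asarray(vpd))


def generate_fluxes(forcing: pd.DataFrame, theta_rel: np.ndarray,
                    truth: TruthParams, config: SyntheticConfig,
                    seed: int, aet: np.ndarray | None = None
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Fill fluxes and greenness into a forcing table; return true beta too.

    ``gpp_nt`` is ``PAR * fAPAR * LUE_true`` plus Gaussian observation noise;
    ``gpp_dt`` adds independent noise to ``gpp_nt``. Latent heat is the
    driving bucket-model AET converted at the latent-heat constant. Quality
    fractions are initialised to zero (see :func:`degrade_observations`).
    """
    theta_rel = np.asarray(theta_rel, dtype=float)
    if len(theta_rel) != len(forcing):
        raise ValueError("theta_rel and forcing must have equal length")
    rng = np.random.default_rng(seed)
    beta = beta_truth(theta_rel, truth)

    fapar_season = _fapar_seasonal(forcing.index, truth, config.latitude)
    if truth.deciduous:
        fapar = fapar_season * _greenness_multiplier(beta, truth)
    else:
        fapar = fapar_season
    fapar = np.clip(fapar, 0.02, 1.0)

    lue_true = lue_unstressed(forcing["ta"].to_numpy(),
                              forcing["vpd"].to_numpy(), truth) * beta
    gpp_true = forcing["par"].to_numpy() * fapar * lue_true
    gpp_nt = gpp_true + rng.normal(0.0, config.noise_sd_gpp, len(forcing))
    gpp_dt = gpp_nt + rng.normal(0.0, config.noise_sd_gpp * 0.7, len(forcing))

    if aet is None:
        aet = np.zeros(len(forcing))
    le = np.asarray(aet, dtype=float) * LATENT_HEAT_J_PER_MM

    out = forcing.copy()
    out["le"] = le
    out["gpp_nt"] = gpp_nt
    out["gpp_dt"] = gpp_dt
    out["gpp_qc_frac"] = 0.0
    out["le_qc_frac"] = 0.0
    out["evi_true_daily"] = fapar
    return out, beta


def degrade_observations(series: pd.DataFrame, config: SyntheticConfig,
                         seed: int) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Inject the observation defects the QC filters are designed to remove.

    Assigns per-day gap-fill quality fractions (a configurable share above
    the filter thresholds), injects negative-GPP days and gross night/day
    partitioning disagreements on disjoint day sets, and subsamples the true
    daily greenness every 16 days with noise, flagging a known subset as
    contaminated (their values pulled towards zero, as cloud or snow
    contamination does).

    Returns (degraded series, greenness sample table, defect record).
    The defect record holds the injected day indices for bookkeeping tests.
    """
    rng = np.random.default_rng(seed)
    n = len(series)
    out = series.copy()

    gap_days = np.flatnonzero(rng.random(n) < config.gapfill_frac_prob)
    qc = rng.uniform(0.0, 0.45, n)
    qc[gap_days] = rng.uniform(0.5, 1.0, gap_days.size)
    out["gpp_qc_frac"] = qc

    le_gap_days = np.flatnonzero(rng.random(n) < config.le_gapfill_frac_prob)
    le_qc = rng.uniform(0.0, 0.75, n)
    le_qc[le_gap_days] = rng.uniform(0.81, 1.0, le_gap_days.size)
    out["le_qc_frac"] = le_qc

    # negative-GPP days: only on days that survive the gap-fill filter, with
    # the night/day difference kept central so the consistency filter cannot
    # claim them first (each removed day carries exactly one reason)
    ok = np.setdiff1d(np.arange(n), gap_days)
    neg_days = ok[rng.random(ok.size) < config.negative_gpp_prob]
    gpp_nt = out["gpp_nt"].to_numpy().copy()
    gpp_dt = out["gpp_dt"].to_numpy().copy()
    gpp_nt[neg_days] = rng.uniform(-2.0, -0.1, neg_days.size)
    gpp_dt[neg_days] = gpp_nt[neg_days]

    remaining = np.setdiff1d(ok, neg_days)
    outlier_days = remaining[rng.random(remaining.size) < config.nt_dt_outlier_prob]
    gpp_dt[outlier_days] += rng.choice([-1.0, 1.0], outlier_days.size) * \
        rng.uniform(8.0, 15.0, outlier_days.size)
    out["gpp_nt"] = gpp_nt
    out["gpp_dt"] = gpp_dt

    # 16-day greenness extracts with noise and contamination flags
    idx = np.arange(0, n, 16)
    evi = series["evi_true_daily"].to_numpy()[idx] + \
        rng.normal(0.0, config.noise_sd_evi, idx.size)
    contaminated = rng.random(idx.size) < config.evi_contaminated_prob
    evi = np.where(contaminated, evi * rng.uniform(0.0, 0.4, idx.size), evi)
    evi = np.clip(evi, -0.2, 1.0)
    samples = pd.DataFrame(
        {"evi": evi,
         "qa_flag": np.where(contaminated, "contaminated", "good")},
        index=pd.Index(series.index[idx], name="date"),
    )

    defects = {
        "gapfill_days": gap_days,
        "le_gapfill_days": le_gap_days,
        "negative_days": neg_days,
        "outlier_days": outlier_days,
        "contaminated_samples": np.flatnonzero(contaminated),
    }
    return out, samples, defects


def yearly_dry_season(n_years: int, start_doy: int = 150, length: int = 120
                      ) -> tuple[tuple[int, int], ...]:
    """Dry-spell blocks recurring every year at the same day of year."""
    return tuple((int(start_doy + 365.25 * y), length) for y in range(n_years))


def generate_site(config: SyntheticConfig, truth: TruthParams,
                  driving_bucket: BucketParams | None = None) -> dict:
    """Generate one complete synthetic site, end to end.

    Runs the forcing generator, derives potential evapotranspiration with
    the Priestley-Taylor formulation, drives a soil-moisture bucket (the
    SPLASH-style 150 mm bucket by default) to obtain the true relative soil
    water, builds fluxes with the known stress, and degrades observations.

    Returns a dict with keys ``series`` (degraded daily table),
    ``clean_series`` (before degradation), ``evi_samples``, ``beta_truth``,
    ``theta_rel_truth``, ``defects``, ``config`` and ``truth``.
    """
    if driving_bucket is None:
        driving_bucket = BucketParams(capacity=150.0, runoff_mode="at_capacity")
    forcing = generate_forcing(config)
    pet = water.priestley_taylor_pet(forcing["netrad"].to_numpy(),
                                     forcing["ta"].to_numpy(),
                                     driving_bucket)
    sm = water.run_splash(forcing["precip"].to_numpy(), pet, driving_bucket,
                          dates=forcing.index)
    theta_rel = sm["theta_rel"].to_numpy()
    fluxes, beta = generate_fluxes(forcing, theta_rel, truth, config,
                                   seed=config.seed + 1,
                                   aet=sm["aet"].to_numpy())
    degraded, samples, defects = degrade_observations(fluxes, config,
                                                      seed=config.seed + 2)
    return {
        "series": degraded,
        "clean_series": fluxes,
        "evi_samples": samples,
        "beta_truth": beta,
        "theta_rel_truth": theta_rel,
        "soil_moisture_truth": sm,
        "defects": defects,
        "config": config,
        "truth": truth,
    }
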