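"""Paired-network estimation of the soil-moisture effect on LUE.

Three networks are trained per site and per soil-moisture realisation:

* potential LUE — temperature, VPD and PAR as predictors, trained only on
  days with relatively high soil moisture ("moist days");
* actual LUE — the same predictors plus soil moisture, trained on all days;
* VPD-only LUE — the actual-LUE setup without soil moisture, a control for
  how much of the dryness signal VPD alone can carry.

The ratio of actual over potential LUE (fLUE) isolates the soil-moisture
effect; the moist/dry split threshold is optimised so that the dry-day gap
between potential and actual LUE is large while fLUE stays quiet on moist
days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import MIN_TRAIN_DAYS, InsufficientDataError, LueNN, train_lue_nn
from .types import NNHyper, SEARCH_HYPER

#: Candidate moist/dry thresholds in relative soil water.
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.15, 0.751, 0.05), 2))

POT_FEATURES = ["ta", "vpd", "par"]
FLUE_CLIP_MAX = 1.5


@dataclass
class ThresholdResult:
    threshold: float
    no_limitation: bool
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)


def _feature_frame(data: pd.DataFrame, theta_rel=None) -> pd.DataFrame:
    cols = {c: data[c] for c in POT_FEATURES}
    if theta_rel is not None:
        cols["theta_rel"] = np.asarray(theta_rel, dtype=float)
    return pd.DataFrame(cols, index=data.index)


def optimize_moist_threshold(data: pd.DataFrame, theta_rel, lue_obs: pd.Series,
                             candidate_grid=DEFAULT_THRESHOLD_GRID,
                             hyper: NNHyper = SEARCH_HYPER,
                             min_train: int = MIN_TRAIN_DAYS,
                             gap_sd_factor: float = 1.5) -> ThresholdResult:
    """Choose the relative-soil-water threshold splitting moist from dry days.

    For each candidate the potential-LUE network is retrained on the moist
    side (the actual-LUE network does not depend on the split and is trained
    once); the candidates in the top tercile by mean dry-day gap between
    potential and actual LUE are then ranked by the variance of fLUE on
    moist days, smallest wins. Candidates leaving fewer than 90% of the
    minimum training size on either side are skipped.

    The dry-day gap is evaluated only on dry days whose predictors lie
    inside the moist-training range: outside that support the
    potential-LUE model extrapolates, and its extrapolation error grows
    with the candidate threshold, which would otherwise bias the "highest
    gap" subset towards the wettest splits. When fewer than 30 in-support
    dry days exist the plain dry-day mean is used for that candidate.

    If no candidate's dry-day gap rises above ``gap_sd_factor`` times the
    moist-day spread of (potential - actual) predictions — the level the
    two models disagree by when nothing is limiting — the site is flagged
    ``no_limitation`` (the returned threshold is still the variance-optimal
    candidate).
    """
    theta_rel = np.asarray(theta_rel, dtype=float)
    y = lue_obs.to_numpy(dtype=float)
    finite = np.isfinite(y)
    min_side = int(0.9 * min_train)

    feats_act = _feature_frame(data, theta_rel)
    nn_act = train_lue_nn(feats_act, lue_obs, hyper, day_mask=finite,
                          min_days=min_train)
    act = nn_act.predict(feats_act)
    feats_pot = _feature_frame(data)
    feat_matrix = feats_pot.to_numpy(dtype=float)

    rows = []
    for cand in candidate_grid:
        moist = theta_rel >= cand
        n_moist = int((moist & finite).sum())
        n_dry = int((~moist & finite).sum())
        if n_moist < min_side or n_dry < min_side:
            continue
        try:
            nn_pot = train_lue_nn(feats_pot, lue_obs, hyper,
                                  day_mask=moist & finite, min_days=min_side)
        except InsufficientDataError:
            continue
        pot = nn_pot.predict(feats_pot)
        floor = np.nanpercentile(y[finite & (y > 0)], 1)
        flue = act / np.clip(pot, floor, None)
        lo = feat_matrix[moist & finite].min(axis=0)
        hi = feat_matrix[moist & finite].max(axis=0)
        in_support = np.all((feat_matrix >= lo) & (feat_matrix <= hi), axis=1)
        gap_days = ~moist & finite & in_support
        if gap_days.sum() < 30:
            gap_days = ~moist & finite
        dry_gap = float(np.mean(pot[gap_days] - act[gap_days]))
        moist_var = float(np.var(flue[moist & finite]))
        moist_gap_sd = float(np.std(pot[moist & finite] - act[moist & finite]))
        rows.append({"threshold": float(cand), "dry_gap": dry_gap,
                     "moist_var": moist_var, "moist_gap_sd": moist_gap_sd,
                     "n_moist": n_moist, "n_dry": n_dry,
                     "n_gap_days": int(gap_days.sum())})
    if not rows:
        raise InsufficientDataError(
            "no threshold candidate leaves enough data on both sides")
    table = pd.DataFrame(rows)

    n_top = max(1, int(np.ceil(len(table) / 3)))
    top = table.nlargest(n_top, "dry_gap", keep="first")
    pick = top.loc[top["moist_var"].idxmin()]
    no_limit = bool((table["dry_gap"] <
                     gap_sd_factor * table["moist_gap_sd"]).all())
    return ThresholdResult(threshold=float(pick["threshold"]),
                           no_limitation=no_limit, candidates=table)


@dataclass
class LUEPredictions:
    """Daily observed LUE and the three network predictions for one site
    and one soil-moisture realisation."""

    frame: pd.DataFrame          # lue_obs, lue_act, lue_pot, lue_vpd, moist_flag
    threshold: float
    sm_source: str = ""
    nn_act: LueNN | None = None
    nn_pot: LueNN | None = None
    nn_vpd: LueNN | None = None

    def __getitem__(self, key):
        return self.frame[key]


def predict_lue_triplet(data: pd.DataFrame, theta_rel, lue_obs: pd.Series,
                        threshold: float, hyper: NNHyper,
                        sm_source: str = "", min_train: int = MIN_TRAIN_DAYS
                        ) -> LUEPredictions:
    """Train the three networks at full budget and predict on all days."""
    theta_rel = np.asarray(theta_rel, dtype=float)
    finite = np.isfinite(lue_obs.to_numpy(dtype=float))
    moist = theta_rel >= threshold

    feats_pot = _feature_frame(data)
    feats_act = _feature_frame(data, theta_rel)

    nn_pot = train_lue_nn(feats_pot, lue_obs, hyper,
                          day_mask=moist & finite,
                          min_days=int(0.9 * min_train))
    nn_act = train_lue_nn(feats_act, lue_obs, hyper, day_mask=finite,
                          min_days=min_train)
    nn_vpd = train_lue_nn(feats_pot, lue_obs, hyper.with_(seed=hyper.seed + 1),
                          day_mask=finite, min_days=min_train)

    frame = pd.DataFrame({
        "lue_obs": lue_obs,
        "lue_act": nn_act.predict(feats_act),
        "lue_pot": nn_pot.predict(feats_pot),
        "lue_vpd": nn_vpd.predict(feats_pot),
        "moist_flag": moist,
    }, index=data.index)
    return LUEPredictions(frame=frame, threshold=float(threshold),
                          sm_source=sm_source, nn_act=nn_act, nn_pot=nn_pot,
                          nn_vpd=nn_vpd)


def compute_flue(predictions: LUEPredictions, floor: float | None = None,
                 warn_frac: float = 0.05) -> pd.Series:
    """fLUE = actual / potential LUE, stabilised and clipped to (0, 1.5].

    The denominator is floored at the 1st percentile of positive observed
    LUE (values above 1 are retained up to the clip; wet-day fLUE can
    legitimately exceed 1). The number of floor and clip events is recorded
    in ``.attrs``.
    """
    f = predictions.frame
    obs = f["lue_obs"].to_numpy(dtype=float)
    if floor is None:
        pos = obs[np.isfinite(obs) & (obs > 0)]
        floor = float(np.percentile(pos, 1)) if pos.size else 1e-6
    pot = f["lue_pot"].to_numpy(dtype=float)
    act = f["lue_act"].to_numpy(dtype=float)
    n_floor = int((pot < floor).sum())
    flue = act / np.clip(pot, floor, None)
    n_clip = int((flue > FLUE_CLIP_MAX).sum() + (flue <= 0).sum())
    flue = np.clip(flue, 1e-6, FLUE_CLIP_MAX)
    out = pd.Series(flue, index=f.index, name="flue")
    out.attrs["floor"] = floor
    out.attrs["n_floor_events"] = n_floor
    out.attrs["n_clip_events"] = n_clip
    out.attrs["floor_warning"] = n_floor > warn_frac * len(f)
    return out


def ensemble_flue(flue_by_source: dict[str, pd.Series]) -> pd.DataFrame:
    """Per-day mean and min/max envelope of fLUE across soil-moisture sources."""
    if not flue_by_source:
        raise ValueError("at least one fLUE realisation is required")
    wide = pd.DataFrame(flue_by_source)
    out = pd.DataFrame({
        "flue_mean": wide.mean(axis=1),
        "flue_min": wide.min(axis=1),
        "flue_max": wide.max(axis=1),
    })
    out["n_sources"] = wide.notna().sum(axis=1)
    return out


@dataclass
class GateResult:
    passed: bool
    checks: dict[str, bool]
    diagnostics: dict[str, float]


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    m = np.isfinite(pred) & np.isfinite(obs)
    if m.sum() < 2:
        return np.nan
    ss_res = np.sum((obs[m] - pred[m]) ** 2)
    ss_tot = np.sum((obs[m] - obs[m].mean()) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan


def site_performance_gate(predictions: LUEPredictions, flue: pd.Series,
                          events: pd.DataFrame,
                          rmse_max: float = 2.8, r2_act_min: float = 0.5,
                          r2_pot_min: float = 0.3,
                          min_days: int = MIN_TRAIN_DAYS) -> GateResult:
    """Site retention criteria on model skill and data volume.

    A site passes when: mean actual LUE over drought days is below mean
    potential LUE; the RMSE of both the actual and potential LUE predictions
    against observed LUE stays below 2.8 g C mol-1; R2 of actual vs observed
    LUE exceeds 0.5; R2 of potential vs observed LUE on moist days exceeds
    0.3; and at least 500 cleaned days are available.
    """
    f = predictions.frame
    obs = f["lue_obs"].to_numpy(dtype=float)
    act = f["lue_act"].to_numpy(dtype=float)
    pot = f["lue_pot"].to_numpy(dtype=float)
    moist = f["moist_flag"].to_numpy(dtype=bool)
    finite = np.isfinite(obs)

    drought_days = np.zeros(len(f), dtype=bool)
    for _, ev in events.iterrows():
        drought_days[int(ev["onset_idx"]):int(ev["onset_idx"] + ev["length"])] = True
    if drought_days.any():
        drought_gap_ok = bool(np.mean(act[drought_days]) <
                              np.mean(pot[drought_days]))
        gap = float(np.mean(pot[drought_days]) - np.mean(act[drought_days]))
    else:  # no droughts detected: the criterion is vacuously met
        drought_gap_ok, gap = True, np.nan

    rmse_act = float(np.sqrt(np.nanmean((act[finite] - obs[finite]) ** 2)))
    pm = finite & moist
    rmse_pot = float(np.sqrt(np.nanmean((pot[pm] - obs[pm]) ** 2)))
    r2_act = _r2(act, obs)
    r2_pot = _r2(pot[pm], obs[pm])

    checks = {
        "drought_act_below_pot": drought_gap_ok,
        "rmse_below_max": (rmse_act < rmse_max) and (rmse_pot < rmse_max),
        "r2_act": bool(r2_act > r2_act_min),
        "r2_pot": bool(r2_pot > r2_pot_min),
        "enough_days": bool(finite.sum() >= min_days),
    }
    diags = {"rmse_act": rmse_act, "rmse_pot": rmse_pot, "r2_act": r2_act,
             "r2_pot": r2_pot, "drought_gap": gap,
             "n_days": float(finite.sum())}
    return GateResult(passed=all(checks.values()), checks=checks,
                      diagnostics=diags)


def vpd_sensitivity_profile(model: LueNN, data: pd.DataFrame,
                            events: pd.DataFrame, window: int = 20,
                            vpd_grid=None) -> pd.DataFrame:
    """Normalised LUE response to VPD with other predictors held fixed.

    The non-VPD predictors are frozen at their median over the ``window``
    days preceding each drought onset (pooled across events); VPD is swept
    over ``vpd_grid`` and the prediction normalised by its value at VPD = 0.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["vpd", "lue_norm"])
    pre_rows = []
    for _, ev in events.iterrows():
        i0 = int(ev["onset_idx"])
        if i0 >= window:
            pre_rows.append(data.iloc[i0 - window:i0])
    if not pre_rows:
        return pd.DataFrame(columns=["vpd", "lue_norm"])
    pre = pd.concat(pre_rows)
    base = {c: float(pre[c].median()) for c in model.feature_names if c != "vpd"}
    if vpd_grid is None:
        vpd_grid = np.linspace(0.0, float(data["vpd"].quantile(0.99)), 50)
    sweep = pd.DataFrame({c: np.full(len(vpd_grid), v) for c, v in base.items()})
    sweep["vpd"] = np.asarray(vpd_grid, dtype=float)
    pred = model.predict(sweep[model.feature_names])
    ref = pred[np.argmin(np.abs(np.asarray(vpd_grid)))]
    return pd.DataFrame({"vpd": vpd_grid, "lue_norm": pred / ref})


def regime_bias_values(predictions: LUEPredictions, theta_rel, vpd,
                       theta_lo: float = 0.25, theta_hi: float = 0.75,
                       vpd_q_lo: float = 0.10, vpd_q_hi: float = 0.90) -> dict:
    """Raw per-day log-biases by regime and model (for pooling across sites)."""
    f = predictions.frame
    theta_rel = np.asarray(theta_rel, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    obs = f["lue_obs"].to_numpy(dtype=float)
    q_lo, q_hi = np.nanquantile(vpd, [vpd_q_lo, vpd_q_hi])
    usable = np.isfinite(obs) & (obs > 0)
    regimes = {
        "dry_soil_low_vpd": usable & (theta_rel < theta_lo) & (vpd < q_lo),
        "moist_soil_high_vpd": usable & (theta_rel > theta_hi) & (vpd > q_hi),
    }
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, mask in regimes.items():
        entry = {}
        for model in ("lue_act", "lue_pot", "lue_vpd"):
            pred = f[model].to_numpy(dtype=float)
            ok = mask & (pred > 0)
            entry[model] = np.log(pred[ok] / obs[ok])
        out[name] = entry
    return out


def regime_bias(predictions: LUEPredictions, theta_rel, vpd,
                theta_lo: float = 0.25, theta_hi: float = 0.75,
                vpd_q_lo: float = 0.10, vpd_q_hi: float = 0.90) -> dict:
    """Log-bias of each model in the two soil-moisture/VPD decoupling regimes.

    Regime ``dry_soil_low_vpd``: soil moisture below 0.25 of capacity and
    VPD below its 10% quantile — only soil moisture limits. Regime
    ``moist_soil_high_vpd``: soil moisture above 0.75 and VPD above its 90%
    quantile — only VPD limits. Bias is log(modelled / observed LUE);
    medians and quartiles are returned per model and regime, with day
    counts.
    """
    f = predictions.frame
    theta_rel = np.asarray(theta_rel, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    obs = f["lue_obs"].to_numpy(dtype=float)
    q_lo, q_hi = np.nanquantile(vpd, [vpd_q_lo, vpd_q_hi])
    usable = np.isfinite(obs) & (obs > 0)
    regimes = {
        "dry_soil_low_vpd": usable & (theta_rel < theta_lo) & (vpd < q_lo),
        "moist_soil_high_vpd": usable & (theta_rel > theta_hi) & (vpd > q_hi),
    }
    out: dict[str, dict] = {}
    for name, mask in regimes.items():
        if not mask.any():
            out[name] = {"n": 0}
            continue
        entry: dict[str, object] = {"n": int(mask.sum())}
        for model in ("lue_act", "lue_pot", "lue_vpd"):
            pred = f[model].to_numpy(dtype=float)
            ok = mask & (pred > 0)
            bias = np.log(pred[ok] / obs[ok])
            entry[model] = {
                "median": float(np.median(bias)),
                "q25": float(np.percentile(bias, 25)),
                "q75": float(np.percentile(bias, 75)),
            }
        out[name] = entry
    return out
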