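"""Quality control of daily flux tables and greenness extracts.

Three filters clean daily GPP, applied in this order: (1) drop days on
which at least half of the underlying half-hours were gap-filled; (2) drop
days on which the daytime and night-time partitioning methods disagree,
defined as the difference falling outside its empirical [2.5%, 97.5%]
quantile interval over the retained days (inclusive at the boundary);
(3) drop days with negative GPP. Each removed day carries exactly one
removal reason.

Greenness extracts (16-day samples) are cleaned of contaminated samples,
linearly interpolated to daily resolution and smoothed with a
Savitzky-Golay filter of polynomial order 3 and window length 31 days.
Observed LUE is GPP divided by absorbed light, ``gpp / (fapar * par)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.neural_network import MLPRegressor

from .nn import scale_predictors

GAPFILL_MAX_FRAC = 0.5     # drop daily GPP if >= 50% of half-hours gap-filled
LE_GAPFILL_MAX_FRAC = 0.8  # blank daily LE if > 80% of half-hours gap-filled
CONSISTENCY_QUANTILES = (0.025, 0.975)
SG_ORDER = 3
SG_WINDOW = 31


class SiteQCError(RuntimeError):
    """Raised when a site-level cleaning step cannot produce usable data."""


def clean_gpp(series: pd.DataFrame,
              quantile_bounds: tuple[float, float] | None = None
              ) -> pd.DataFrame:
    """Apply the three GPP filters and record a removal reason per day.

    Returns a copy of ``series`` with columns ``gpp`` (night-time GPP where
    kept, NaN otherwise) and ``removal_reason`` in
    {kept, gapfill, nt_dt_inconsistent, negative}.  ``quantile_bounds`` can
    freeze the consistency interval (used to check filter idempotence);
    by default it is estimated from the data retained by the gap-fill filter.
    """
    out = series.copy()
    reason = np.full(len(out), "kept", dtype=object)
    gpp_nt = out["gpp_nt"].to_numpy(dtype=float)
    gpp_dt = out["gpp_dt"].to_numpy(dtype=float)

    gap = out["gpp_qc_frac"].to_numpy(dtype=float) >= GAPFILL_MAX_FRAC
    reason[gap] = "gapfill"

    d = gpp_dt - gpp_nt
    retained = ~gap
    if not retained.any():
        raise SiteQCError("all days removed by GPP filters")
    if quantile_bounds is None:
        lo, hi = np.quantile(d[retained], CONSISTENCY_QUANTILES)
    else:
        lo, hi = quantile_bounds
    if np.isclose(lo, hi):
        # degenerate: the two partitioning methods agree exactly on nearly
        # all days; only true disagreements are inconsistent
        inconsistent = retained & ~np.isclose(d, lo)
    else:
        inconsistent = retained & ((d <= lo) | (d >= hi))
    reason[inconsistent] = "nt_dt_inconsistent"

    negative = retained & ~inconsistent & (gpp_nt < 0.0)
    reason[negative] = "negative"

    out["removal_reason"] = reason
    out["gpp"] = np.where(reason == "kept", gpp_nt, np.nan)
    out.attrs["consistency_bounds"] = (float(lo), float(hi))
    if not np.any(reason == "kept"):
        raise SiteQCError("all days removed by GPP filters")
    return out


def smooth_fapar(samples: pd.DataFrame, dates: pd.DatetimeIndex | None = None
                 ) -> pd.Series:
    """Daily fAPAR from 16-day greenness samples.

    Drops contaminated samples, interpolates the remainder linearly to a
    daily axis and applies the order-3, 31-day Savitzky-Golay filter;
    output is clipped to [0, 1]. ``dates`` extends the output axis beyond
    the sample span (edge-filled) so it aligns with the flux table.
    """
    good = samples[samples["qa_flag"] == "good"]
    if len(good) < 4:
        raise SiteQCError("fewer than 4 uncontaminated greenness samples")
    span = pd.date_range(good.index[0], good.index[-1], freq="D")
    if len(span) < SG_WINDOW:
        raise SiteQCError("greenness record shorter than the smoothing window")
    daily = good["evi"].reindex(span).interpolate(method="time")
    smoothed = savgol_filter(daily.to_numpy(), SG_WINDOW, SG_ORDER)
    fapar = pd.Series(np.clip(smoothed, 0.0, 1.0), index=span, name="fapar")
    if dates is not None:
        fapar = fapar.reindex(dates).ffill().bfill()
    return fapar


def compute_lue_obs(gpp: pd.Series, fapar_daily: pd.Series, par: pd.Series
                    ) -> pd.Series:
    """Observed LUE = GPP / (fAPAR * PAR), missing where absorbed light is 0."""
    absorbed = fapar_daily * par
    lue = gpp / absorbed.where(absorbed > 0)
    return lue.rename("lue_obs")


def build_cleaned_series(series: pd.DataFrame, samples: pd.DataFrame
                         ) -> pd.DataFrame:
    """Run the full cleaning chain on one site table.

    Applies the GPP filters, smooths greenness to daily fAPAR, forms
    observed LUE and tags days whose absorbed light vanished with the
    ``fapar_zero`` removal reason.
    """
    cleaned = clean_gpp(series)
    fapar = smooth_fapar(samples, dates=cleaned.index)
    cleaned["fapar_daily"] = fapar
    lue = compute_lue_obs(cleaned["gpp"], fapar, cleaned["par"])
    zero_light = cleaned["gpp"].notna() & lue.isna()
    cleaned.loc[zero_light, "removal_reason"] = "fapar_zero"
    cleaned.loc[zero_light, "gpp"] = np.nan
    cleaned["lue_obs"] = lue
    return cleaned


def gapfill_le(series: pd.DataFrame, et_splash: np.ndarray,
               min_train_days: int = 100, seed: int = 0) -> pd.Series:
    """Gap-fill the latent heat flux with a small neural network.

    Days on which more than 80% of the half-hourly record was gap-filled are
    blanked first; all missing values are then predicted by a single-hidden-
    layer network (20 nodes, 10-fold cross-validated for a performance
    estimate) trained on the retained days with temperature, PAR, VPD and
    bucket-model ET as predictors.  Returns a gap-free LE series (J m-2 d-1);
    the cross-validated R2 is stored in ``.attrs['cv_r2']``.
    """
    le = series["le"].to_numpy(dtype=float).copy()
    blank = series["le_qc_frac"].to_numpy(dtype=float) > LE_GAPFILL_MAX_FRAC
    le[blank] = np.nan
    missing = ~np.isfinite(le)
    if not missing.any():
        filled = pd.Series(le, index=series.index, name="le_filled")
        filled.attrs["cv_r2"] = np.nan
        filled.attrs["n_filled"] = 0
        return filled
    feats = pd.DataFrame({
        "ta": series["ta"], "par": series["par"], "vpd": series["vpd"],
        "et_splash": np.asarray(et_splash, dtype=float),
    }, index=series.index)
    train = ~missing
    if train.sum() < min_train_days:
        raise SiteQCError(
            f"only {int(train.sum())} days available to train the LE gap-filler")
    X, _ = scale_predictors(feats, train_mask=train)
    Xt, yt = X.to_numpy()[train], le[train]

    def make(rs):
        return MLPRegressor(hidden_layer_sizes=(20,), solver="lbfgs",
                            alpha=0.1, max_iter=400, random_state=rs)

    # 10-fold CV performance estimate, then refit on all retained days
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(yt))
    folds = np.array_split(order, 10)
    pred_cv = np.empty(len(yt))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, fold in enumerate(folds):
            tr = np.setdiff1d(order, fold)
            m = make(seed + k)
            m.fit(Xt[tr], yt[tr])
            pred_cv[fold] = m.predict(Xt[fold])
        ss_res = float(np.sum((yt - pred_cv) ** 2))
        ss_tot = float(np.sum((yt - yt.mean()) ** 2))
        model = make(seed + 100)
        model.fit(Xt, yt)
        le[missing] = model.predict(X.to_numpy()[missing])
    filled = pd.Series(le, index=series.index, name="le_filled")
    filled.attrs["cv_r2"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    filled.attrs["n_filled"] = int(missing.sum())
    return filled


def removal_counts(cleaned: pd.DataFrame) -> pd.Series:
    """Days per removal reason (including 'kept')."""
    return cleaned["removal_reason"].value_counts()
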