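"""Meteorological drought indices and aridity metrics.

SPI fits, per calendar month, a gamma distribution to positive monthly
precipitation totals with a point mass at zero, and maps the cumulative
probability through the standard-normal inverse. SPEI does the same with a
three-parameter log-logistic distribution fitted to the monthly climatic
water balance (precipitation minus Thornthwaite potential
evapotranspiration). Both are 1-month-timescale indices: they standardise
each calendar month against its own climatology, so seasonally recurring
dryness scores near zero by construction — the property the
drought-vs-non-drought contrast exposes.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def monthly_climate(daily: pd.DataFrame, pet_daily=None) -> pd.DataFrame:
    """Aggregate a daily table to monthly precipitation totals and mean
    temperature (plus PET totals when a daily PET series is given)."""
    g = daily.groupby(pd.PeriodIndex(daily.index, freq="M"))
    out = pd.DataFrame({
        "precip_total": g["precip"].sum(),
        "temp_mean": g["ta"].mean(),
    })
    if pet_daily is not None:
        pet = pd.Series(np.asarray(pet_daily, dtype=float), index=daily.index)
        out["pet_total"] = pet.groupby(
            pd.PeriodIndex(daily.index, freq="M")).sum()
    out.index.name = "month"
    return out


def _day_length_hours(latitude: float, doy: np.ndarray) -> np.ndarray:
    """Astronomical day length from solar declination, hours."""
    phi = np.radians(latitude)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(x)


def thornthwaite_pet(monthly_temp: pd.Series, latitude: float) -> pd.Series:
    """Classic Thornthwaite monthly potential evapotranspiration, mm.

    Heat index from the monthly normals, exponent ``a(I)``, day-length and
    month-length correction from latitude; zero for months with mean
    temperature at or below 0 degC, and the hot-month polynomial above
    26.5 degC. Requires all 12 calendar months in the record; latitudes
    poleward of 66.5 deg are rejected (polar day/night undefined here).
    """
    if abs(latitude) > 66.5:
        raise ValueError("day-length correction undefined poleward of 66.5 deg")
    months = monthly_temp.index.month
    if len(np.unique(months)) < 12:
        raise ValueError("all 12 calendar months must be represented")
    t = monthly_temp.to_numpy(dtype=float)
    # heat index from the mean climatology of each calendar month
    clim = monthly_temp.groupby(months).mean()
    tc = np.clip(clim.to_numpy(dtype=float), 0.0, None)
    heat_index = float(np.sum((tc / 5.0) ** 1.514))
    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index + 0.49239)

    pet = np.zeros(len(t))
    for i, (temp, period) in enumerate(zip(t, monthly_temp.index)):
        if temp <= 0:
            continue
        mid_doy = pd.Timestamp(period.year, period.month, 15).dayofyear
        L = _day_length_hours(latitude, np.asarray([float(mid_doy)]))[0]
        n_days = calendar.monthrange(period.year, period.month)[1]
        corr = (L / 12.0) * (n_days / 30.0)
        if temp > 26.5:
            base = -415.85 + 32.24 * temp - 0.43 * temp**2
        else:
            base = 16.0 * (10.0 * temp / heat_index) ** a
        pet[i] = corr * base
    return pd.Series(pet, index=monthly_temp.index, name="pet_thornthwaite")


def _standardize(cdf: np.ndarray) -> np.ndarray:
    eps = 1e-6
    return stats.norm.ppf(np.clip(cdf, eps, 1.0 - eps))


def compute_spi(monthly_precip: pd.Series, min_years: int = 20) -> pd.Series:
    """Standardized Precipitation Index at the 1-month timescale.

    Per calendar month: gamma fit to the positive totals, mixed with the
    empirical zero-precipitation probability; the cumulative probability is
    mapped to standard-normal deviates. Months whose calibration sample is
    all zero (or constant) are left undefined (NaN).
    """
    months = monthly_precip.index.month
    if len(monthly_precip) < 12 * min_years:
        raise ValueError(f"need at least {min_years} years for calibration")
    x = monthly_precip.to_numpy(dtype=float)
    out = np.full(len(x), np.nan)
    for m in range(1, 13):
        sel = months == m
        vals = x[sel]
        pos = vals[vals > 0]
        q_zero = float((vals == 0).sum()) / len(vals)
        if len(pos) < 4 or np.ptp(pos) == 0:
            continue  # degenerate calibration: index undefined for this month
        shape, _, scale = stats.gamma.fit(pos, floc=0.0)
        cdf = q_zero + (1.0 - q_zero) * stats.gamma.cdf(vals, shape, loc=0.0,
                                                        scale=scale)
        cdf[vals == 0] = q_zero / 2.0  # centre of the zero mass
        out[sel] = _standardize(cdf)
    return pd.Series(out, index=monthly_precip.index, name="spi")


def _loglogistic_pwm(vals: np.ndarray) -> tuple[float, float, float] | None:
    """Three-parameter log-logistic fit by probability-weighted moments.

    Returns (shape beta, location gamma, scale alpha) of
    ``F(x) = 1 / (1 + (alpha / (x - gamma))**beta)``, the standard
    plotting-position PWM estimator used for this index family; None when
    the estimator degenerates (shape <= 1 gives an undefined mean).
    """
    x = np.sort(vals)
    n = x.size
    i = np.arange(1, n + 1)
    # unbiased PWMs of (1-F)^s; their weights average to exactly 1/2 and
    # 1/3, which makes the fitted shape and scale shift-invariant
    w0 = float(np.mean(x))
    w1 = float(np.sum(x * (n - i)) / (n * (n - 1.0)))
    w2 = float(np.sum(x * (n - i) * (n - i - 1)) / (n * (n - 1.0) * (n - 2.0)))
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0:
        return None
    beta = (2.0 * w1 - w0) / denom
    if not np.isfinite(beta) or beta <= 1.0:
        return None
    from scipy.special import gamma as gfun
    g = gfun(1.0 + 1.0 / beta) * gfun(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g
    loc = w0 - alpha * g
    if alpha <= 0:
        return None
    return beta, loc, alpha


def compute_spei(balance: pd.Series, min_years: int = 20) -> pd.Series:
    """Standardized Precipitation-Evapotranspiration Index, 1-month timescale.

    Per calendar month, a three-parameter log-logistic distribution is
    fitted to the climatic balance (precipitation minus PET, may be
    negative) by probability-weighted moments and the cumulative
    probability mapped to standard-normal deviates. Months with degenerate
    fits stay undefined.
    """
    months = balance.index.month
    if len(balance) < 12 * min_years:
        raise ValueError(f"need at least {min_years} years for calibration")
    x = balance.to_numpy(dtype=float)
    out = np.full(len(x), np.nan)
    for m in range(1, 13):
        sel = months == m
        vals = x[sel]
        if np.ptp(vals) == 0:
            continue
        fit = _loglogistic_pwm(vals)
        if fit is not None:
            beta, loc, alpha = fit
            z = np.clip(vals - loc, 1e-12, None)
            cdf = 1.0 / (1.0 + (alpha / z) ** beta)
        else:
            # negatively skewed month: fit the reflected sample and take
            # the complementary probability
            fit = _loglogistic_pwm(-vals)
            if fit is None:
                continue
            beta, loc, alpha = fit
            z = np.clip(-vals - loc, 1e-12, None)
            cdf = 1.0 - 1.0 / (1.0 + (alpha / z) ** beta)
        out[sel] = _standardize(cdf)
    return pd.Series(out, index=balance.index, name="spei")


def aridity_metrics(precip: pd.Series, pet: pd.Series, aet: pd.Series
                    ) -> pd.DataFrame:
    """Annual aridity and Budyko coordinates from daily series.

    Per complete calendar year: P/PET (ratio of annual totals), the mean of
    daily AET/PET (days with zero PET skipped), AET/P, and the Budyko
    coordinates (PET/P, AET/P). Site means are stored in ``.attrs``.
    """
    df = pd.DataFrame({"precip": precip, "pet": pet, "aet": aet}).dropna()
    years = df.index.year
    rows = []
    for y in np.unique(years):
        sel = df[years == y]
        if len(sel) < pd.Timestamp(f"{y}-12-31").dayofyear:
            continue
        p, e_pot, e_act = (float(sel[c].sum()) for c in ("precip", "pet", "aet"))
        if e_pot <= 0:
            continue
        daily_ok = sel["pet"] > 0
        rows.append({
            "year": int(y),
            "p_over_pet": p / e_pot,
            "aet_over_pet_daily_mean":
                float((sel.loc[daily_ok, "aet"] / sel.loc[daily_ok, "pet"])
                      .clip(upper=1.0).mean()),
            "aet_over_p": e_act / p if p > 0 else np.nan,
            "pet_over_p": e_pot / p if p > 0 else np.nan,
        })
    out = pd.DataFrame(rows)
    for c in out.columns.drop("year") if len(out) else []:
        out.attrs[f"mean_{c}"] = float(out[c].mean())
    return out


@dataclass
class DroughtContrast:
    summary: pd.DataFrame     # per variable: group medians/quartiles and N
    tests: pd.DataFrame       # per variable: Welch t statistic and p value


def contrast_by_drought(daily_values: pd.DataFrame, drought_mask
                        ) -> DroughtContrast:
    """Compare index distributions inside vs outside fLUE droughts.

    ``daily_values`` holds one column per index at daily resolution (monthly
    indices broadcast to their member days). For each column, group medians
    and quartiles plus an unpaired Welch t-test between drought and
    non-drought days are returned; columns with an empty group are skipped.
    """
    mask = np.asarray(drought_mask, dtype=bool)
    sum_rows, test_rows = [], []
    for col in daily_values.columns:
        x = daily_values[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        a, b = x[ok & mask], x[ok & ~mask]
        if a.size == 0 or b.size == 0:
            continue
        for name, g in (("drought", a), ("no_drought", b)):
            sum_rows.append({
                "variable": col, "group": name, "n": int(g.size),
                "median": float(np.median(g)),
                "q25": float(np.percentile(g, 25)),
                "q75": float(np.percentile(g, 75)),
            })
        t, p = stats.ttest_ind(a, b, equal_var=False)
        pooled_sd = float(np.std(np.concatenate([a, b])))
        sep = abs(np.median(a) - np.median(b)) / pooled_sd if pooled_sd > 0 \
            else np.nan
        test_rows.append({"variable": col, "t": float(t), "p": float(p),
                          "n_drought": int(a.size), "n_no_drought": int(b.size),
                          "median_separation": float(sep)})
    return DroughtContrast(summary=pd.DataFrame(sum_rows),
                           tests=pd.DataFrame(test_rows))


def broadcast_monthly(monthly: pd.Series, dates: pd.DatetimeIndex) -> pd.Series:
    """Map a monthly index onto daily dates by month membership."""
    per = pd.PeriodIndex(dates, freq="M")
    return pd.Series(monthly.reindex(per).to_numpy(), index=dates,
                     name=monthly.name)
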