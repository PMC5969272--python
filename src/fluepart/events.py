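"""fLUE drought events: detection, onset-aligned composites, the
fLUE-soil-moisture stress curve and annual GPP loss accounting.

A drought event is a maximal run of consecutive days on which the ensemble
fLUE stays below a site-specific threshold derived from moist-day fLUE
statistics; runs shorter than a minimum duration are discarded and short
data gaps are bridged before scanning. Events are aligned by onset (day 0)
to form event-by-relative-day composite matrices for any daily variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_EVENT_DURATION = 5
MAX_BRIDGE_DAYS = 3
COMPOSITE_WINDOW = (-20, 79)


def site_flue_threshold(flue: pd.Series, moist_flag, min_moist_days: int = 100
                        ) -> float:
    """Site-specific fLUE drought threshold from moist-day statistics.

    The threshold is ``max(0.97*m - 1.5*s, p5)`` capped from above at
    ``0.97*m``, where ``m`` and ``s`` are the median and robust (MAD-based)
    standard deviation of moist-day fLUE and ``p5`` its 5th percentile.
    It depends on moist days only, is strictly below the moist-day median,
    and is self-calibrating: a noisier fLUE series pushes it further down,
    so noise alone does not trigger events.
    """
    moist_flag = np.asarray(moist_flag, dtype=bool)
    vals = flue.to_numpy(dtype=float)[moist_flag]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_moist_days:
        raise ValueError(
            f"only {vals.size} moist days; need {min_moist_days} for a threshold")
    med = float(np.median(vals))
    robust_sd = float(1.4826 * np.median(np.abs(vals - med)))
    p5 = float(np.percentile(vals, 5))
    return min(0.97 * med, max(0.97 * med - 1.5 * robust_sd, p5))


def _bridge_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap."""
    if max_gap <= 0:
        return x
    s = pd.Series(x)
    return s.interpolate(limit=max_gap, limit_area="inside").to_numpy()


def detect_events(flue: pd.Series, threshold: float,
                  min_duration: int = MIN_EVENT_DURATION,
                  max_gap: int = MAX_BRIDGE_DAYS) -> pd.DataFrame:
    """Maximal below-threshold runs of at least ``min_duration`` days.

    Returns one row per event with ``onset_idx`` (positional), ``onset_date``,
    ``length``, ``min_flue`` and ``cum_deficit`` (sum of 1 - fLUE over the
    event). Events are disjoint and chronological.
    """
    x = _bridge_gaps(flue.to_numpy(dtype=float), max_gap)
    below = np.isfinite(x) & (x < threshold)
    padded = np.concatenate([[False], below, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    rows = []
    for s, e in zip(starts, ends):
        if e - s < min_duration:
            continue
        seg = x[s:e]
        rows.append({
            "onset_idx": int(s),
            "onset_date": flue.index[s],
            "length": int(e - s),
            "min_flue": float(np.nanmin(seg)),
            "cum_deficit": float(np.nansum(1.0 - seg)),
        })
    return pd.DataFrame(rows, columns=["onset_idx", "onset_date", "length",
                                       "min_flue", "cum_deficit"])


def events_with_clean_baseline(events: pd.DataFrame, window: int = 20
                               ) -> pd.DataFrame:
    """Subset of events whose pre-onset window contains no other event day.

    Onset-normalised composites divide by the median over the ``window``
    days before onset; when a drought fragments into several
    threshold-crossing runs, the later onsets sit inside the drought and
    their baseline is not a drought-free reference. Response features are
    built from the clean-baseline events only.
    """
    keep = []
    prev_end = -10**9
    for i, ev in events.iterrows():
        if int(ev["onset_idx"]) - prev_end >= window:
            keep.append(i)
        prev_end = int(ev["onset_idx"] + ev["length"])
    return events.loc[keep]


@dataclass
class CompositeResult:
    """Onset-aligned composites: per-variable event x relative-day matrices
    and their across-event quantile bands."""

    matrices: dict[str, pd.DataFrame]
    bands: dict[str, pd.DataFrame] = field(default_factory=dict)

    def band(self, variable: str) -> pd.DataFrame:
        return self.bands[variable]


def align_and_composite(series_map: dict[str, pd.Series], events: pd.DataFrame,
                        window: tuple[int, int] = COMPOSITE_WINDOW,
                        normalize: set[str] = frozenset(),
                        invert: set[str] = frozenset()) -> CompositeResult:
    """Align daily variables on event onsets and aggregate across events.

    Each variable becomes an event-by-relative-day matrix over
    ``window`` (day 0 = onset). Variables in ``normalize`` are divided by
    their event-specific median over the 20 pre-onset days; variables in
    ``invert`` additionally report the inverse of that relative change
    (useful for VPD, whose relative rise then reads like a soil-moisture
    decline). Rows extending beyond the series are padded with NaN and
    excluded from the day-wise quantiles.

    Bands are the day-wise median and 10/25/75/90% quantiles across events.
    """
    lo, hi = window
    rel_days = np.arange(lo, hi + 1)
    matrices: dict[str, pd.DataFrame] = {}
    bands: dict[str, pd.DataFrame] = {}
    for name, series in series_map.items():
        x = series.to_numpy(dtype=float)
        n = len(x)
        rows = []
        for _, ev in events.iterrows():
            i0 = int(ev["onset_idx"])
            row = np.full(rel_days.size, np.nan)
            src_lo = max(0, i0 + lo)
            src_hi = min(n, i0 + hi + 1)
            row[src_lo - (i0 + lo): src_hi - (i0 + lo)] = x[src_lo:src_hi]
            if name in normalize or name in invert:
                pre = x[max(0, i0 - 20): i0]
                pre = pre[np.isfinite(pre)]
                ref = np.median(pre) if pre.size else np.nan
                row = row / ref if (np.isfinite(ref) and ref != 0) else \
                    np.full_like(row, np.nan)
                if name in invert:
                    row = 1.0 / row
            rows.append(row)
        mat = pd.DataFrame(rows, columns=rel_days)
        mat.index.name = "event"
        mat.columns.name = "rel_day"
        matrices[name] = mat
        bands[name] = pd.DataFrame({
            "median": mat.median(axis=0),
            "q10": mat.quantile(0.10, axis=0),
            "q25": mat.quantile(0.25, axis=0),
            "q75": mat.quantile(0.75, axis=0),
            "q90": mat.quantile(0.90, axis=0),
            "n": mat.notna().sum(axis=0),
        })
    return CompositeResult(matrices=matrices, bands=bands)


@dataclass
class StressCurve:
    """Binned fLUE-vs-soil-moisture relationship with its end members.

    ``flue0`` is the fLUE level as relative soil water approaches zero (the
    maximum soil-moisture-driven LUE reduction) and ``flue1`` the level at
    the saturated end.
    """

    bins: pd.DataFrame
    flue0: float
    flue1: float
    flue0_method: str
    no_dry_days: bool = False


def _flue0_fit(theta: np.ndarray, flue: np.ndarray) -> float:
    """Fallback: theta->0 intercept of a plateau-plus-ramp least-squares fit."""
    best = (np.inf, np.nan)
    for bp in np.arange(0.2, 0.81, 0.05):
        ramp = np.clip(theta / bp, None, 1.0)
        # model: flue = f0 + (1 - f0) * ramp  -> linear in f0
        a = 1.0 - ramp
        b = flue - ramp
        denom = float(np.dot(a, a))
        if denom <= 0:
            continue
        f0 = float(np.dot(a, b) / denom)
        resid = float(np.sum((f0 * a - b) ** 2))
        if resid < best[0]:
            best = (resid, f0)
    return float(np.clip(best[1], 0.0, 1.5))


def estimate_stress_curve(flue: pd.Series, theta_rel,
                          bin_width: float = 0.05,
                          min_dry_days: int = 30) -> StressCurve:
    """Bin pooled (soil moisture, fLUE) pairs and estimate the end members.

    ``flue0`` is the median fLUE over days with relative soil water below
    0.1 when at least ``min_dry_days`` such days exist, otherwise the
    zero-moisture intercept of a piecewise-linear fit (plateau at 1 above a
    free breakpoint). ``flue1`` is the median over days above 0.9. A site
    whose soil water never drops below 0.5 has an undefined ``flue0``
    (flagged ``no_dry_days``).
    """
    theta = np.asarray(theta_rel, dtype=float)
    f = flue.to_numpy(dtype=float)
    ok = np.isfinite(theta) & np.isfinite(f)
    theta, f = theta[ok], f[ok]

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    which = np.clip(np.digitize(theta, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append({
            "theta_lo": edges[b], "theta_hi": edges[b + 1],
            "n": int(sel.sum()),
            "flue_median": float(np.median(f[sel])) if sel.any() else np.nan,
            "flue_q25": float(np.percentile(f[sel], 25)) if sel.any() else np.nan,
            "flue_q75": float(np.percentile(f[sel], 75)) if sel.any() else np.nan,
        })
    bins = pd.DataFrame(rows)

    no_dry = not np.any(theta < 0.5)
    dry = theta < 0.1
    if no_dry:
        flue0, method = np.nan, "undefined"
    elif dry.sum() >= min_dry_days:
        flue0, method = float(np.median(f[dry])), "dry_median"
    else:
        flue0, method = _flue0_fit(theta, f), "piecewise_fit"
    wet = theta > 0.9
    flue1 = float(np.median(f[wet])) if wet.any() else np.nan
    return StressCurve(bins=bins, flue0=flue0, flue1=flue1,
                       flue0_method=method, no_dry_days=no_dry)


def annual_gpp_loss(gpp_pot: pd.Series, flue: pd.Series) -> pd.DataFrame:
    """Fractional annual GPP loss attributable to soil moisture.

    For each complete calendar year, ``1 - sum(flue * gpp_pot) / sum(gpp_pot)``
    where ``gpp_pot = PAR * fAPAR * LUE_pot``; partial years are excluded.
    The across-year mean is stored in ``.attrs['mean_loss']``.
    """
    df = pd.DataFrame({"gpp_pot": gpp_pot, "flue": flue}).dropna()
    years = df.index.year
    rows = []
    for y in np.unique(years):
        sel = df[years == y]
        n_expected = pd.Timestamp(f"{y}-12-31").dayofyear
        if len(sel) < n_expected:
            continue
        tot = float(sel["gpp_pot"].sum())
        if tot <= 0:
            continue
        rows.append({"year": int(y),
                     "loss": 1.0 - float((sel["flue"] * sel["gpp_pot"]).sum()) / tot})
    out = pd.DataFrame(rows, columns=["year", "loss"])
    out.attrs["mean_loss"] = float(out["loss"].mean()) if len(out) else np.nan
    return out


def cumulative_deficit(flue: pd.Series, events: pd.DataFrame) -> pd.DataFrame:
    """Per-year cumulative fLUE deficit, sum of (1 - fLUE) over drought days."""
    deficit = np.zeros(len(flue))
    mask = np.zeros(len(flue), dtype=bool)
    x = flue.to_numpy(dtype=float)
    for _, ev in events.iterrows():
        s, e = int(ev["onset_idx"]), int(ev["onset_idx"] + ev["length"])
        mask[s:e] = True
    deficit[mask] = 1.0 - x[mask]
    per_year = pd.Series(deficit, index=flue.index).groupby(
        flue.index.year).sum()
    per_year.index.name = "year"
    return per_year.rename("cum_deficit").to_frame()
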