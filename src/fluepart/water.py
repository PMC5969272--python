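"""Bucket soil-water-balance models and the Priestley-Taylor PET.

Five single-store models form the soil-moisture ensemble: a Priestley-Taylor
bucket at two water-holding capacities (150 and 220 mm), a net-radiation
driven bucket with pre-capacity runoff (220 mm, runoff exponent alpha = 6.4,
ET down-scaling exponent gamma = 0.06), and two buckets driven directly by
the measured latent heat flux (220 mm), with and without pre-capacity runoff.
Latent heat is converted to water mass at 2.26476e6 J mm-1.

Every model closes its mass balance exactly: over any horizon,
``theta_end - theta_start == sum(P) - sum(AET) - sum(runoff)``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .types import BucketParams

LATENT_HEAT_J_PER_MM = 2.26476e6  # J mm-1
LAMBDA_V_MJ_PER_MM = 2.45         # MJ per mm water (latent heat of vaporization)
GAMMA_PSY_KPA = 0.067             # psychrometric constant, kPa K-1


def svp_slope(ta) -> np.ndarray:
    """Slope of the saturation vapour pressure curve, kPa per degC."""
    ta = np.asarray(ta, dtype=float)
    es = 0.6108 * np.exp(17.27 * ta / (ta + 237.3))
    return 4098.0 * es / (ta + 237.3) ** 2


def priestley_taylor_pet(netrad, ta, params: BucketParams | None = None
                         ) -> np.ndarray:
    """Priestley-Taylor potential evapotranspiration, mm d-1.

    ``pet = pt_alpha * s/(s + gamma_psy) * max(netrad, 0) / lambda_v`` with
    net radiation in MJ m-2 d-1 (negative, night-dominated days clamp to
    zero demand).
    """
    if params is None:
        params = BucketParams()
    netrad = np.asarray(netrad, dtype=float)
    ta = np.asarray(ta, dtype=float)
    if not (np.all(np.isfinite(netrad)) and np.all(np.isfinite(ta))):
        raise ValueError("netrad and ta must be finite")
    s = svp_slope(ta)
    energy = np.clip(netrad, 0.0, None)
    return params.pt_alpha * s / (s + GAMMA_PSY_KPA) * energy / LAMBDA_V_MJ_PER_MM


def _spinup_theta(step, precip, n_spin, theta0):
    """Run the first year once and return the resulting storage."""
    theta = theta0
    for i in range(n_spin):
        theta, _, _ = step(i, theta)
    return theta


def _simulate(step, precip, params: BucketParams, dates=None,
              source: str = "bucket", pet=None, spinup: bool = True
              ) -> pd.DataFrame:
    """Shared daily loop: spin-up, update, mass-balance bookkeeping."""
    n = len(precip)
    theta0 = params.initial_theta if params.initial_theta is not None \
        else 0.5 * params.capacity
    if spinup:
        theta0 = _spinup_theta(step, precip, min(365, n), theta0)
    theta = np.empty(n)
    aet = np.empty(n)
    runoff = np.empty(n)
    state = theta0
    for i in range(n):
        state, aet[i], runoff[i] = step(i, state)
        theta[i] = state
    index = pd.Index(dates, name="date") if dates is not None \
        else pd.RangeIndex(n, name="day")
    out = pd.DataFrame(
        {"theta_mm": theta, "theta_rel": theta / params.capacity,
         "aet": aet, "pet": np.full(n, np.nan) if pet is None else np.asarray(pet, float),
         "runoff": runoff, "precip": np.asarray(precip, float)},
        index=index,
    )
    out.attrs["source"] = source
    out.attrs["capacity"] = params.capacity
    out.attrs["theta_start"] = theta0
    return out


def mass_balance_residual(sm: pd.DataFrame) -> float:
    """theta_end - theta_start - (sum P - sum AET - sum runoff), mm."""
    flux = sm["precip"].sum() - sm["aet"].sum() - sm["runoff"].sum()
    return float(sm["theta_mm"].iloc[-1] - sm.attrs["theta_start"] - flux)


def run_splash(precip, pet, params: BucketParams, dates=None,
               spinup: bool = True) -> pd.DataFrame:
    """Priestley-Taylor bucket with overflow runoff at capacity.

    AET is supply-limited by the linear curve ``pet * theta/capacity``;
    any storage above capacity spills as runoff.
    """
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if len(precip) != len(pet):
        raise ValueError("precip and pet must have equal length")
    cap = params.capacity

    def step(i, theta):
        aet = pet[i] * min(1.0, theta / cap)
        aet = min(aet, theta + precip[i])
        theta_new = theta + precip[i] - aet
        runoff = max(0.0, theta_new - cap)
        return theta_new - runoff, aet, runoff

    name = f"splash{int(params.capacity)}"
    return _simulate(step, precip, params, dates=dates, source=name, pet=pet,
                     spinup=spinup)


def run_swbm(precip, netrad_mm, params: BucketParams | None = None,
             dates=None, spinup: bool = True) -> pd.DataFrame:
    """Net-radiation driven bucket with pre-capacity runoff.

    Runoff is ``P * (theta/capacity)**alpha``; AET is the radiative demand
    (net radiation in water-equivalent mm d-1) down-scaled by the ET
    fraction ``(theta/capacity)**gamma``, a monotone non-decreasing function
    of soil water bounded in [0, 1].
    """
    if params is None:
        params = BucketParams(capacity=220.0, runoff_mode="pre_capacity",
                              alpha=6.4, gamma=0.06)
    precip = np.asarray(precip, dtype=float)
    netrad_mm = np.asarray(netrad_mm, dtype=float)
    if len(precip) != len(netrad_mm):
        raise ValueError("precip and netrad must have equal length")
    cap, alpha, gamma = params.capacity, params.alpha, params.gamma
    demand = np.clip(netrad_mm, 0.0, None)

    def step(i, theta):
        frac = min(1.0, max(0.0, theta / cap))
        runoff = precip[i] * frac ** alpha
        aet = demand[i] * frac ** gamma
        aet = min(aet, theta + precip[i] - runoff)
        theta_new = theta + precip[i] - runoff - aet
        spill = max(0.0, theta_new - cap)
        return theta_new - spill, aet, runoff + spill

    return _simulate(step, precip, params, dates=dates, source="swbm",
                     pet=demand, spinup=spinup)


def run_et_bucket(precip, le, params: BucketParams | None = None,
                  dates=None, spinup: bool = True) -> pd.DataFrame:
    """Bucket driven by the (gap-filled) latent heat flux.

    LE in J m-2 d-1 maps to ET through the 2.26476e6 J mm-1 constant.
    With ``runoff_mode='at_capacity'`` no runoff occurs until the bucket is
    full; with ``'pre_capacity'`` runoff forms as ``P*(theta/capacity)**alpha``
    before the storage update, as in the net-radiation bucket.
    """
    if params is None:
        params = BucketParams(capacity=220.0, runoff_mode="at_capacity")
    precip = np.asarray(precip, dtype=float)
    et = np.clip(np.asarray(le, dtype=float) / LATENT_HEAT_J_PER_MM, 0.0, None)
    if len(precip) != len(et):
        raise ValueError("precip and le must have equal length")
    cap, alpha = params.capacity, params.alpha
    pre = params.runoff_mode == "pre_capacity"

    def step(i, theta):
        if pre:
            frac = min(1.0, max(0.0, theta / cap))
            runoff = precip[i] * frac ** alpha
        else:
            runoff = 0.0
        avail = theta + precip[i] - runoff
        aet = min(et[i], max(avail, 0.0))
        theta_new = avail - aet
        spill = max(0.0, theta_new - cap)
        return theta_new - spill, aet, runoff + spill

    name = "etbucket_runoff" if pre else "etbucket_norunoff"
    return _simulate(step, precip, params, dates=dates, source=name,
                     spinup=spinup)


def le_to_mm(le) -> np.ndarray:
    """Latent heat flux (J m-2 d-1) to water-equivalent mm d-1."""
    return np.asarray(le, dtype=float) / LATENT_HEAT_J_PER_MM


def netrad_to_mm(netrad_mj) -> np.ndarray:
    """Net radiation (MJ m-2 d-1) to water-equivalent mm d-1."""
    return np.asarray(netrad_mj, dtype=float) / LAMBDA_V_MJ_PER_MM


class SoilMoistureEnsemble:
    """Ordered collection of soil-moisture realisations for one site.

    Members keep their identity (``source`` attribute); the pairwise Pearson
    correlation of relative soil water supports the model-consistency site
    gate.
    """

    def __init__(self, members: list[pd.DataFrame]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        index = members[0].index
        for m in members[1:]:
            if not m.index.equals(index):
                raise ValueError("ensemble members must share the date axis")
        self.members = {m.attrs.get("source", f"member{i}"): m
                        for i, m in enumerate(members)}

    @property
    def sources(self) -> list[str]:
        return list(self.members)

    def theta_rel(self) -> pd.DataFrame:
        return pd.DataFrame({k: v["theta_rel"] for k, v in self.members.items()})

    def mean_theta_rel(self) -> pd.Series:
        return self.theta_rel().mean(axis=1)

    def consistency(self) -> pd.DataFrame:
        """Pairwise Pearson correlation matrix of relative soil water."""
        return self.theta_rel().corr(method="pearson")

    def is_consistent(self, min_r: float = 0.7) -> bool:
        c = self.consistency().to_numpy()
        off = [c[i, j] for i, j in
               itertools.combinations(range(c.shape[0]), 2)]
        return bool(np.all(np.asarray(off) > min_r)) if off else True


def build_ensemble(series_list: list[pd.DataFrame],
                   observed: pd.DataFrame | None = None) -> SoilMoistureEnsemble:
    """Assemble an ensemble from model runs plus optional observations.

    ``observed`` is a date-indexed table of relative soil water (one column
    per measurement depth); it joins the ensemble as a single member whose
    ``theta_rel`` is the across-depth mean, while the per-depth columns are
    retained for use as individual predictors.
    """
    members = list(series_list)
    if observed is not None:
        obs = pd.DataFrame({"theta_rel": observed.mean(axis=1)})
        obs["theta_mm"] = np.nan
        obs["aet"] = np.nan
        obs["pet"] = np.nan
        obs["runoff"] = np.nan
        obs["precip"] = np.nan
        obs.attrs["source"] = "observed"
        obs.attrs["depth_columns"] = list(observed.columns)
        for c in observed.columns:
            obs[f"depth_{c}"] = observed[c]
        members.append(obs)
    return SoilMoistureEnsemble(members)
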