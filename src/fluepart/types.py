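"""Configuration and parameter containers shared across the pipeline.

Daily series are plain :class:`pandas.DataFrame` objects indexed by calendar
date; the dataclasses here hold the scalar knobs: the synthetic-site
generator configuration, the ground-truth stress parameters used for
recovery tests, bucket-model parameters and the neural-network training
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic flux-site weather and observation generator.

    Units: temperatures in degC, shortwave radiation in MJ m-2 d-1,
    precipitation in mm d-1, VPD in Pa, PAR conversion in mol MJ-1.
    ``dry_spell_blocks`` lists (start_day, length) windows in which the
    wet-day probability is replaced by ``dry_spell_wet_prob`` (0 forces a
    rain-free window), emulating seasonal dry periods.
    """

    n_days: int = 2192
    seed: int = 42
    latitude: float = 40.0
    temp_mean: float = 12.0
    temp_amplitude: float = 9.0
    precip_wet_prob: float = 0.35
    precip_mean_depth: float = 6.0
    dry_spell_blocks: tuple[tuple[int, int], ...] = ()
    dry_spell_wet_prob: float = 0.0
    sw_mean: float = 14.0
    sw_amplitude: float = 9.0
    # VPD = vpd_base + c_temp * (T - temp_mean) + c_dry * dryness + noise,
    # with dryness in [0, 1] from antecedent precipitation
    vpd_base: float = 500.0
    vpd_coupling: tuple[float, float] = (60.0, 900.0)
    vpd_noise_sd: float = 60.0
    vpd_lognorm_sd: float = 0.45
    vpd_intrusion_prob: float = 0.06
    vpd_spike_prob: float = 0.05
    par_conversion: float = 2.04
    # netrad follows sw_in by a fixed affine rule (recorded here)
    netrad_slope: float = 0.75
    netrad_intercept: float = -1.0
    noise_sd_gpp: float = 1.0
    noise_sd_evi: float = 0.02
    gapfill_frac_prob: float = 0.05
    le_gapfill_frac_prob: float = 0.05
    negative_gpp_prob: float = 0.004
    nt_dt_outlier_prob: float = 0.004
    evi_contaminated_prob: float = 0.10

    def __post_init__(self) -> None:
        if self.n_days < 365:
            raise ValueError("n_days must be >= 365 (seasonal cycle undefined)")
        for name in ("precip_wet_prob", "dry_spell_wet_prob", "gapfill_frac_prob",
                     "le_gapfill_frac_prob", "negative_gpp_prob",
                     "nt_dt_outlier_prob", "evi_contaminated_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("temp_amplitude", "sw_amplitude", "precip_mean_depth",
                     "noise_sd_gpp", "noise_sd_evi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of the generative LUE model.

    The daily true light use efficiency is
    ``lue_max * g(T) * exp(-vpd_k * VPD) * beta(theta_rel)`` with ``g`` a
    Gaussian temperature response around ``temp_opt`` and ``beta`` the
    piecewise-linear soil-moisture stress: 1 above ``theta_crit`` and
    linearly declining to ``flue0`` at zero relative soil water.
    """

    flue0: float = 0.5
    theta_crit: float = 0.5
    lue_max: float = 0.9
    temp_opt: float = 20.0
    temp_width: float = 14.0
    vpd_k: float = 3.0e-4
    deciduous: bool = False
    greenness_sensitivity: float = 0.6
    greenness_lag: float = 10.0
    fapar_base: float = 0.35
    fapar_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.flue0 <= 1.0:
            raise ValueError("flue0 must be in (0, 1]")
        if not 0.0 < self.theta_crit < 1.0:
            raise ValueError("theta_crit must be in (0, 1)")
        if self.lue_max <= 0:
            raise ValueError("lue_max must be > 0")

    def with_(self, **kw) -> "TruthParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class BucketParams:
    """Parameters of a single-store soil water balance model.

    ``runoff_mode='at_capacity'`` only spills the overflow above the
    water-holding capacity; ``'pre_capacity'`` generates runoff before the
    bucket is full as ``P * (theta/capacity)**alpha``. ``gamma`` is the
    exponent down-scaling the ET fraction of net radiation with soil water
    content, and ``pt_alpha`` the Priestley-Taylor coefficient.
    """

    capacity: float = 220.0
    runoff_mode: str = "at_capacity"
    alpha: float = 6.4
    gamma: float = 0.06
    pt_alpha: float = 1.26
    initial_theta: float | None = None

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("capacity must be > 0")
        if self.runoff_mode not in ("at_capacity", "pre_capacity"):
            raise ValueError(f"unknown runoff_mode {self.runoff_mode!r}")
        if self.runoff_mode == "pre_capacity" and self.alpha <= 0:
            raise ValueError("alpha must be > 0 for pre-capacity runoff")
        if self.initial_theta is not None and not (
                0.0 <= self.initial_theta <= self.capacity):
            raise ValueError("initial_theta must be in [0, capacity]")

    def with_(self, **kw) -> "BucketParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class NNHyper:
    """Training protocol of the single-hidden-layer LUE networks.

    The reference protocol selects the hidden-layer size by repeated
    k-fold cross-validation over a node grid at fixed weight decay,
    refits on all data, and repeats the whole procedure ``outer_repeats``
    times, averaging the repeat predictions.
    """

    n_folds: int = 5
    cv_repeats: int = 5
    train_fraction: float = 0.75
    hidden_nodes_grid: tuple[int, ...] = (4, 6, 8, 10, 12, 14, 16, 18, 20)
    decay: float = 0.1
    outer_repeats: int = 5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_nodes_grid) == 0:
            raise ValueError("hidden_nodes_grid must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def with_(self, **kw) -> "NNHyper":
        return replace(self, **kw)


#: Reduced protocol for desk-scale runs: a coarser node grid, single CV
#: repeat and two outer repeats. Used by the example scripts and tests.
FAST_HYPER = NNHyper(n_folds=5, cv_repeats=1, hidden_nodes_grid=(8, 12, 16),
                     outer_repeats=2, max_iter=300)

#: Protocol for the moist/dry threshold search: a single node count and no
#: CV, but six averaged repeats — candidate scores are small differences,
#: so prediction averaging matters more than model selection there.
SEARCH_HYPER = NNHyper(n_folds=5, cv_repeats=1, hidden_nodes_grid=(12,),
                       outer_repeats=6, max_iter=300)
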