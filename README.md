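# fluepart

Partitioning soil-moisture effects on ecosystem light use efficiency from
daily eddy-covariance-style data.

## The problem

Gross primary productivity (GPP) of an ecosystem can be written as

```
GPP = PAR × fAPAR × LUE
```

with PAR the incident photosynthetically active radiation, fAPAR the
fraction of it absorbed by the canopy (proxied by a greenness index such as
EVI), and LUE the light use efficiency. Satellite GPP products typically
let vapour pressure deficit (VPD) and greenness carry all the dryness
information. But stomata also close in response to dry *soil*, and the two
effects are only partly correlated. This package quantifies the separate
soil-moisture effect as

```
fLUE = LUE_act / LUE_pot
```

where both terms come from paired single-hidden-layer neural networks
trained per site on observed LUE (`LUE_obs = GPP / (fAPAR × PAR)`):

* **potential LUE** — predictors temperature, VPD and PAR, trained only on
  days with relatively high soil moisture ("moist days"), so it predicts
  the LUE a day *would* have had without soil-moisture limitation;
* **actual LUE** — the same predictors plus soil moisture, trained on all
  days;
* a **VPD-only control** — trained on all days without soil moisture, used
  to show that VPD alone cannot carry the dryness signal.

The moist/dry split threshold is optimised per site and per soil-moisture
realisation; soil moisture itself comes from an ensemble of single-bucket
water-balance models (a Priestley–Taylor bucket at 150 and 220 mm
water-holding capacity, a net-radiation-driven bucket with pre-capacity
runoff, and two buckets driven by the measured latent heat flux).

Downstream, fLUE supports: detection of *fLUE droughts* (runs of days below
a site-specific threshold), onset-aligned composites of soil moisture, VPD,
greenness and fLUE; the fLUE-vs-soil-moisture stress curve and its
zero-moisture intercept fLUE₀; annual GPP loss attributable to soil
moisture; classification of sites into four drought-response types (cNA not
affected, cLS low sensitivity, cDD drought-deciduous, cGR evergreen); and a
contrast of fLUE droughts with anomaly-based drought indices (1-month SPI
and SPEI, Thornthwaite PET, AET/PET, Budyko coordinates).

Because the method is defined by recovery of a known signal, the package
ships a first-class synthetic flux-site generator
(`fluepart.synthetic`) whose ground truth — a piecewise-linear stress
factor β(θ) with known depth fLUE₀ and critical soil moisture — makes every
stage testable end to end without any external data.

## Who it is for

Ecosystem ecologists and land-surface modellers who want to (a) apply the
paired-network fLUE partitioning to daily flux-tower-style tables, or
(b) study the estimator itself — its identifiability, biases and failure
modes — under controlled synthetic conditions.

## Worked example

`examples/03_estimate_flue.py` generates a six-year site with a recurring
four-month dry season and a stress function of depth fLUE₀ = 0.4 below a
critical relative soil water of 0.5, runs the full pipeline with a
two-member soil-moisture ensemble, and prints:

```
moist/dry threshold per soil-moisture source: {'splash150': 0.45, 'splash220': 0.35}
fLUE vs true stress factor: RMSE = 0.050
median fLUE on moist days: 1.003  (1.0 = no spurious stress)
estimated fLUE0 = 0.45   (generated with fLUE0 = 0.4)
site performance gate passed: True
  rmse_act: 0.121
  rmse_pot: 0.150
  r2_act: 0.602
  r2_pot: 0.381
  drought_gap: 0.247
  n_days: 1931.000
```

The recovered split threshold (0.45 against a true 0.5 on the driving
bucket's scale), the fLUE series tracking the true stress factor with RMSE
0.05, a moist-day median of 1.003 (no spurious stress where none was
generated) and an fLUE₀ estimate of 0.45 show the partitioning working;
the gate lines are the site-retention diagnostics (prediction RMSE in
g C mol⁻¹ and R² against observed LUE).

`examples/04_drought_events_and_losses.py` continues to event detection and
loss accounting — on the same site it finds the seasonal drought events and
an average annual GPP loss of 28% due to soil moisture alone — and
`examples/05_classify_sites.py` classifies a twelve-site synthetic cohort
into the four response types with 100% accuracy. The other examples cover
the generator, the water-balance ensemble and the drought-index contrast.

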