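"""Generate one synthetic flux site with a known soil-moisture stress.

Builds six years of daily weather with a recurring ~4-month dry season,
produces GPP as PAR x fAPAR x LUE with a piecewise-linear stress on LUE
(fLUE0 = 0.5 below a critical relative soil water of 0.5), degrades the
observations the way real flux and satellite data are degraded, and writes
the tables in a FLUXNET-style CSV dialect.
"""

import fluepart as fp

config = fp.SyntheticConfig(
    n_days=2192, seed=42,
    dry_spell_blocks=fp.synthetic.yearly_dry_season(7))
truth = fp.TruthParams(flue0=0.5, theta_crit=0.5)

site = fp.synthetic.generate_site(config, truth)
series = site["series"]

fp.io.write_site_table(series, "site_daily.csv")
fp.io.write_evi_table(site["evi_samples"], "site_evi.csv")
fp.io.write_truth_sidecar(truth, config, "site_truth.yaml")

print(f"days: {len(series)}  ({series.index[0].date()} .. {series.index[-1].date()})")
print(f"annual precipitation: {series['precip'].sum() / 6:.0f} mm yr-1")
print(f"GPP mean / max: {series['gpp_nt'].mean():.1f} / {series['gpp_nt'].max():.1f} g C m-2 d-1")
print(f"true relative soil water range: {site['theta_rel_truth'].min():.2f} .. "
      f"{site['theta_rel_truth'].max():.2f}")
print(f"days with beta < 1 (soil-moisture-stressed): {(site['beta_truth'] < 1).sum()}")
print("wrote site_daily.csv, site_evi.csv, site_truth.yaml")
# The stressed-day count shows how much of the record carries the signal the
# downstream neural networks must separate from VPD and greenness effects.
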