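# All-in-one pipeline: simulate a confounded cohort, estimate the effect of
# +1 treatment-year with every method, bootstrap intervals, plot.
seed: 1
simulate:
  n_patients: 1000
  treatment_effect_per_year: -1.5
outcomes: [updrs3_off]
horizons: [2]
methods: [naive, baseline_adjusted, baseline_adjusted_mw, iptw_msm, gformula]
bootstrap:
  repeats: 100
outdir: pdstart_out
plot: true
log_level: INFO
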