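# Progressive-only pathway: every lesion progresses to clinical cancer.
# Stage order: LGD, IGD, HGD, preclinical cancer I, II, III/IV.
pathway_name: progressive_only
progressive_stage_means: [3.33, 3.33, 3.33, 2.0, 2.0, 1.0]
indolent_stage_means: null
indolent_fraction: 0.0
clinical_dx_prob: [0.051, 0.131, 1.0]
five_year_survival: [0.291, 0.114, 0.0]
lifetime_risk_target: 0.075
cases_per_10k_target: 921
deaths_per_10k_target: 751
# Onset hazard H(a) = onset_scale * (a / onset_ref_age) ** onset_shape.
# onset_scale is the calibration product (no-screening case burden);
# onset_shape pins how steeply onset rises with age (see docs/methods.md).
# shape anchored to the unscreened deaths/cases ratio; scale calibrated to
# the no-screening case burden at n=10^6 (seed 20250927).
onset_shape: 5.0
onset_scale: 0.31357421875
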