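# Indolent-included pathway: fast progressive lesions coexist with indolent
# lesions that at most reach preclinical cancer stage I and are never lethal.
pathway_name: indolent_included
progressive_stage_means: [1.11, 1.11, 1.11, 0.66, 0.66, 0.33]
indolent_stage_means: [7.08, 11.78, 24.15]   # LGD, IGD, HGD; preclinical I is absorbing
# indolent share calibrated against the annual-screening mortality reduction
# (see docs/methods.md); unscreened burden identifies only the progressive rate.
indolent_fraction: 0.48
clinical_dx_prob: [0.051, 0.131, 1.0]
five_year_survival: [0.291, 0.114, 0.0]
lifetime_risk_target: 0.075
cases_per_10k_target: 918
deaths_per_10k_target: 753
onset_shape: 5.0
onset_scale: 0.4150390625
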