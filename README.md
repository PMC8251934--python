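# pancsim

Microsimulation of pancreatic-cancer screening in high-risk individuals.

Pancreatic cancer is usually found late and is then almost uniformly fatal,
so surveillance of high-risk groups (familial pancreatic cancer kindreds,
carriers of *BRCA2*/*CDKN2A*/*LKB1* variants) with EUS/MRI imaging is an
active question — but trials large and long enough to measure a mortality
effect do not exist. `pancsim` addresses that gap the way screening
evaluation is usually done in silico: it simulates individual life
histories with a multistate natural-history model of the disease, overlays
a screening-and-surveillance program on the *same* histories, and reads the
effect of screening off the paired difference.

The package is for epidemiologists and modelers who want to reproduce,
probe or extend this class of analysis: every parameter (dwell times,
detection probabilities, test characteristics, management probabilities,
life table) is an explicit, swappable input.

## Model in brief

A person's disease course is a forward walk through ordered states

```
LGD → IGD → HGD → preclinical I → preclinical II → preclinical III/IV → clinical
```

with exponential stage dwell times d_s = −mean_s·ln(1−v) sharing one
quantile v per lesion (perfect rank correlation across stages), Weibull
lesion-onset hazard H(a) = s·(a/80)^k, stage-specific clinical-detection
probabilities (5.1%/13.1%/100%) and five-year relative survival after
diagnosis (29.1%/11.4%/0%) applied as a cure fraction plus a uniform death
time on (0, 5] years, competing with an other-cause death age drawn from a
life table. Two natural-history hypotheses ship as presets:
**progressive-only** (every lesion eventually becomes clinical cancer, mean
preclinical duration ≈ 14 years) and **indolent-included** (48% of lesions
never pass preclinical stage I and are never lethal; progressive lesions
move fast, ≈ 5 years). Screening at ages 50–75 applies a stage-specific
test (sensitivity 60–99%, specificity 90%), resection with 3% surgical
mortality, and 6-monthly surveillance after unresected positives. Screening
effectiveness is summarized as mortality reduction, NNS/NNSurv/NNT
(screening tests / surveillance tests / resections per cancer death
prevented), life-years gained and interval-cancer rates. Both arms of every
scenario consume identical natural-history random numbers (common random
numbers), so small between-arm differences are estimated with low variance.

See `docs/methods.md` for the full model description, calibration strategy
and known limitations.

## Worked example

Run the progressive-only base case, annual screening, 200,000 persons:

```sh
pancsim run --pathway progressive_only --policy annual --n 200000 --seed 11
```

Key lines of the JSON it prints (values per 10,000 simulated persons unless
stated):

```
"deaths_per_10k_unscreened": 759.4,
"deaths_per_10k_screened":   316.3,
"mortality_rate_unscreened": 110.3,     # per 100,000 life-years
"mortality_rate_screened":    45.7,
"mortality_reduction_pct":    58.6,
"screen_tests_per_10k":   185589.5,
"surveillance_tests_per_10k": 20292.7,
"lyg_per_10k":              3995.8,
"nns": 418.8,  "nnsurv": 45.8,  "nnt": 2.9
```

Read: without screening ≈759 of 10,000 high-risk persons die of pancreatic
cancer; annual EUS/MRI screening at 50–75 averts ≈443 of those deaths (a
≈59% mortality reduction), at the price of ≈18.6 screening tests and ≈2
surveillance tests per person ever screened — ≈419 screening tests, ≈46
surveillance tests and ≈2.9 resections per cancer death prevented, gaining
≈4,000 life-years per 10,000 persons.

Other entry points:

```sh
pancsim calibrate --pathway progressive_only --n 200000 --seed 3   # onset-scale calibration + fresh-seed check
pancsim run --pathway indolent_included --policy 5yearly --n 1000000 --seed 1
pancsim grid --n 200000 --seed 1 --out-dir grid_out                # full sensitivity grid (risk, sensitivity, specificity, surgical mortality)
pancsim report --in grid_out/sensitivity_grid.csv --out summary.csv
```

or from Python:

```python
from pancsim import (load_preset, annual_policy, TestCharacteristics,
                     ManagementPolicy, run_paired_scenario)

res = run_paired_scenario(load_preset("progressive_only"), annual_policy(),
                          TestCharacteristics(), ManagementPolicy(),
                          n_persons=1_000_000, seed=1)
print(res.table.to_dict()["nns"])
```

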