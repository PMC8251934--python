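# Methods

`pancsim` is an individual-level (microsimulation) model of pancreatic-cancer
natural history in high-risk individuals, with an imaging-based screening and
surveillance program overlaid on each simulated life. This note documents the
model, its parameters and defaults, the calibration strategy, the numerical
choices, and the known limitations.

## 1. Model structure

### Life histories

Each simulated person receives

1. an **other-cause death age** drawn from a life table (inverse-CDF sampling
   with linear interpolation inside year-of-age bins, so death ages are
   continuous);
2. possibly a **pancreatic lesion**, whose onset age follows a Weibull
   cumulative hazard `H(a) = s · (a/80)^k` (see calibration);
3. a **lesion fate**: *progressive* or, in the indolent-included pathway,
   *indolent* with probability `indolent_fraction`.

A progressive lesion traverses six stages — low-, intermediate-, high-grade
dysplasia (LGD, IGD, HGD), then preclinical invasive cancer TNM stages I, II
and III/IV. Stage dwell times are exponential with the stage means of the
chosen pathway (progressive-only: 3.33/3.33/3.33/2/2/1 years;
indolent-included progressive lesions: 1.11/1.11/1.11/0.66/0.66/0.33 years).
All six durations of one lesion share a single uniform quantile mapped
through each stage's inverse CDF (`d_s = −mean_s · ln(1−v)`), i.e. perfect
rank correlation: a lesion fast in one stage is fast in all. A correlation
below 1 is not currently exposed; perfect correlation is the strongest
reading of "fast in one stage, fast in the next" and a single shared
quantile keeps the draw protocol reproducible.

An indolent lesion uses its own dwell means (7.08/11.78/24.15 years for
LGD/IGD/HGD), progresses at most to preclinical stage I, stays there until
death from other causes, is never clinically diagnosed and never lethal.

During each preclinical cancer stage a progressive lesion may surface
clinically with probability 5.1% (I), 13.1% (II) or 100% (III/IV); given
detection, the diagnosis instant is uniform over that stage's dwell. After
clinical diagnosis the person is cured with the stage-specific five-year
survival (29.1% / 11.4% / 0%); otherwise cancer death occurs uniformly
within (0, 5] years of diagnosis ("linear" five-year mortality), competing
with other-cause death. Five-year survivors never die of the disease.
Disease events scheduled after the other-cause death age simply never
happen.

### Screening and management

Screening (combined EUS/MRI, one test) is offered from age 50 to 75 at a
1- or 5-year interval with full adherence. Test sensitivity by true stage is
60/60/75/90/93/99% (LGD → preclinical III/IV); specificity is 90%. A
positive test triggers management:

* **preclinical stage III/IV** — palliative care: the person becomes a
  screen-detected case with the stage III/IV survival law (no resection);
* otherwise **resection** with probability 0.9 per positive test (all
  resectable stages, configurable), with 3% surgical mortality. Resected
  preinvasive lesions are cured; the person returns to routine screening and
  remains at risk of a *new* lesion (re-onset uses the same hazard
  conditioned on current age). Resected preclinical stage I/II cancers are
  screen-detected cases that keep the *clinically observed* stage-specific
  survival — including indolent stage-I lesions, which is how overtreatment
  can kill;
* otherwise **surveillance**: the same test every 6 months, with routine
  screens suppressed, until resection, clinical diagnosis or death; a
  false-positive episode (no lesion) ends after
  `false_positive_surveillance_rounds` (default 1) consecutive negative
  surveillance tests.

### Paired design and randomness

Each scenario simulates the *same* persons with and without screening.
Natural-history draws (12 uniforms per person, in a documented column
order) come from a seeded numpy PCG64 generator and are shared by both
arms. Screening decisions draw from an independent per-person SplitMix64
counter stream, so a person untouched by screening is bit-identical across
arms; differences between arms estimate the policy effect with strongly
reduced variance. Screen-detected invasive cancers reuse the person's
natural-history survival uniforms, so a person who would have been cured
after clinical diagnosis is also cured after an (equal-stage) screen
detection.

The production engine is a numba-compiled loop over per-person arrays. An
independently written, plain-Python per-person walk implements the same
event order and draw protocol; the test suite enforces their *exact*
(bit-for-bit) agreement on 10^4 simulated persons, which guards both
implementations.

## 2. Calibration

Three quantities are not pinned down by the benchmark tabulations this package reproduces, and must be fixed:

* **Onset-hazard scale `s`** — calibrated by monotone bisection, with common
  random numbers across iterates, to the no-screening clinical-case burden
  (921 cases per 10,000 simulated persons for the progressive-only pathway,
  918 for indolent-included). The empirical case count is non-decreasing in
  `s` person-by-person, so bisection is exact up to Monte-Carlo resolution.
  Calibration uses ≥2·10^5 persons; a fresh-seed verification is reported.

  The nominal lifetime-risk headline of 7.5% is *not* the calibration
  objective: the benchmark no-screening burden (921/918 cases and 751/753
  cancer deaths per 10,000) corresponds to a realized lifetime clinical
  risk of ≈9.2%, and deaths can never exceed cases, so the nominal 7.5%
  and the benchmark burden cannot hold together under any parameterization.
  Every downstream effectiveness measure (mortality rates, NNS, NNSurv,
  NNT, the sensitivity grid) is consistent only with the realized burden,
  so the package calibrates to it and reports the realized risk honestly.
  `calibrate_onset_scale(..., objective="lifetime_risk")` is available for
  anyone who wants the nominal target instead. Halved/doubled-risk
  scenarios recalibrate `s` to the proportionally scaled burden.

* **Onset-hazard shape `k`** (default 5.0) — fixed once, during model
  development, so that the unscreened deaths/cases ratio matches the
  benchmark 751/921 ≈ 0.815. The ratio is governed by how old people are at
  clinical diagnosis (older diagnoses are more often pre-empted by
  other-cause death within the five-year window), so it pins the slope of
  the onset hazard; shapes 2–6 give ratios 0.90–0.80. The resulting
  age-specific preinvasive prevalence rises steeply from midlife, as
  expected for pancreatic precursor lesions in high-risk cohorts.

* **Indolent fraction** (default 0.48) — not identified by any unscreened
  quantity: indolent lesions are never clinically diagnosed and never
  lethal, so the unscreened burden constrains only the progressive-lesion
  onset rate. The share is identified by screened-arm outcomes instead; it
  was calibrated once against the benchmark annual-screening mortality-rate
  reduction of 41% (jointly with `s` at each candidate fraction) and ships
  as a preset constant. The annual-screening NNS (≈600) then emerges
  without having been targeted. `calibrate_indolent_fraction` re-runs this
  joint search for any reduction anchor.

* **Life table** — a Gompertz–Makeham survival curve (background hazard
  5·10⁻⁴, Gompertz level and slope fitted) anchored to the two quantities
  the benchmark tabulations imply: probability 0.925 of surviving to the
  screening start age of 50 (10,000 simulated ≈ 9,250 screened) and 69.7
  person-years lived per person (921 cases at an incidence of 132 per
  100,000 life-years). Users can substitute any table as a two-column CSV.

## 3. Outcome definitions

Cancer cases = clinical diagnoses + screen-detected invasive cancers
(stages I–III/IV); resected preinvasive lesions are not cases. Cancer
deaths include surgical deaths (screening-induced harm must count against
screening); incidence does not. Rates divide by person-years from birth to
death in the respective arm. NNS/NNSurv/NNT divide screening tests,
surveillance tests and total resections (including stage-III/IV
screen-detected managements) by the paired between-arm difference in cancer
deaths. Life-years gained is the per-person sum of death-age differences
(surgical deaths contribute negatively). Interval cancers are clinical
diagnoses whose most recent screening test was negative; their rate is per
100,000 person-years lived after the first negative screen (the benchmark
denominator is not reconstructible: a rate on whole-cohort person-years
would exceed the total number of clinical diagnoses under annual
screening).

## 4. Numerical choices

* Death ages, onset ages and all event times are continuous float64; ties
  between a diagnosis and a same-instant test resolve in favor of the
  diagnosis only when strictly earlier (measure-zero either way).
* Bisection stops when the bracketed case counts are within the relative
  tolerance (default 2%) *and* the scale bracket is below 0.1% relative;
  a stalled or non-bracketing search raises with the achieved range.
* Degenerate inputs are handled explicitly: onset scale 0 means no lesions
  ever; `sample_pc_survival` returns "cured" rather than a death time;
  empty screening schedules and policies starting after the oldest death
  leave histories untouched.
* Default cohort sizes: 10^6 persons for scenario runs (the study scale),
  2·10^5 for calibration; both complete in seconds on one CPU because the
  natural history is vectorized and the screening walk is compiled.

## 5. What the simulated data do and do not show

The generator *is* the study design: it emulates a high-risk birth cohort
with the stated natural-history, test and management parameters. It does
not emulate: real registry life tables (parametric stand-in), lesion
multifocality, PanIN-vs-IPMN distinctions, tumor size, stage
misclassification at detection, systematic false negatives, imperfect
adherence, screening-related morbidity or quality-of-life loss, or costs.
Passing tests therefore demonstrate internal reproduction of the modeled
design, not external validity for any clinical population.

## 6. Known limitations and residual discrepancies

* **Nominal 7.5% lifetime risk** — see §2; the realized risk of the
  calibrated cohorts is ≈9.2% and is reported as such.
* **Resection stage mix**: with a uniform 0.9 referral probability the
  model resects most lesions at LGD, whereas the benchmark mix peaks at
  IGD with fewer LGD resections — the underlying stage-specific referral
  probabilities were never released. Totals,
  deaths, NNS/NNSurv/NNT and life-years gained reproduce nevertheless.
* **Surveillance volume at perfect specificity**: the benchmark ~5
  surveillance tests per death prevented at specificity 1.0 implies long
  surveillance episodes for truly diseased persons. Reproducing that
  volume requires delaying resection behind surveillance, which (we
  verified) destroys the benchmark effectiveness profile (mortality
  reduction would fall from ~58% to ~50%); no flow consistent with the
  stated design reproduces both. The shipped flow resects at the positive
  test, reproducing effectiveness, the base-case surveillance volume
  (≈20,200 tests per 10,000 vs the benchmark 20,182) and the specificity
  0.85/0.95 surveillance burdens, but yields ≈0.5 rather than 5
  surveillance tests per death prevented in the perfect-specificity corner.
* **Indolent pathway, 5-yearly screening** is less effective here (≈10%
  mortality reduction) than the benchmark (≈18%): the 4.8-year progressive
  preclinical window straddles 5-year intervals differently depending on
  the unreleased referral schedule. Annual-screening outcomes, which the
  sensitivity analyses build on, reproduce.
* One lesion at a time per person; a new lesion can only arise after
  curative resection of the previous one.
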