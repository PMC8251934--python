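"""Unscreened pancreatic-cancer disease courses under two pathway hypotheses.

Model
-----
Each person may develop at most one preinvasive lesion at a time.  A lesion
is either *progressive* (it walks LGD -> IGD -> HGD -> preclinical cancer
stage I -> II -> III/IV and, unless death intervenes, is eventually
diagnosed clinically) or *indolent* (it progresses at most to preclinical
stage I, where it remains until death from other causes; it is never
diagnosed clinically and never lethal).

Stage dwell times are exponential with stage-specific means.  Within one
lesion all stage durations share a single uniform quantile ``v`` mapped
through each stage's inverse CDF, i.e. ``d_s = -mean_s * ln(1 - v)``: a
lesion that is fast in one stage is fast in every stage (perfect rank
correlation, the strongest reading of correlated sojourns).

During each preclinical cancer stage the person may be clinically diagnosed
with the stage-specific probability (5.1% / 13.1% / 100%); given diagnosis,
the diagnosis time is uniform over that stage's dwell.  After clinical
diagnosis, the person is cured with the stage-specific five-year survival
probability (29.1% / 11.4% / 0%); otherwise pancreatic-cancer death occurs
at a time uniform on (0, 5] years after diagnosis, competing with
other-cause death.  Survivors of the first five years never die of the
disease.

Lesion onset follows a Weibull cumulative hazard
``H(a) = scale * (a / ref_age)**shape``; the scale is a calibration product
(see :mod:`pancsim.calibration`), the shape fixes how steeply onset risk
rises with age.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .demography import LifeTable, sample_death_age

INF = float("inf")

# Number of natural-history uniforms consumed per person, in draw order:
# u_death, u_onset, u_fate, v_stage, (u_det, w_det) x {I, II, III/IV},
# u_surv, t_surv.
N_DRAWS = 12
COL_DEATH, COL_ONSET, COL_FATE, COL_V = 0, 1, 2, 3
COL_DET_U = (4, 6, 8)
COL_DET_W = (5, 7, 9)
COL_SURV_U, COL_SURV_T = 10, 11


class Stage(enum.IntEnum):
    """Ordered disease states; progression only ever moves forward."""

    NONE = 0
    LGD = 1
    IGD = 2
    HGD = 3
    PRECLIN_I = 4
    PRECLIN_II = 5
    PRECLIN_III_IV = 6
    CLINICAL_I = 7
    CLINICAL_II = 8
    CLINICAL_III_IV = 9
    PC_DEATH = 10


PREINVASIVE = (Stage.LGD, Stage.IGD, Stage.HGD)
PRECLINICAL = (Stage.PRECLIN_I, Stage.PRECLIN_II, Stage.PRECLIN_III_IV)
CLINICAL = (Stage.CLINICAL_I, Stage.CLINICAL_II, Stage.CLINICAL_III_IV)

#: preclinical stage -> matching clinical stage
CLINICAL_OF = {Stage.PRECLIN_I: Stage.CLINICAL_I,
               Stage.PRECLIN_II: Stage.CLINICAL_II,
               Stage.PRECLIN_III_IV: Stage.CLINICAL_III_IV}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayConfig:
    """Natural-history parameters for one pathway hypothesis.

    ``progressive_stage_means`` has six entries (LGD, IGD, HGD, preclinical
    I, II, III/IV).  ``indolent_stage_means`` has three (LGD, IGD, HGD);
    the indolent preclinical-stage-I dwell is unbounded.  ``onset_scale``
    is the calibrated Weibull cumulative-hazard level at ``onset_ref_age``.
    """

    pathway_name: str
    progressive_stage_means: tuple
    indolent_stage_means: Optional[tuple]
    indolent_fraction: float
    clinical_dx_prob: tuple = (0.051, 0.131, 1.0)
    five_year_survival: tuple = (0.291, 0.114, 0.0)
    lifetime_risk_target: float = 0.075
    cases_per_10k_target: float = 921.0
    deaths_per_10k_target: float = 751.0
    onset_scale: Optional[float] = None
    onset_shape: float = 5.0
    onset_ref_age: float = 80.0

    def __post_init__(self):
        if len(self.progressive_stage_means) != 6:
            raise ConfigError("progressive_stage_means needs 6 entries")
        if not (0.0 <= self.indolent_fraction <= 1.0):
            raise ConfigError("indolent_fraction must lie in [0, 1]")
        if self.indolent_fraction > 0 and self.indolent_stage_means is None:
            raise ConfigError("indolent pathway requires indolent_stage_means")
        if self.clinical_dx_prob[2] != 1.0:
            raise ConfigError("stage III/IV clinical-diagnosis probability must be 1")

    @property
    def calibrated(self) -> bool:
        return self.onset_scale is not None

    def require_calibrated(self) -> float:
        if self.onset_scale is None:
            raise ConfigError(
                f"pathway '{self.pathway_name}' has no onset_scale; run "
                "`pancsim calibrate` or calibration.calibrate_onset_scale first")
        return self.onset_scale

    def with_onset_scale(self, scale: float) -> "PathwayConfig":
        return replace(self, onset_scale=float(scale))

    def with_indolent_fraction(self, frac: float) -> "PathwayConfig":
        return replace(self, indolent_fraction=float(frac))

    @classmethod
    def from_yaml(cls, source) -> "PathwayConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PathwayConfig":
        ind = raw.get("indolent_stage_means")
        return cls(
            pathway_name=raw["pathway_name"],
            progressive_stage_means=tuple(raw["progressive_stage_means"]),
            indolent_stage_means=tuple(ind) if ind else None,
            indolent_fraction=float(raw.get("indolent_fraction", 0.0)),
            clinical_dx_prob=tuple(raw.get("clinical_dx_prob", (0.051, 0.131, 1.0))),
            five_year_survival=tuple(raw.get("five_year_survival", (0.291, 0.114, 0.0))),
            lifetime_risk_target=float(raw.get("lifetime_risk_target", 0.075)),
            cases_per_10k_target=float(raw.get("cases_per_10k_target", 921.0)),
            deaths_per_10k_target=float(raw.get("deaths_per_10k_target", 751.0)),
            onset_scale=(None if raw.get("onset_scale") is None
                         else float(raw["onset_scale"])),
            onset_shape=float(raw.get("onset_shape", 5.0)),
            onset_ref_age=float(raw.get("onset_ref_age", 80.0)),
        )


def load_preset(name: str) -> PathwayConfig:
    """Load a shipped pathway preset: ``progressive_only`` or ``indolent_included``."""
    ref = resources.files("pancsim").joinpath(f"presets/{name}.yaml")
    with ref.open() as fh:
        return PathwayConfig.from_yaml(fh)


# ---------------------------------------------------------------------------
# Elementary sampling operations (scalar and vectorized)
# ---------------------------------------------------------------------------

def sample_onset_age(config: PathwayConfig, u):
    """Age of lesion onset at uniform quantile ``u`` (inf = never).

    Inverse of ``P(onset <= a) = 1 - exp(-scale * (a/ref_age)**shape)``.
    """
    scale = config.require_calibrated()
    u = np.asarray(u, dtype=float)
    if scale == 0.0:
        out = np.full(u.shape, INF)
    else:
        e = -np.log1p(-u)
        out = config.onset_ref_age * (e / scale) ** (1.0 / config.onset_shape)
    return float(out) if out.ndim == 0 else out


def sample_onset_age_conditional(config: PathwayConfig, current_age: float, u: float) -> float:
    """Onset age of a *new* lesion given lesion-free survival to ``current_age``.

    Used after curative resection of a preinvasive lesion: the person
    re-enters the at-risk state with the same onset hazard, conditioned on
    the current age (memoryless in cumulative hazard).
    """
    scale = config.require_calibrated()
    if scale == 0.0:
        return INF
    h_now = scale * (current_age / config.onset_ref_age) ** config.onset_shape
    h_new = h_now - math.log1p(-u)
    return config.onset_ref_age * (h_new / scale) ** (1.0 / config.onset_shape)


def assign_lesion_fate(config: PathwayConfig, u):
    """True = indolent, False = progressive; Bernoulli(indolent_fraction)."""
    u = np.asarray(u, dtype=float)
    out = u < config.indolent_fraction
    return bool(out) if out.ndim == 0 else out


def sample_stage_durations(config: PathwayConfig, indolent: bool, v: float) -> np.ndarray:
    """Durations (years) for each stage of one lesion at shared quantile ``v``.

    Returns six entries ordered LGD..preclinical III/IV; indolent lesions get
    an infinite preclinical-stage-I dwell and no later stages.
    """
    if not (0.0 < v < 1.0):
        raise ValueError("v must lie in (0, 1)")
    e = -math.log1p(-v)
    if indolent:
        m = config.indolent_stage_means
        return np.array([m[0] * e, m[1] * e, m[2] * e, INF, 0.0, 0.0])
    m = config.progressive_stage_means
    return np.array([mi * e for mi in m])


def sample_clinical_detection(stage: Stage, dwell: float, config: PathwayConfig,
                              u: float, w: float) -> Optional[float]:
    """Time *within* a preclinical stage at which clinical diagnosis occurs.

    With the stage's detection probability the diagnosis lands uniformly in
    (0, dwell); otherwise returns None (the lesion moves on undetected).
    """
    if stage not in PRECLINICAL:
        raise ValueError(f"clinical detection applies to preclinical stages, got {stage!r}")
    p = config.clinical_dx_prob[stage - Stage.PRECLIN_I]
    if u < p:
        return w * dwell
    return None


def sample_pc_survival(stage_at_dx: Stage, config: PathwayConfig,
                       u: float, t: float) -> Optional[float]:
    """Years from diagnosis to pancreatic-cancer death, or None if cured.

    Cure probability is the stage-specific five-year survival; conditional
    on dying, the death time is uniform on (0, 5] years (linear mortality).
    The same law applies to screen-detected invasive cancer.
    """
    if stage_at_dx in CLINICAL:
        idx = stage_at_dx - Stage.CLINICAL_I
    elif stage_at_dx in PRECLINICAL:
        idx = stage_at_dx - Stage.PRECLIN_I
    else:
        raise ValueError(f"no survival law for stage {stage_at_dx!r}")
    s5 = config.five_year_survival[idx]
    if u < s5:
        return None
    return 5.0 * (1.0 - t)


# ---------------------------------------------------------------------------
# Full course assembly
# ---------------------------------------------------------------------------

@dataclass
class DiseaseCourse:
    """One person's unscreened timeline (latent disease values untruncated).

    ``stage_entry_ages`` maps each entered stage to its entry age on the
    latent (death-free) disease clock; events at or after
    ``other_cause_death_age`` never happen.  ``clinical_dx``/``pc_death_age``
    are None when the event does not occur before death.
    """

    onset_age: Optional[float]
    indolent: bool
    stage_entry_ages: dict
    clinical_dx: Optional[tuple]  # (age, clinical Stage)
    pc_death_age: Optional[float]
    other_cause_death_age: float
    final_death_age: float
    death_cause: str  # "other" | "pancreatic_cancer"


def _lesion_timeline(config: PathwayConfig, onset: float, indolent: bool,
                     v: float, det_u, det_w, surv_u: float, surv_t: float):
    """Latent lesion course from its draws (scalar; shared by the reference
    screening walk for re-onset lesions).

    Returns (entry_ages[6], dx_age, dx_preclin_stage, pc_death_age) with
    inf/0 sentinels: dx_stage 0 means never clinically diagnosed,
    pc_death_age inf means cured or undiagnosed.
    """
    e = -math.log1p(-v)
    entries = np.empty(6)
    t = onset
    if indolent:
        means = config.indolent_stage_means
        for i in range(3):
            entries[i] = t
            t += means[i] * e
        entries[3] = t          # preclinical stage I, absorbing
        entries[4] = INF
        entries[5] = INF
        return entries, INF, 0, INF
    means = config.progressive_stage_means
    for i in range(6):
        entries[i] = t
        t += means[i] * e
    dx_age, dx_stage = INF, 0
    for j in range(3):  # preclinical I, II, III/IV in order
        dwell = means[3 + j] * e
        if det_u[j] < config.clinical_dx_prob[j]:
            dx_age = entries[3 + j] + det_w[j] * dwell
            dx_stage = 4 + j
            break
    pc_death = INF
    if dx_stage:
        s5 = config.five_year_survival[dx_stage - 4]
        if not (surv_u < s5):
            pc_death = dx_age + 5.0 * (1.0 - surv_t)
    return entries, dx_age, dx_stage, pc_death


def build_disease_course(draws, config: PathwayConfig,
                         life_table: LifeTable) -> DiseaseCourse:
    """Assemble one person's unscreened course from its 12 uniform draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.shape != (N_DRAWS,):
        raise ValueError(f"expected {N_DRAWS} draws")
    other_death = sample_death_age(life_table, draws[COL_DEATH])
    onset = sample_onset_age(config, draws[COL_ONSET])
    if not np.isfinite(onset) or onset >= other_death:
        return DiseaseCourse(None, False, {}, None, None, other_death,
                             other_death, "other")
    indolent = assign_lesion_fate(config, draws[COL_FATE])
    entries, dx_age, dx_stage, pc_death = _lesion_timeline(
        config, onset, indolent, draws[COL_V],
        draws[list(COL_DET_U)], draws[list(COL_DET_W)],
        draws[COL_SURV_U], draws[COL_SURV_T])
    stage_entry_ages = {Stage(i + 1): entries[i] for i in range(6)
                        if np.isfinite(entries[i]) and entries[i] < other_death}
    clinical_dx = None
    pc_death_age = None
    if dx_stage and dx_age < other_death:
        clinical_dx = (dx_age, CLINICAL_OF[Stage(dx_stage)])
        if np.isfinite(pc_death) and pc_death < other_death:
            pc_death_age = pc_death
    final = other_death if pc_death_age is None else pc_death_age
    cause = "other" if pc_death_age is None else "pancreatic_cancer"
    return DiseaseCourse(onset, indolent, stage_entry_ages, clinical_dx,
                         pc_death_age, other_death, final, cause)


@dataclass
class Cohort:
    """Vectorized unscreened cohort (latent timelines + realized deaths).

    All per-person arrays have length ``n``.  ``entry`` is (n, 6) with the
    latent entry ages into LGD..preclinical III/IV (inf where never
    entered).  ``dx_age``/``dx_stage`` give the latent clinical diagnosis
    (stage coded 4/5/6 = preclinical index, 0 = never); ``pc_death`` the
    latent cancer death age.  Realized values (``cases``, ``final_death``,
    ``cause``) account for other-cause death truncation.
    """

    config: PathwayConfig
    other_death: np.ndarray
    onset: np.ndarray
    indolent: np.ndarray
    entry: np.ndarray
    dx_age: np.ndarray
    dx_stage: np.ndarray
    pc_death: np.ndarray
    surv_u: np.ndarray
    surv_t: np.ndarray

    @property
    def n(self) -> int:
        return self.other_death.size

    @property
    def case_mask(self) -> np.ndarray:
        """Clinically diagnosed before other-cause death (realized cases)."""
        return self.dx_age < self.other_death

    @property
    def pc_death_mask(self) -> np.ndarray:
        return self.case_mask & (self.pc_death < self.other_death)

    @property
    def final_death(self) -> np.ndarray:
        return np.where(self.pc_death_mask, self.pc_death, self.other_death)

    @property
    def cause(self) -> np.ndarray:
        """0 = other, 1 = pancreatic cancer."""
        return self.pc_death_mask.astype(np.int8)


def prevalence_by_age(cohort: "Cohort", ages=None) -> "np.ndarray":
    """Fraction of living persons in each disease stage at the given ages.

    Returns an array of shape (len(ages), 7): columns are NONE plus the six
    preinvasive/preclinical stages.  Persons already clinically diagnosed or
    dead at an age are excluded from that age's denominator.  This is the
    no-screening age-prevalence profile used as a qualitative calibration
    check and exportable as plot data.
    """
    if ages is None:
        ages = np.arange(30, 91, 5, dtype=float)
    ages = np.asarray(ages, dtype=float)
    out = np.zeros((ages.size, 7))
    for i, a in enumerate(ages):
        alive = (cohort.other_death > a) & ~(cohort.case_mask & (cohort.dx_age <= a))
        denom = alive.sum()
        if denom == 0:
            continue
        stage = np.zeros(cohort.n, dtype=np.int8)
        has = cohort.onset <= a
        for k in range(6):
            stage[has & (cohort.entry[:, k] <= a)] = k + 1
        for s in range(7):
            out[i, s] = np.mean(stage[alive] == s)
    return out


def draw_uniforms(n: int, seed) -> np.ndarray:
    """The (n, 12) natural-history uniforms in documented column order."""
    rng = np.random.default_rng(seed)
    return rng.random((n, N_DRAWS))


def simulate_cohort(config: PathwayConfig, n: int, seed,
                    life_table: LifeTable,
                    uniforms: Optional[np.ndarray] = None) -> Cohort:
    """Simulate ``n`` unscreened disease courses (vectorized).

    With ``uniforms`` given (shape (n, 12)), the draws are taken as-is,
    which is how the paired scenario engine imposes common random numbers.
    """
    config.require_calibrated()
    u = draw_uniforms(n, seed) if uniforms is None else uniforms
    if u.shape != (n, N_DRAWS):
        raise ValueError("uniforms must have shape (n, 12)")

    other_death = sample_death_age(life_table, u[:, COL_DEATH])
    onset = sample_onset_age(config, u[:, COL_ONSET])
    has_lesion = np.isfinite(onset) & (onset < other_death)
    onset = np.where(has_lesion, onset, INF)
    indolent = has_lesion & (u[:, COL_FATE] < config.indolent_fraction)
    progressive = has_lesion & ~indolent

    e = -np.log1p(-u[:, COL_V])
    entry = np.full((n, 6), INF)
    prog_means = np.asarray(config.progressive_stage_means)
    # progressive lesions: cumulative entry ages over all six stages
    dur_p = e[:, None] * prog_means[None, :]
    cum_p = np.cumsum(dur_p, axis=1)
    entry_p = onset[:, None] + np.concatenate(
        [np.zeros((n, 1)), cum_p[:, :5]], axis=1)
    entry[progressive] = entry_p[progressive]
    if config.indolent_fraction > 0:
        ind_means = np.asarray(config.indolent_stage_means)
        dur_i = e[:, None] * ind_means[None, :]
        cum_i = np.cumsum(dur_i, axis=1)
        entry_i = onset[:, None] + np.concatenate(
            [np.zeros((n, 1)), cum_i], axis=1)  # LGD, IGD, HGD, preclin I
        idx = np.where(indolent)[0]
        entry[idx, :4] = entry_i[idx]
        entry[idx, 4:] = INF

    # clinical detection: first preclinical stage whose Bernoulli fires
    dx_age = np.full(n, INF)
    dx_stage = np.zeros(n, dtype=np.int8)
    undetected = progressive.copy()
    for j in range(3):
        p = config.clinical_dx_prob[j]
        hit = undetected & (u[:, COL_DET_U[j]] < p)
        dwell = prog_means[3 + j] * e
        dx_age[hit] = entry[hit, 3 + j] + u[hit, COL_DET_W[j]] * dwell[hit]
        dx_stage[hit] = 4 + j
        undetected &= ~hit

    # survival after clinical diagnosis
    s5 = np.zeros(n)
    for j in range(3):
        s5[dx_stage == 4 + j] = config.five_year_survival[j]
    diagnosed = dx_stage > 0
    cured = diagnosed & (u[:, COL_SURV_U] < s5)
    pc_death = np.full(n, INF)
    dies = diagnosed & ~cured
    pc_death[dies] = dx_age[dies] + 5.0 * (1.0 - u[dies, COL_SURV_T])

    return Cohort(config=config, other_death=other_death, onset=onset,
                  indolent=indolent, entry=entry, dx_age=dx_age,
                  dx_stage=dx_stage, pc_death=pc_death,
                  surv_u=u[:, COL_SURV_U].copy(), surv_t=u[:, COL_SURV_T].copy())
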