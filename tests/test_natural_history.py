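"""Natural-history model: dwell times, detection, survival, full courses."""

import math

import numpy as np
import pytest

from pancsim import Stage, build_disease_course, simulate_cohort
from pancsim.natural_history import (ConfigError, PathwayConfig,
                                     assign_lesion_fate, draw_uniforms,
                                     sample_clinical_detection,
                                     sample_onset_age,
                                     sample_onset_age_conditional,
                                     sample_pc_survival,
                                     sample_stage_durations)

V_MEAN = 1.0 - math.exp(-1.0)  # exponential quantile at which duration == mean


def test_stage_durations_hit_means_at_unit_quantile(prog_config, ind_config):
    d = sample_stage_durations(prog_config, indolent=False, v=V_MEAN)
    np.testing.assert_allclose(d, [3.33, 3.33, 3.33, 2.0, 2.0, 1.0], rtol=1e-12)
    d = sample_stage_durations(ind_config, indolent=False, v=V_MEAN)
    np.testing.assert_allclose(d, [1.11, 1.11, 1.11, 0.66, 0.66, 0.33], rtol=1e-12)
    d = sample_stage_durations(ind_config, indolent=True, v=V_MEAN)
    np.testing.assert_allclose(d[:3], [7.08, 11.78, 24.15], rtol=1e-12)
    assert np.isinf(d[3])  # indolent preclinical stage I is absorbing


def _expected_onset_to_diagnosis(config):
    """Closed-form mean latent sojourn from lesion onset to clinical diagnosis.

    Detection fires in preclinical stage j with probability p_j (given no
    earlier detection) and then lands halfway through that stage's dwell on
    average; the shared exponential quantile has mean 1.
    """
    m = config.progressive_stage_means
    p1, p2, _ = config.clinical_dx_prob
    pre = sum(m[:3])
    return (pre
            + p1 * 0.5 * m[3]
            + (1 - p1) * p2 * (m[3] + 0.5 * m[4])
            + (1 - p1) * (1 - p2) * (m[3] + m[4] + 0.5 * m[5]))


@pytest.mark.parametrize("preset", ["prog_config", "ind_config"])
def test_mean_onset_to_diagnosis_sojourn(preset, request, life_table):
    """Monte-Carlo latent sojourn matches the closed-form stage arithmetic."""
    config = request.getfixturevalue(preset).with_indolent_fraction(0.0)
    n = 200_000
    cohort = simulate_cohort(config, n, 23, life_table)
    m = cohort.dx_stage > 0  # latent diagnoses, untruncated by death
    sojourn = (cohort.dx_age[m] - cohort.onset[m]).mean()
    assert sojourn == pytest.approx(_expected_onset_to_diagnosis(config), rel=0.02)


def test_shared_quantile_gives_perfect_rank_correlation(prog_config):
    d1 = sample_stage_durations(prog_config, False, 0.2)
    d2 = sample_stage_durations(prog_config, False, 0.8)
    assert np.all(d2 > d1)  # every stage is slower for the slower lesion


def test_clinical_detection_probabilities(prog_config):
    rng = np.random.default_rng(1)
    n = 100_000
    hits = sum(sample_clinical_detection(Stage.PRECLIN_I, 2.0, prog_config,
                                         rng.random(), rng.random()) is not None
               for _ in range(n))
    assert hits / n == pytest.approx(0.051, abs=0.003)
    # stage III/IV is always detected, uniformly within the dwell
    times = [sample_clinical_detection(Stage.PRECLIN_III_IV, 1.5, prog_config,
                                       rng.random(), rng.random())
             for _ in range(1000)]
    assert all(t is not None and 0 <= t <= 1.5 for t in times)
    with pytest.raises(ValueError):
        sample_clinical_detection(Stage.HGD, 1.0, prog_config, 0.5, 0.5)


def test_pc_survival_law(prog_config):
    rng = np.random.default_rng(2)
    n = 100_000
    times = np.array([
        t if (t := sample_pc_survival(Stage.CLINICAL_I, prog_config,
                                      rng.random(), rng.random())) is not None
        else np.inf for _ in range(n)])
    cured = np.isinf(times)
    assert cured.mean() == pytest.approx(0.291, abs=0.005)
    # linear mortality over 5 years: P(death <= 2.5y) = (1 - 0.291)/2
    assert (times <= 2.5).mean() == pytest.approx(0.3545, abs=0.005)
    assert np.all(times[~cured] <= 5.0)
    # stage III/IV: nobody survives 5 years
    t34 = [sample_pc_survival(Stage.CLINICAL_III_IV, prog_config,
                              rng.random(), rng.random()) for _ in range(1000)]
    assert all(t is not None and 0 < t <= 5.0 for t in t34)
    with pytest.raises(ValueError):
        sample_pc_survival(Stage.LGD, prog_config, 0.5, 0.5)


def test_onset_age_model(prog_config):
    assert np.isinf(sample_onset_age(prog_config.with_onset_scale(0.0), 0.5))
    cfg = prog_config.with_onset_scale(0.3)
    # quantile inversion round trip
    a = sample_onset_age(cfg, 0.25)
    u_back = 1.0 - math.exp(-0.3 * (a / 80.0) ** cfg.onset_shape)
    assert u_back == pytest.approx(0.25, rel=1e-9)
    # conditional re-onset is memoryless in cumulative hazard and beyond age
    a2 = sample_onset_age_conditional(cfg, 60.0, 0.5)
    assert a2 > 60.0
    uncal = cfg.with_onset_scale(0.3).__class__(**{**cfg.__dict__, "onset_scale": None})
    with pytest.raises(ConfigError):
        sample_onset_age(uncal, 0.5)


def test_low_risk_linearity_in_onset_scale(prog_config, life_table):
    # at low risk the lifetime case fraction is ~linear in the hazard scale
    n = 150_000
    u = draw_uniforms(n, 5)
    c1 = simulate_cohort(prog_config.with_onset_scale(0.01), n, None,
                         life_table, uniforms=u)
    c2 = simulate_cohort(prog_config.with_onset_scale(0.02), n, None,
                         life_table, uniforms=u)
    r1, r2 = c1.case_mask.mean(), c2.case_mask.mean()
    assert r2 / r1 == pytest.approx(2.0, rel=0.05)


def test_lesion_fate_bernoulli(ind_config):
    assert assign_lesion_fate(ind_config.with_indolent_fraction(0.0), 0.99) is False
    assert assign_lesion_fate(ind_config.with_indolent_fraction(1.0), 0.99) is True
    rng = np.random.default_rng(3)
    frac = np.mean(assign_lesion_fate(ind_config, rng.random(50_000)))
    assert frac == pytest.approx(ind_config.indolent_fraction, abs=0.01)


def test_build_disease_course_no_onset(prog_config, life_table):
    draws = np.full(12, 0.5)
    draws[1] = 1.0 - 1e-12  # onset quantile ~1 -> onset far beyond death
    course = build_disease_course(draws, prog_config, life_table)
    assert course.onset_age is None
    assert course.death_cause == "other"
    assert course.clinical_dx is None


def test_course_matches_vectorized_cohort(prog_config, life_table):
    n = 2_000
    u = draw_uniforms(n, 11)
    cohort = simulate_cohort(prog_config, n, None, life_table, uniforms=u)
    for i in range(0, n, 37):
        course = build_disease_course(u[i], prog_config, life_table)
        assert course.other_cause_death_age == pytest.approx(
            cohort.other_death[i], rel=1e-12)
        if course.clinical_dx is None:
            assert not cohort.case_mask[i]
        else:
            assert cohort.case_mask[i]
            assert course.clinical_dx[0] == pytest.approx(cohort.dx_age[i], rel=1e-9)
        assert course.final_death_age == pytest.approx(
            cohort.final_death[i], rel=1e-9)


def test_cohort_invariants_bulk(ind_config, life_table):
    n = 100_000
    cohort = simulate_cohort(ind_config, n, 17, life_table)
    has = np.isfinite(cohort.onset)
    fin = np.isfinite(cohort.entry)
    # entries strictly increasing where finite
    e = cohort.entry
    for k in range(5):
        m = has & fin[:, k] & fin[:, k + 1]
        assert np.all(e[m, k] < e[m, k + 1])
    # diagnosis lies inside the diagnosing stage; death within 5y of diagnosis
    dxd = cohort.dx_stage > 0
    for j, st in enumerate((3, 4, 5)):
        m = dxd & (cohort.dx_stage == 4 + j)
        assert np.all(cohort.dx_age[m] >= e[m, st])
    dies = np.isfinite(cohort.pc_death)
    assert np.all(cohort.pc_death[dies] > cohort.dx_age[dies])
    assert np.all(cohort.pc_death[dies] <= cohort.dx_age[dies] + 5.0)
    # indolent lesions: never diagnosed, never lethal
    assert not np.any(cohort.indolent & (cohort.dx_stage > 0))
    assert not np.any(cohort.indolent & np.isfinite(cohort.pc_death))
    # conservation: exactly one death cause each
    cause = cohort.cause
    assert np.all((cause == 0) | (cause == 1))
    assert (cause == 1).sum() + (cause == 0).sum() == n
    # cancer death requires prior diagnosis and is the realized minimum
    assert np.all(cohort.case_mask[cause == 1])
    np.testing.assert_array_equal(
        cohort.final_death,
        np.where(cohort.pc_death_mask, cohort.pc_death, cohort.other_death))


def test_preset_parameters_match_documented_values(prog_config, ind_config):
    assert prog_config.indolent_fraction == 0.0
    assert ind_config.indolent_stage_means == (7.08, 11.78, 24.15)
    assert prog_config.clinical_dx_prob == (0.051, 0.131, 1.0)
    assert prog_config.five_year_survival == (0.291, 0.114, 0.0)
    with pytest.raises(ConfigError):
        PathwayConfig(pathway_name="bad",
                      progressive_stage_means=(1, 1, 1, 1, 1, 1),
                      indolent_stage_means=None, indolent_fraction=0.0,
                      clinical_dx_prob=(0.1, 0.2, 0.5))


def test_prevalence_rises_with_age_and_indolent_accumulates(
        prog_config, ind_config, life_table):
    """Preinvasive prevalence rises steeply from midlife in both pathways,
    and the indolent pathway accumulates far more prevalent (harmless)
    lesions at older ages than the progressive-only pathway."""
    from pancsim.natural_history import prevalence_by_age

    n = 150_000
    ages = np.array([40.0, 55.0, 70.0, 85.0])
    prev_p = prevalence_by_age(simulate_cohort(prog_config, n, 29, life_table), ages)
    prev_i = prevalence_by_age(simulate_cohort(ind_config, n, 29, life_table), ages)
    lesion_p = prev_p[:, 1:].sum(axis=1)
    lesion_i = prev_i[:, 1:].sum(axis=1)
    assert np.all(np.diff(lesion_p) > 0)
    assert np.all(np.diff(lesion_i) > 0)
    assert lesion_i[-1] > lesion_p[-1]
    # each age row is a probability distribution over states
    np.testing.assert_allclose(prev_p.sum(axis=1), 1.0, atol=1e-12)
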