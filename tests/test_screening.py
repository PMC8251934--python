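"""Screening state machine: tests, management, surveillance, engine identity."""

import numpy as np
import pytest
from scipy.stats import binomtest

from pancsim import (ManagementPolicy, ScreeningPolicy, Stage,
                     TestCharacteristics, apply_test, manage_positive,
                     screen_schedule, simulate_screened_history)
from pancsim._engine import run_screening_cohort
from pancsim.engine import derive_seeds
from pancsim.natural_history import draw_uniforms, simulate_cohort
from pancsim.rng import CounterStream
from pancsim.screening import PolicyError, person_course


def make_cohort(config, n, seed, life_table):
    nh_seed, sc_seed = derive_seeds(seed)
    cohort = simulate_cohort(config, n, None, life_table,
                             uniforms=draw_uniforms(n, nh_seed))
    return cohort, sc_seed


def test_screen_schedule_counts():
    assert len(screen_schedule(ScreeningPolicy(interval=1.0))) == 26
    np.testing.assert_allclose(screen_schedule(ScreeningPolicy(interval=5.0)),
                               [50, 55, 60, 65, 70, 75])
    with pytest.raises(PolicyError):
        ScreeningPolicy(start_age=80, stop_age=75)


def test_apply_test_operating_points(chars):
    rng = np.random.default_rng(0)
    n = 50_000
    fp = np.mean([apply_test(Stage.NONE, chars, rng.random()) for _ in range(n)])
    assert fp == pytest.approx(0.10, abs=0.005)
    tp = np.mean([apply_test(Stage.PRECLIN_III_IV, chars, rng.random())
                  for _ in range(n)])
    assert tp == pytest.approx(0.99, abs=0.002)
    perfect = TestCharacteristics(sensitivity=(1.0,) * 6, specificity=1.0)
    assert apply_test(Stage.LGD, perfect, 0.999999)
    assert not apply_test(Stage.NONE, perfect, 1e-9)
    with pytest.raises(PolicyError):
        apply_test(Stage.CLINICAL_I, chars, 0.5)


def test_manage_positive_dispositions(mgmt):
    assert manage_positive(Stage.PRECLIN_III_IV, mgmt, 0.0) == "palliate"
    never = ManagementPolicy(resect_prob_given_positive=(0.0,) * 5)
    assert manage_positive(Stage.HGD, never, 0.5) == "surveil"
    assert manage_positive(Stage.NONE, mgmt, 0.5) == "surveil"


def test_stage_one_effective_resection_fraction(chars, mgmt):
    """Sensitivity 0.9 x resection probability 0.9 => 81% of stage-I persons
    are referred for resection per screening round (exact binomial check)."""
    rng = np.random.default_rng(81)
    n = 100_000
    resected = 0
    for _ in range(n):
        if apply_test(Stage.PRECLIN_I, chars, rng.random()):
            if manage_positive(Stage.PRECLIN_I, mgmt, rng.random()) == "resect":
                resected += 1
    assert binomtest(resected, n, 0.81).pvalue > 1e-3


def test_null_policy_equivalence(prog_config, life_table, policy_annual, mgmt):
    """Sensitivity 0 / specificity 1: screening changes nothing, person by person."""
    blind = TestCharacteristics(sensitivity=(0.0,) * 6, specificity=1.0)
    cohort, sc_seed = make_cohort(prog_config, 20_000, 9, life_table)
    arrs = run_screening_cohort(cohort, policy_annual, blind, mgmt, sc_seed)
    np.testing.assert_array_equal(arrs["final_death_age"], cohort.final_death)
    np.testing.assert_array_equal(arrs["cause"], cohort.cause)
    assert arrs["resections"].sum() == 0
    assert arrs["n_surveillance_tests"].sum() == 0
    assert (arrs["clinical_dx_stage"] > 0).sum() == cohort.case_mask.sum()


@pytest.mark.parametrize("preset", ["prog_config", "ind_config"])
def test_reference_walk_matches_engine_exactly(preset, request, life_table,
                                               policy_annual, chars, mgmt):
    """Event-by-event oracle: the interpreted per-person walk and the compiled
    cohort engine agree bit-for-bit on 10^4 persons."""
    config = request.getfixturevalue(preset)
    n = 10_000
    cohort, sc_seed = make_cohort(config, n, 5, life_table)
    arrs = run_screening_cohort(cohort, policy_annual, chars, mgmt, sc_seed)
    for i in range(n):
        h = simulate_screened_history(person_course(cohort, i), policy_annual,
                                      chars, mgmt, config,
                                      CounterStream(sc_seed, i))
        assert h.n_screen_tests == arrs["n_screen_tests"][i]
        assert h.n_surveillance_tests == arrs["n_surveillance_tests"][i]
        assert h.final_death_age == arrs["final_death_age"][i]
        assert h.death_cause == arrs["cause"][i]
        assert np.array_equal(h.resections, arrs["resections"][i])
        sd = h.screen_dx or (np.nan, 0)
        assert sd[1] == arrs["sd_stage"][i]
        cd = h.clinical_dx or (np.nan, 0)
        assert cd[1] == arrs["clinical_dx_stage"][i]
        assert h.interval_cancer == arrs["interval_cancer"][i]
        assert h.interval_cancer_5y == arrs["interval_cancer_5y"][i]


def test_event_log_respects_lifetimes(prog_config, life_table, policy_annual,
                                      chars, mgmt):
    """No test before start age, after death, or after program exit; no
    surveillance without a preceding positive."""
    n = 3_000
    cohort, sc_seed = make_cohort(prog_config, n, 13, life_table)
    for i in range(n):
        h = simulate_screened_history(person_course(cohort, i), policy_annual,
                                      chars, mgmt, prog_config,
                                      CounterStream(sc_seed, i))
        seen_positive = False
        for ev, age, stage in h.events:
            if ev in ("screen_test", "surveillance_test"):
                assert 50.0 <= age < cohort.other_death[i]
                assert age <= h.final_death_age
            if ev == "surveillance_test":
                assert seen_positive
            if ev == "to_surveillance":
                seen_positive = True
        if cohort.other_death[i] <= 50.0:
            assert h.n_screen_tests == 0


def test_screen_detected_late_cancer_is_palliated(prog_config, life_table,
                                                  policy_annual, chars, mgmt):
    n = 100_000
    cohort, sc_seed = make_cohort(prog_config, n, 21, life_table)
    arrs = run_screening_cohort(cohort, policy_annual, chars, mgmt, sc_seed)
    late = arrs["sd_stage"] == 6
    assert late.sum() > 0
    # stage III/IV keeps the 0% five-year survival: death (from cancer or
    # other causes) within five years of screen detection, never surgical
    dt = arrs["final_death_age"][late] - arrs["sd_age"][late]
    assert np.all(dt <= 5.0 + 1e-9)
    assert not np.any(arrs["cause"][late] == 2)


def test_surgical_mortality_extremes(prog_config, life_table, policy_annual,
                                     chars):
    n = 30_000
    cohort, sc_seed = make_cohort(prog_config, n, 31, life_table)
    lethal = ManagementPolicy(surgical_mortality=0.999999)
    arrs = run_screening_cohort(cohort, policy_annual, chars, lethal, sc_seed)
    had_resection = arrs["resections"].sum(axis=1) > 0
    assert had_resection.sum() > 0
    assert np.all(arrs["cause"][had_resection] == 2)
    # with no surgical mortality, a resected preinvasive lesion (and no later
    # disease) cannot cause a cancer death
    safe = ManagementPolicy(surgical_mortality=0.0)
    arrs = run_screening_cohort(cohort, policy_annual, chars, safe, sc_seed)
    preinv_only = ((arrs["resections"][:, 1:4].sum(axis=1) > 0)
                   & (arrs["sd_stage"] == 0)
                   & (arrs["clinical_dx_stage"] == 0))
    assert preinv_only.sum() > 0
    assert np.all(arrs["cause"][preinv_only] == 0)
    np.testing.assert_array_equal(arrs["final_death_age"][preinv_only],
                                  cohort.other_death[preinv_only])


def test_policy_after_all_deaths_changes_nothing(prog_config, life_table,
                                                 chars, mgmt):
    late = ScreeningPolicy(start_age=112.0, stop_age=120.0, interval=1.0)
    n = 5_000
    cohort, sc_seed = make_cohort(prog_config, n, 3, life_table)
    arrs = run_screening_cohort(cohort, late, chars, mgmt, sc_seed)
    assert arrs["n_screen_tests"].sum() == 0
    np.testing.assert_array_equal(arrs["final_death_age"], cohort.final_death)


def test_screening_config_yaml_round_trip(tmp_path):
    from pancsim.screening import load_screening_config

    cfg = tmp_path / "screening.yaml"
    cfg.write_text(
        "policy: {start_age: 50, stop_age: 75, interval: 5.0}\n"
        "test: {sensitivity: [0.6, 0.6, 0.75, 0.9, 0.93, 0.99], specificity: 0.95}\n"
        "management: {surgical_mortality: 0.05}\n")
    policy, chars, mgmt = load_screening_config(cfg)
    assert policy.interval == 5.0
    assert chars.specificity == 0.95
    assert mgmt.surgical_mortality == 0.05
    assert mgmt.resect_prob_given_positive == (0.9,) * 5


def test_event_log_export(prog_config, life_table, policy_annual, chars, mgmt,
                          tmp_path):
    from pancsim.screening import event_log_frame

    cohort, sc_seed = make_cohort(prog_config, 500, 7, life_table)
    frame = event_log_frame(cohort, policy_annual, chars, mgmt, prog_config,
                            sc_seed)
    assert set(frame.columns) == {"person_id", "event_type", "age", "stage"}
    assert (frame.event_type == "screen_test").sum() > 0
    out = tmp_path / "events.csv"
    frame.to_csv(out, index=False)
    assert out.exists()
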