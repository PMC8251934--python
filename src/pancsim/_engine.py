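"""Compiled cohort-scale screening engine.

Implements exactly the per-person walk of
:func:`pancsim.screening.simulate_screened_history`, over whole cohorts of
latent disease timelines, consuming the same counter-based draw protocol.
The two implementations are kept independent on purpose: their event-by-
event agreement is an enforced test invariant, so any divergence in either
is caught.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .rng import stream_key_nb, u01_nb

INF = np.inf


@njit(cache=True)
def _lesion_timeline_nb(prog_means, ind_means, dx_prob, s5, onset, indolent,
                        v, det_u, det_w, surv_u, surv_t, entry_out):
    """Latent lesion course from its draws; fills entry_out (6,).

    Returns (dx_age, dx_stage, pc_death).
    """
    e = -np.log1p(-v)
    t = onset
    if indolent:
        for k in range(3):
            entry_out[k] = t
            t += ind_means[k] * e
        entry_out[3] = t
        entry_out[4] = INF
        entry_out[5] = INF
        return INF, 0, INF
    for k in range(6):
        entry_out[k] = t
        t += prog_means[k] * e
    dx_age = INF
    dx_stage = 0
    for j in range(3):
        dwell = prog_means[3 + j] * e
        if det_u[j] < dx_prob[j]:
            dx_age = entry_out[3 + j] + det_w[j] * dwell
            dx_stage = 4 + j
            break
    pc_death = INF
    if dx_stage > 0:
        if not (surv_u < s5[dx_stage - 4]):
            pc_death = dx_age + 5.0 * (1.0 - surv_t)
    return dx_age, dx_stage, pc_death


@njit(cache=True)
def _run(other_death, onset0, indolent0, entry0, dx_age0, dx_stage0,
         pc_death0, surv_u0, surv_t0,
         sched, surveillance_interval,
         sens, one_minus_spec,
         resect_prob, surgical_mortality, fp_rounds,
         onset_scale, onset_shape, onset_ref_age, indolent_fraction,
         prog_means, ind_means, dx_prob, s5,
         seed,
         n_screen, n_surv, resect_counts, sd_age_arr, sd_stage_arr,
         clin_age_arr, clin_stage_arr, final_death, cause,
         interval_tot, interval_5y, first_neg):
    n = other_death.size
    n_sched = sched.size
    entry = np.empty(6)
    det_u = np.empty(3)
    det_w = np.empty(3)
    seed_u = np.uint64(seed)
    one_u = np.uint64(1)
    for p in range(n):
        key = stream_key_nb(seed_u, np.uint64(p))
        ctr = np.uint64(0)
        od = other_death[p]
        onset = onset0[p]
        indolent = indolent0[p]
        for k in range(6):
            entry[k] = entry0[p, k]
        dx_age = dx_age0[p]
        dx_stage = dx_stage0[p]
        pc_death = pc_death0[p]
        surv_u = surv_u0[p]
        surv_t = surv_t0[p]

        i = 0
        in_surveillance = False
        surv_next = 0.0
        fp_streak = 0
        last_screen_negative = False
        last_neg_age = np.nan
        firstneg = np.nan
        nsc = 0
        nsu = 0
        sd_age = np.nan
        sd_stage = 0
        clin_age = np.nan
        clin_stage = 0
        fdeath = od
        fcause = 0
        exited = False
        got_clin = False

        while True:
            if in_surveillance:
                a = surv_next
            else:
                if i >= n_sched:
                    break
                a = sched[i]
            if dx_age < a and dx_age < od:
                got_clin = True
                exited = True
                break
            if od <= a:
                break
            if not in_surveillance:
                i += 1
            # true stage at test time
            stage = 0
            if a >= onset:
                for k in range(6):
                    if a >= entry[k]:
                        stage = k + 1
            u = u01_nb(key, ctr)
            ctr += one_u
            if stage == 0:
                positive = u < one_minus_spec
            else:
                positive = u < sens[stage - 1]
            if in_surveillance:
                nsu += 1
            else:
                nsc += 1
                last_screen_negative = not positive
                if not positive:
                    last_neg_age = a
                    if np.isnan(firstneg):
                        firstneg = a
            if not positive:
                if in_surveillance:
                    if stage == 0:
                        fp_streak += 1
                        if fp_streak >= fp_rounds:
                            in_surveillance = False
                            while i < n_sched and sched[i] <= a:
                                i += 1
                        else:
                            surv_next = a + surveillance_interval
                    else:
                        surv_next = a + surveillance_interval
                continue
            # positive test
            if stage == 6:
                sd_age = a
                sd_stage = 6
                pc = a + 5.0 * (1.0 - surv_t)
                if pc < od:
                    fdeath = pc
                    fcause = 1
                exited = True
                break
            u2 = u01_nb(key, ctr)
            ctr += one_u
            if u2 < resect_prob[stage]:
                resect_counts[p, stage] += 1
                u3 = u01_nb(key, ctr)
                ctr += one_u
                if u3 < surgical_mortality:
                    fdeath = a
                    fcause = 2
                    exited = True
                    break
                if stage == 4 or stage == 5:
                    sd_age = a
                    sd_stage = stage
                    if not (surv_u < s5[stage - 4]):
                        pc = a + 5.0 * (1.0 - surv_t)
                        if pc < od:
                            fdeath = pc
                            fcause = 1
                    exited = True
                    break
                if stage != 0:
                    onset = INF
                    dx_age = INF
                    dx_stage = 0
                    pc_death = INF
                    for k in range(6):
                        entry[k] = INF
                    u4 = u01_nb(key, ctr)
                    ctr += one_u
                    if onset_scale > 0.0:
                        h_now = onset_scale * (a / onset_ref_age) ** onset_shape
                        h_new = h_now - np.log1p(-u4)
                        new_onset = onset_ref_age * (h_new / onset_scale) ** (1.0 / onset_shape)
                    else:
                        new_onset = INF
                    if new_onset < od:
                        onset = new_onset
                        uf = u01_nb(key, ctr)
                        ctr += one_u
                        indolent = uf < indolent_fraction
                        v = u01_nb(key, ctr)
                        ctr += one_u
                        for j in range(3):
                            det_u[j] = u01_nb(key, ctr)
                            ctr += one_u
                            det_w[j] = u01_nb(key, ctr)
                            ctr += one_u
                        us = u01_nb(key, ctr)
                        ctr += one_u
                        ts = u01_nb(key, ctr)
                        ctr += one_u
                        dx_age, dx_stage, pc_death = _lesion_timeline_nb(
                            prog_means, ind_means, dx_prob, s5, new_onset,
                            indolent, v, det_u, det_w, us, ts, entry)
                        surv_u = us
                        surv_t = ts
                in_surveillance = False
                fp_streak = 0
                while i < n_sched and sched[i] <= a:
                    i += 1
            else:
                in_surveillance = True
                fp_streak = 0
                surv_next = a + surveillance_interval

        if not exited and dx_age < od:
            got_clin = True
        if got_clin:
            clin_age = dx_age
            clin_stage = dx_stage
            if pc_death < od:
                fdeath = pc_death
                fcause = 1
            if nsc > 0 and last_screen_negative:
                interval_tot[p] = True
                if dx_age - last_neg_age <= 5.0:
                    interval_5y[p] = True

        n_screen[p] = nsc
        n_surv[p] = nsu
        sd_age_arr[p] = sd_age
        sd_stage_arr[p] = sd_stage
        clin_age_arr[p] = clin_age
        clin_stage_arr[p] = clin_stage
        final_death[p] = fdeath
        cause[p] = fcause
        first_neg[p] = firstneg


def run_screening_cohort(cohort, policy, chars, mgmt, seed: int) -> dict:
    """Apply a screening policy to a whole cohort; returns per-person arrays."""
    from .screening import screen_schedule  # local import avoids a cycle

    cfg = cohort.config
    n = cohort.n
    out = {
        "n_screen_tests": np.zeros(n, dtype=np.int32),
        "n_surveillance_tests": np.zeros(n, dtype=np.int32),
        "resections": np.zeros((n, 6), dtype=np.int16),
        "sd_age": np.full(n, np.nan),
        "sd_stage": np.zeros(n, dtype=np.int8),
        "clinical_dx_age": np.full(n, np.nan),
        "clinical_dx_stage": np.zeros(n, dtype=np.int8),
        "final_death_age": np.empty(n),
        "cause": np.zeros(n, dtype=np.int8),
        "interval_cancer": np.zeros(n, dtype=np.bool_),
        "interval_cancer_5y": np.zeros(n, dtype=np.bool_),
        "first_negative_screen_age": np.full(n, np.nan),
    }
    ind_means = (np.asarray(cfg.indolent_stage_means, dtype=float)
                 if cfg.indolent_stage_means else np.zeros(3))
    _run(cohort.other_death, cohort.onset,
         cohort.indolent.astype(np.bool_), cohort.entry,
         cohort.dx_age, cohort.dx_stage.astype(np.int64), cohort.pc_death,
         cohort.surv_u, cohort.surv_t,
         screen_schedule(policy), policy.surveillance_interval,
         np.asarray(chars.sensitivity, dtype=float), 1.0 - chars.specificity,
         mgmt.resect_prob_vector(), mgmt.surgical_mortality,
         mgmt.false_positive_surveillance_rounds,
         cfg.require_calibrated(), cfg.onset_shape, cfg.onset_ref_age,
         cfg.indolent_fraction,
         np.asarray(cfg.progressive_stage_means, dtype=float), ind_means,
         np.asarray(cfg.clinical_dx_prob, dtype=float),
         np.asarray(cfg.five_year_survival, dtype=float),
         np.uint64(seed & ((1 << 64) - 1)),
         out["n_screen_tests"], out["n_surveillance_tests"],
         out["resections"], out["sd_age"], out["sd_stage"],
         out["clinical_dx_age"], out["clinical_dx_stage"],
         out["final_death_age"], out["cause"],
         out["interval_cancer"], out["interval_cancer_5y"],
         out["first_negative_screen_age"])
    return out
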