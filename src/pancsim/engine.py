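"""Paired-scenario orchestration: common random numbers, base cases, grids.

Both arms of a scenario consume identical natural-history draws (one block
of uniforms per person, drawn from a seed derived from the scenario seed),
while screening decisions use a separate per-person counter-based stream.
A person whose history screening never touches is therefore bit-identical
across arms, which is what makes small between-arm differences (deaths
prevented, life-years gained) estimable at practical cohort sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._engine import run_screening_cohort
from .demography import LifeTable, default_life_table
from .natural_history import PathwayConfig, draw_uniforms, simulate_cohort
from .outcomes import (OutcomeTable, ScenarioCounters, counters_from_screened,
                       counters_from_unscreened, life_years_gained,
                       outcome_frame)
from .screening import ManagementPolicy, ScreeningPolicy, TestCharacteristics


def annual_policy() -> ScreeningPolicy:
    return ScreeningPolicy(start_age=50.0, stop_age=75.0, interval=1.0)


def five_yearly_policy() -> ScreeningPolicy:
    return ScreeningPolicy(start_age=50.0, stop_age=75.0, interval=5.0)


POLICIES = {"annual": annual_policy, "5yearly": five_yearly_policy,
            "five_yearly": five_yearly_policy}


def derive_seeds(seed: int) -> tuple[int, int]:
    """(natural-history seed, screening-stream seed) from the scenario seed."""
    ss = np.random.SeedSequence(seed)
    nh, sc = ss.generate_state(2, np.uint64)
    return int(nh), int(sc)


@dataclass
class PairedResult:
    table: OutcomeTable
    unscreened: ScenarioCounters
    screened: ScenarioCounters
    final_death_unscreened: np.ndarray
    final_death_screened: np.ndarray
    screened_arrays: dict


def run_paired_scenario(config: PathwayConfig,
                        policy: Optional[ScreeningPolicy],
                        chars: TestCharacteristics,
                        mgmt: ManagementPolicy,
                        n_persons: int, seed: int,
                        life_table: Optional[LifeTable] = None,
                        scenario_name: str = "") -> PairedResult:
    """Simulate one cohort with and without the given screening policy.

    ``policy=None`` runs the no-screening scenario in both arms (a null
    comparison with zero differences everywhere).
    """
    config.require_calibrated()
    table = life_table or default_life_table()
    nh_seed, screen_seed = derive_seeds(seed)
    uniforms = draw_uniforms(n_persons, nh_seed)
    cohort = simulate_cohort(config, n_persons, None, table, uniforms=uniforms)
    cu = counters_from_unscreened(cohort)
    fd_u = cohort.final_death

    if policy is None:
        cs = cu
        fd_s = fd_u
        arrs = {}
    else:
        arrs = run_screening_cohort(cohort, policy, chars, mgmt, screen_seed)
        cs = counters_from_screened(n_persons, arrs)
        fd_s = arrs["final_death_age"]

    lyg = life_years_gained(fd_s, fd_u)
    name = scenario_name or f"{config.pathway_name}"
    out = OutcomeTable(scenario=name, unscreened=cu, screened=cs, lyg=lyg)
    return PairedResult(table=out, unscreened=cu, screened=cs,
                        final_death_unscreened=fd_u, final_death_screened=fd_s,
                        screened_arrays=arrs)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario/sensitivity grid."""

    pathway: str = "progressive_only"
    policy: str = "annual"                  # none | annual | 5yearly
    risk_multiplier: float = 1.0            # 0.5 | 1 | 2 (recalibrated)
    sensitivity_multiplier: float = 1.0     # per stage, capped at 1
    specificity: Optional[float] = None
    surgical_mortality: Optional[float] = None
    n_persons: int = 1_000_000
    seed: int = 1

    def label(self) -> str:
        parts = [self.pathway, self.policy]
        if self.risk_multiplier != 1.0:
            parts.append(f"risk_x{self.risk_multiplier:g}")
        if self.sensitivity_multiplier != 1.0:
            parts.append(f"sens_x{self.sensitivity_multiplier:g}")
        if self.specificity is not None:
            parts.append(f"spec_{self.specificity:g}")
        if self.surgical_mortality is not None:
            parts.append(f"surgmort_{self.surgical_mortality:g}")
        return "/".join(parts)


def run_spec(spec: ScenarioSpec, configs_by_risk: dict,
             life_table: Optional[LifeTable] = None) -> PairedResult:
    """Run one grid cell; ``configs_by_risk[pathway][multiplier]`` holds the
    calibrated configs (base-case and recalibrated halved/doubled risks)."""
    try:
        config = configs_by_risk[spec.pathway][spec.risk_multiplier]
    except KeyError as exc:
        raise KeyError(
            f"no calibrated config for pathway={spec.pathway!r} at risk "
            f"multiplier {spec.risk_multiplier}; run `pancsim calibrate "
            f"--pathway {spec.pathway} --risk-multiplier {spec.risk_multiplier}`"
        ) from exc
    chars = TestCharacteristics().scaled(spec.sensitivity_multiplier)
    if spec.specificity is not None:
        chars = chars.with_specificity(spec.specificity)
    mgmt = ManagementPolicy()
    if spec.surgical_mortality is not None:
        mgmt = mgmt.with_surgical_mortality(spec.surgical_mortality)
    policy = None if spec.policy == "none" else POLICIES[spec.policy]()
    return run_paired_scenario(config, policy, chars, mgmt, spec.n_persons,
                               spec.seed, life_table, scenario_name=spec.label())


def sensitivity_grid_specs(pathway: str, n_persons: int, seed: int,
                           policy: str = "annual") -> list[ScenarioSpec]:
    """The sensitivity-analysis row set for one pathway and interval."""
    base = dict(pathway=pathway, policy=policy, n_persons=n_persons, seed=seed)
    specs = [ScenarioSpec(**base)]
    specs += [ScenarioSpec(**base, risk_multiplier=m) for m in (0.5, 2.0)]
    specs += [ScenarioSpec(**base, sensitivity_multiplier=m)
              for m in (1.05, 1.10, 0.95, 0.90)]
    specs += [ScenarioSpec(**base, specificity=s) for s in (0.85, 0.95, 1.0)]
    specs += [ScenarioSpec(**base, surgical_mortality=0.05)]
    return specs


def run_sensitivity_grid(configs_by_risk: dict, n_persons: int, seed: int,
                         pathways=("progressive_only", "indolent_included"),
                         policy: str = "annual",
                         life_table: Optional[LifeTable] = None) -> pd.DataFrame:
    """Execute the full sensitivity row set, sharing base seeds across cells.

    Failures are isolated per cell: a failed cell is logged as a row with an
    ``error`` column and the grid continues.
    """
    rows = []
    tables = []
    for pathway in pathways:
        for spec in sensitivity_grid_specs(pathway, n_persons, seed, policy):
            try:
                res = run_spec(spec, configs_by_risk, life_table)
                tables.append(res.table)
            except Exception as exc:  # noqa: BLE001 - cell isolation is the point
                rows.append({"scenario": spec.label(), "error": str(exc)})
    frame = outcome_frame(tables)
    if rows:
        frame = pd.concat([frame, pd.DataFrame(rows)], ignore_index=True)
    return frame


def write_manifest(path, *, seed: int, n_persons: int, configs: dict,
                   extra: Optional[dict] = None) -> None:
    """Run manifest: seeds and parameters sufficient to reproduce every count."""
    import pancsim

    manifest = {
        "pancsim_version": pancsim.__version__,
        "seed": seed,
        "n_persons": n_persons,
        "configs": configs,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
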