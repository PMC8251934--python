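"""All-cause (other-cause) mortality: life tables and death-age sampling.

The simulated cohort needs a death age from causes other than pancreatic
cancer for every person.  Because the high-risk cohorts of interest are not
tied to one national registry, the default table is parametric: a
Gompertz-Makeham survival curve

    S(x) = exp(-c*x - (b/g) * (exp(g*x) - 1))

with a small fixed background (Makeham) hazard ``c`` and the two Gompertz
parameters fitted to a target life expectancy and a target probability of
surviving to age 50 (the age screening starts).  The shipped default is
anchored to a life expectancy of 69.7 years and survival-to-50 of 0.925,
which reproduce the person-years and screened-fraction bookkeeping of the
benchmark cohort (see docs/methods.md).  Any user table can be supplied as a two-column CSV
(age, cumulative_survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

DEFAULT_MAX_AGE = 110
DEFAULT_MAKEHAM = 5e-4

#: Default calibration anchors for the shipped table.
DEFAULT_LIFE_EXPECTANCY = 69.7
DEFAULT_SURVIVAL_50 = 0.925


class LifeTableError(ValueError):
    pass


@dataclass(frozen=True)
class LifeTable:
    """Cumulative survival from birth at exact integer ages 0..max_age.

    Invariants: ``survival[0] == 1``, non-increasing, ``survival[max_age] == 0``.
    Between integer ages survival is linearly interpolated, so sampled death
    ages are continuous.
    """

    survival: np.ndarray
    max_age: int = field(init=False)

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if s.ndim != 1 or s.size < 2:
            raise LifeTableError("survival must be a 1-D array of length >= 2")
        if s[0] != 1.0:
            raise LifeTableError("survival at age 0 must be 1")
        if s[-1] != 0.0:
            raise LifeTableError("survival at max_age must be 0")
        if np.any(np.diff(s) > 0):
            raise LifeTableError("survival must be non-increasing")
        object.__setattr__(self, "survival", s)
        object.__setattr__(self, "max_age", s.size - 1)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.survival.size, dtype=float)

    def life_expectancy(self) -> float:
        """Expected death age under linear interpolation (trapezoid of S)."""
        return float(np.trapezoid(self.survival, self.ages))

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        data = np.genfromtxt(path, delimiter=",", names=True)
        ages = data["age"].astype(int)
        if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)) or ages.min() != 0:
            raise LifeTableError("life-table CSV must list consecutive integer ages from 0")
        return cls(survival=np.asarray(data["cumulative_survival"], dtype=float))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.ages, self.survival])
        np.savetxt(path, arr, delimiter=",", header="age,cumulative_survival",
                   comments="", fmt="%.10g")


def survival_to_age(table: LifeTable, age) -> float | np.ndarray:
    """Cumulative survival at ``age`` (years), linearly interpolated."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0) or np.any(age > table.max_age):
        raise LifeTableError(f"age out of range [0, {table.max_age}]")
    out = np.interp(age, table.ages, table.survival)
    return float(out) if out.ndim == 0 else out


def sample_death_age(table: LifeTable, u) -> float | np.ndarray:
    """Death age at survival quantile ``u`` in [0, 1).

    ``u`` is the survival level: u -> 0+ gives ages near ``max_age``, u -> 1-
    gives ages near 0.  Linear interpolation within years; deterministic in u.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u >= 1):
        raise LifeTableError("u must lie in [0, 1)")
    # np.interp needs ascending x: reverse the (survival, age) pairs.
    out = np.interp(u, table.survival[::-1], table.ages[::-1])
    return float(out) if out.ndim == 0 else out


def sample_death_ages(table: LifeTable, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. death ages."""
    return sample_death_age(table, rng.random(n))


def _gm_survival(x, b, g, c):
    return np.exp(-c * x - (b / g) * (np.expm1(g * x)))


def make_gompertz_makeham_table(b: float, g: float, c: float = DEFAULT_MAKEHAM,
                                max_age: int = DEFAULT_MAX_AGE) -> LifeTable:
    ages = np.arange(max_age + 1, dtype=float)
    s = _gm_survival(ages, b, g, c)
    s[-1] = 0.0  # close the table; the mass beyond max_age is negligible
    s[0] = 1.0
    return LifeTable(survival=s)


def fit_life_table(target_life_expectancy: float = DEFAULT_LIFE_EXPECTANCY,
                   target_survival_50: float = DEFAULT_SURVIVAL_50,
                   makeham: float = DEFAULT_MAKEHAM,
                   max_age: int = DEFAULT_MAX_AGE) -> LifeTable:
    """Fit Gompertz parameters (b, g) to the two anchors.

    For a given slope ``g`` the level ``b`` is available in closed form from
    the survival-to-50 constraint; life expectancy is then monotone
    decreasing in ``g``, so a bracketed root-find suffices.  Raises
    ``LifeTableError`` when the target pair is infeasible.
    """
    if not (0.0 < target_survival_50 < 1.0):
        raise LifeTableError("target_survival_50 must be in (0, 1)")
    if not (0.0 < target_life_expectancy < max_age):
        raise LifeTableError("target_life_expectancy must be in (0, max_age)")

    h50 = -np.log(target_survival_50) - 50.0 * makeham
    if h50 <= 0:
        raise LifeTableError("Makeham background alone exceeds the survival-to-50 target")

    def b_of(g):
        return g * h50 / np.expm1(50.0 * g)

    def le_of(g):
        b = b_of(g)
        val, _ = quad(_gm_survival, 0.0, max_age, args=(b, g, makeham), limit=200)
        return val

    lo, hi = 1e-4, 0.5
    f_lo = le_of(lo) - target_life_expectancy
    f_hi = le_of(hi) - target_life_expectancy
    if f_lo * f_hi > 0:
        raise LifeTableError(
            "infeasible target pair: achievable life expectancy range "
            f"[{le_of(hi):.2f}, {le_of(lo):.2f}] does not cover "
            f"{target_life_expectancy}")
    g = brentq(lambda x: le_of(x) - target_life_expectancy, lo, hi, xtol=1e-10)
    table = make_gompertz_makeham_table(b_of(g), g, makeham, max_age)

    le = table.life_expectancy()
    s50 = survival_to_age(table, 50.0)
    if abs(le - target_life_expectancy) / target_life_expectancy > 0.005 or \
       abs(s50 - target_survival_50) / target_survival_50 > 0.005:
        raise LifeTableError(
            f"fit did not reach targets: LE={le:.3f}, S(50)={s50:.4f}")
    return table


_DEFAULT_TABLE: LifeTable | None = None


def default_life_table() -> LifeTable:
    """The shipped table (fitted once per process, then cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = fit_life_table()
    return _DEFAULT_TABLE
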