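"""Deterministic three-state Markov cohort engine.

States are progression-free survival (PFS), progressed survival (PS) and
death. The whole cohort enters in PFS. Each cycle, death is evaluated first
for both alive states from the arm's overall-survival law; survivors of the
PFS state then progress with the remainder probability implied by the
progression-free survival law (see :func:`sclc_cea.survival.tp_progress`).
Death is absorbing, so total alive occupancy telescopes exactly to the
overall-survival curve.

Accrual convention: per-cycle quantities (life-years, utilities, per-cycle
costs) are accumulated with a standard half-cycle correction by default —
each cycle contributes the mean of its start- and end-of-cycle occupancy —
with ``half_cycle="none"`` (start-of-cycle occupancy) available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .survival import SurvivalParams, survival_probability


@dataclass(frozen=True)
class ModelConfig:
    """Global simulation settings (cycle structure, discounting, WTP)."""

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    days_per_year: float = 365.25
    annual_discount: float = 0.03
    wtp: float = 100_000.0
    half_cycle: str = "standard"

    def __post_init__(self):
        if not 0.0 <= self.annual_discount < 1.0:
            raise ValueError("annual_discount must lie in [0, 1)")
        if self.wtp <= 0:
            raise ValueError("wtp must be positive")
        if self.half_cycle not in ("standard", "none"):
            raise ValueError("half_cycle must be 'standard' or 'none'")

    @property
    def n_cycles(self) -> int:
        return int(np.ceil(self.horizon_years * self.days_per_year / self.cycle_length_days))

    @property
    def cycles_per_year(self) -> float:
        return self.days_per_year / self.cycle_length_days

    @property
    def year_fraction(self) -> float:
        """Years represented by one cycle."""
        return self.cycle_length_days / self.days_per_year


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state membership fractions (rows 0..n_cycles)."""

    pfs: np.ndarray
    ps: np.ndarray
    dead: np.ndarray

    def __post_init__(self):
        rows = self.pfs + self.ps + self.dead
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("trace rows must sum to 1")

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.ps

    @property
    def new_deaths(self) -> np.ndarray:
        """Fraction newly dead during cycle k (length n_cycles)."""
        return np.diff(self.dead)

    @property
    def n_cycles(self) -> int:
        return self.pfs.size - 1

    def to_frame(self, cfg: ModelConfig) -> pd.DataFrame:
        k = np.arange(self.pfs.size)
        return pd.DataFrame(
            {
                "cycle": k,
                "t_years": k * cfg.year_fraction,
                "pfs": self.pfs,
                "ps": self.ps,
                "dead": self.dead,
                "new_deaths": np.concatenate([[0.0], self.new_deaths]),
                "discount_factor": discount_factors(cfg),
            }
        )


def discount_factor(cycle: int, cfg: ModelConfig) -> float:
    """(1 + r)^(-t) with t the cycle-start time in years."""
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    return float((1.0 + cfg.annual_discount) ** (-cycle * cfg.year_fraction))


def discount_factors(cfg: ModelConfig) -> np.ndarray:
    k = np.arange(cfg.n_cycles + 1)
    return (1.0 + cfg.annual_discount) ** (-k * cfg.year_fraction)


def run_cohort(sp_os: SurvivalParams, sp_pfs: SurvivalParams, cfg: ModelConfig) -> CohortTrace:
    """Propagate the cohort over the full horizon.

    Transition probabilities are time-dependent conditional survival ratios;
    the same OS-law death probability applies to both alive states.
    """
    n = cfg.n_cycles
    t = np.arange(n + 1, dtype=float)
    s_os = survival_probability(sp_os, t)
    s_pfs = survival_probability(sp_pfs, t)

    pfs = np.zeros(n + 1)
    ps = np.zeros(n + 1)
    dead = np.zeros(n + 1)
    pfs[0] = 1.0
    for k in range(1, n + 1):
        die = 1.0 - s_os[k] / s_os[k - 1] if s_os[k - 1] > 0.0 else 1.0
        # a fully depleted PFS curve (numeric underflow) carries no stayers
        ratio = s_pfs[k] / s_pfs[k - 1] if s_pfs[k - 1] > 0.0 else 0.0
        progress = min(max(1.0 - die - ratio, 0.0), 1.0 - die)
        stay = 1.0 - die - progress
        if not (0.0 <= die <= 1.0 and 0.0 <= progress <= 1.0 and 0.0 <= stay <= 1.0):
            raise ArithmeticError(f"invalid transition probability at cycle {k}")
        pfs[k] = pfs[k - 1] * stay
        ps[k] = ps[k - 1] * (1.0 - die) + pfs[k - 1] * progress
        dead[k] = dead[k - 1] + (pfs[k - 1] + ps[k - 1]) * die
    return CohortTrace(pfs=pfs, ps=ps, dead=dead)


def cycle_weights(rows: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Per-cycle accrual weights for a per-row (cycle-boundary) quantity.

    Returns a length-``n_cycles`` vector whose k-th entry is the occupancy
    credited to cycle k+1: the mean of the flanking rows under the standard
    half-cycle correction, or the start-of-cycle row under ``"none"``.
    """
    rows = np.asarray(rows, dtype=float)
    if cfg.half_cycle == "standard":
        return 0.5 * (rows[:-1] + rows[1:])
    return rows[:-1].copy()


class LifeYears(NamedTuple):
    total: float
    pfs: float
    ps: float


def life_years(trace: CohortTrace, cfg: ModelConfig, discounted: bool = True) -> LifeYears:
    """(Discounted) life-years overall and split by state.

    The discount factor is folded into the occupancy rows before the
    half-cycle averaging, so utility-weighted accruals reduce to this
    quantity exactly when all utilities are 1.
    """
    disc = discount_factors(cfg) if discounted else np.ones(trace.pfs.size)
    yf = cfg.year_fraction
    pfs_ly = float(np.sum(cycle_weights(trace.pfs * disc, cfg)) * yf)
    ps_ly = float(np.sum(cycle_weights(trace.ps * disc, cfg)) * yf)
    return LifeYears(pfs_ly + ps_ly, pfs_ly, ps_ly)
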