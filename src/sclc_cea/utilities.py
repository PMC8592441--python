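"""Time-to-death utilities and QALY accumulation.

Health-state utilities are assigned by proximity to death rather than by
disease state: cohort members more than 12 months from death carry the
highest utility, those within a month of death the lowest. The four band
values come from EQ-5D measurements in a pembrolizumab-chemotherapy trial
population.

Two cohort-level weightings of the bands are provided:

``baseline`` (default)
    Band masses are read off the arm's fitted overall-survival curve at
    fixed offsets from the current cycle, ``S(t + a) - S(t + b)``, without
    renormalizing by the fraction still alive; the mass of deaths already
    accrued by ``t + a`` falls into the nearest-to-death band. The weights
    still sum to one. This is the reading that reproduces the published
    base-case QALYs of the analysis this package re-implements.

``conditional``
    Proper conditional band probabilities ``[S(t+a) - S(t+b)] / S(t)``
    given survival to ``t`` (a partition of the conditional event space).
    Probabilistically self-consistent; yields systematically higher QALYs
    than the published table (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .markov import CohortTrace, ModelConfig, cycle_weights, discount_factors
from .survival import SurvivalParams, survival_probability

#: Band order used throughout: nearest to death first.
BAND_NAMES = ("le1m", "m1_6", "m6_12", "gt12m")


@dataclass(frozen=True)
class UtilityBands:
    """Utilities by time prior to death, with band edges in months."""

    le1m: float = 0.563
    m1_6: float = 0.709
    m6_12: float = 0.765
    gt12m: float = 0.834
    edges_months: tuple = (1.0, 6.0, 12.0)

    def __post_init__(self):
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValueError("utilities must lie in [0, 1]")
        if list(self.edges_months) != sorted(self.edges_months) or self.edges_months[0] <= 0:
            raise ValueError("band edges must be positive and increasing")

    @property
    def values(self) -> tuple:
        return (self.le1m, self.m1_6, self.m6_12, self.gt12m)

    @property
    def ordered(self) -> bool:
        """True when utility is non-increasing as death approaches.

        Base-case inputs are required to be ordered; jointly sampled
        sensitivity-analysis draws may transiently cross."""
        v = self.values
        return all(v[i] <= v[i + 1] for i in range(3))


def _edge_offsets_cycles(bands: UtilityBands, cfg: ModelConfig) -> np.ndarray:
    month_cycles = (cfg.days_per_year / 12.0) / cfg.cycle_length_days
    return np.asarray(bands.edges_months, dtype=float) * month_cycles


def _band_masses(sp_os: SurvivalParams, t, bands: UtilityBands, cfg: ModelConfig) -> np.ndarray:
    """Unconditional masses (..., 4): [<=1m incl. prior deaths, 1-6m, 6-12m, >12m]."""
    t = np.asarray(t, dtype=float)
    a1, a6, a12 = (survival_probability(sp_os, t + e) for e in _edge_offsets_cycles(bands, cfg))
    return np.stack([1.0 - a1, a1 - a6, a6 - a12, a12], axis=-1)


def band_probabilities(
    sp_os: SurvivalParams, t, bands: UtilityBands, cfg: ModelConfig
) -> np.ndarray:
    """P(death occurs in each time-to-death band | alive at cycle t).

    Returns the four probabilities in :data:`BAND_NAMES` order; they sum
    to one. Requires S(t) > 0.
    """
    s0 = survival_probability(sp_os, t)
    if np.any(np.asarray(s0) <= 0.0):
        raise ValueError("band probabilities undefined where S(t) = 0")
    masses = _band_masses(sp_os, t, bands, cfg)
    cond = masses / np.asarray(s0)[..., None]
    cond[..., 0] -= (1.0 - np.asarray(s0)) / np.asarray(s0)  # deaths before t are excluded
    return cond


def expected_utility(
    sp_os: SurvivalParams,
    t,
    bands: UtilityBands,
    cfg: ModelConfig,
    weighting: str = "baseline",
) -> float | np.ndarray:
    """Band-weighted utility at cycle t under the chosen weighting."""
    u = np.asarray(bands.values)
    if weighting == "conditional":
        w = band_probabilities(sp_os, t, bands, cfg)
    elif weighting == "baseline":
        w = _band_masses(sp_os, t, bands, cfg)
    else:
        raise ValueError("weighting must be 'baseline' or 'conditional'")
    out = w @ u
    return float(out) if out.ndim == 0 else out


def utility_curve(
    sp_os: SurvivalParams, bands: UtilityBands, cfg: ModelConfig, weighting: str = "baseline"
) -> np.ndarray:
    """Per-cycle-boundary utility values over the model horizon (length n_cycles+1)."""
    t = np.arange(cfg.n_cycles + 1, dtype=float)
    return np.asarray(expected_utility(sp_os, t, bands, cfg, weighting))


class Qalys(NamedTuple):
    total: float
    pfs: float
    ps: float


def qalys(
    trace: CohortTrace,
    sp_os: SurvivalParams,
    bands: UtilityBands,
    cfg: ModelConfig,
    weighting: str = "baseline",
    discounted: bool = True,
) -> Qalys:
    """Discounted quality-adjusted life-years, total and split by state.

    Each cycle contributes occupancy x utility x year-fraction x discount,
    with the same accrual convention (half-cycle by default) as life-years.
    The utility applies identically in PFS and PS — the state-wise split
    reflects occupancy only.
    """
    u = utility_curve(sp_os, bands, cfg, weighting)
    disc = discount_factors(cfg) if discounted else np.ones(cfg.n_cycles + 1)
    yf = cfg.year_fraction
    q_pfs = float(np.sum(cycle_weights(trace.pfs * u * disc, cfg)) * yf)
    q_ps = float(np.sum(cycle_weights(trace.ps * u * disc, cfg)) * yf)
    return Qalys(q_pfs + q_ps, q_pfs, q_ps)
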