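"""Per-cycle and one-off cost assembly for the two treatment arms.

Cost categories mirror the base-case table of the analysis: first- and
second-line drug acquisition, a per-arm drug administration / first-line
adverse-event management bundle, first- and second-line adverse-event
management, outpatient follow-up visits, supportive care for progressed
patients without subsequent therapy, and a one-off terminal-care cost.

Doses are computed for a reference patient (weight, body-surface area,
creatinine clearance); carboplatin uses the Calvert formula
``dose = AUC x (CrCl + 25)``. Prices are linear per mg (average sales
price), with no vial rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .markov import CohortTrace, ModelConfig, cycle_weights, discount_factors

CATEGORIES = (
    "first_line_acquisition",
    "second_line_acquisition",
    "drug_administration",
    "ae_first_line",
    "ae_second_line",
    "followup_visit",
    "supportive_care",
    "death",
)


@dataclass(frozen=True)
class PatientProfile:
    weight_kg: float = 70.32
    bsa_m2: float = 1.79
    crcl_ml_min: float = 70.0

    def __post_init__(self):
        if min(self.weight_kg, self.bsa_m2, self.crcl_ml_min) <= 0:
            raise ValueError("patient measurements must be positive")


class DoseKind(str, Enum):
    FIXED_MG = "fixed_mg"
    PER_M2 = "per_m2"
    PER_KG = "per_kg"
    AUC_CALVERT = "auc_calvert"


@dataclass(frozen=True)
class DoseRule:
    kind: DoseKind
    amount: float  # mg, mg/m2, mg/kg or target AUC
    days_per_cycle: int = 1

    def __post_init__(self):
        object.__setattr__(self, "kind", DoseKind(self.kind))
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.days_per_cycle < 1:
            raise ValueError("days_per_cycle must be at least 1")


@dataclass(frozen=True)
class RegimenComponent:
    drug: str
    rule: DoseRule
    weight: float = 1.0  # fraction of patients receiving this component
    max_cycles: int | None = None


@dataclass(frozen=True)
class Regimen:
    name: str
    components: tuple[RegimenComponent, ...]


def compute_dose(rule: DoseRule, profile: PatientProfile) -> float:
    """mg per administration under the dosing rule."""
    if rule.kind is DoseKind.FIXED_MG:
        return rule.amount
    if rule.kind is DoseKind.PER_M2:
        return rule.amount * profile.bsa_m2
    if rule.kind is DoseKind.PER_KG:
        return rule.amount * profile.weight_kg
    if rule.kind is DoseKind.AUC_CALVERT:
        return rule.amount * (profile.crcl_ml_min + 25.0)
    raise ValueError(f"unknown dose kind {rule.kind!r}")


def cycle_drug_cost(
    regimen: Regimen,
    prices: Mapping[str, float],
    profile: PatientProfile,
    component_filter=None,
) -> float:
    """USD drug-acquisition cost of one cycle of a regimen.

    Component weights implement share-weighted alternatives (e.g. the
    carboplatin / cisplatin split of the platinum backbone).
    """
    total = 0.0
    for comp in regimen.components:
        if component_filter is not None and not component_filter(comp):
            continue
        if comp.drug not in prices:
            raise KeyError(f"no unit price for drug {comp.drug!r}")
        dose = compute_dose(comp.rule, profile)
        total += comp.weight * dose * comp.rule.days_per_cycle * prices[comp.drug]
    return total


@dataclass
class CostStreams:
    """Undiscounted per-cycle cost accruals by category.

    Each vector has length ``n_cycles + 1``; entry 0 holds one-off costs
    incurred at model entry and entry k >= 1 the (occupancy-weighted)
    accrual during cycle k.
    """

    streams: dict = field(default_factory=dict)

    def add(self, category: str, vec: np.ndarray):
        if category not in CATEGORIES:
            raise ValueError(f"unknown cost category {category!r}")
        cur = self.streams.setdefault(category, np.zeros_like(vec))
        self.streams[category] = cur + vec


def first_line_cost_stream(
    trace: CohortTrace,
    regimen: Regimen,
    prices: Mapping[str, float],
    profile: PatientProfile,
    cfg: ModelConfig,
    admin_bundle: float,
    ae_first_line: float,
    pembro_policy: str = "pfs_occupancy_max35",
    pembro_median_cycles: int = 7,
) -> CostStreams:
    """First-line acquisition plus the per-arm administration and AE bundles.

    Each regimen component accrues its per-cycle cost over progression-free
    occupancy for its first ``max_cycles`` cycles. Under the default
    duration policy pembrolizumab is costed while progression-free up to its
    35-dose cap; ``fixed_median7`` caps it at the trial's median of 7 cycles
    instead.
    """
    n = cfg.n_cycles
    occ = cycle_weights(trace.pfs, cfg)
    acq = np.zeros(n + 1)
    for comp in regimen.components:
        cap = comp.max_cycles if comp.max_cycles is not None else n
        if comp.drug == "pembrolizumab":
            if pembro_policy == "fixed_median7":
                cap = min(cap, pembro_median_cycles)
            elif pembro_policy != "pfs_occupancy_max35":
                raise ValueError(f"unknown pembrolizumab duration policy {pembro_policy!r}")
        per_cycle = comp.weight * compute_dose(comp.rule, profile) * comp.rule.days_per_cycle * prices[comp.drug]
        acq[1 : cap + 1] += per_cycle * occ[:cap]
    out = CostStreams()
    out.add("first_line_acquisition", acq)
    oneoff_admin = np.zeros(n + 1)
    oneoff_admin[0] = admin_bundle
    out.add("drug_administration", oneoff_admin)
    oneoff_ae = np.zeros(n + 1)
    oneoff_ae[0] = ae_first_line
    out.add("ae_first_line", oneoff_ae)
    return out


def subsequent_regimen_cycle_cost(
    regimens: Sequence[tuple[float, Regimen, float]],
    prices: Mapping[str, float],
    profile: PatientProfile,
    infusion_first_hour: float,
    infusion_additional_hour: float,
) -> float:
    """Share-weighted per-cycle cost of the subsequent-therapy mix.

    ``regimens`` is a sequence of (share, regimen, infusion_hours) triples;
    administration is charged as a first infusion hour plus additional hours.
    """
    total = 0.0
    for share, reg, hours in regimens:
        admin = 0.0
        if hours > 0:
            admin = infusion_first_hour + max(hours - 1.0, 0.0) * infusion_additional_hour
        total += share * (cycle_drug_cost(reg, prices, profile) + admin)
    return total


def subsequent_and_other_cost_stream(
    trace: CohortTrace,
    cfg: ModelConfig,
    uptake: float,
    subsequent_drug_per_cycle: float,
    ae_second_line: float,
    outpatient_visit_per_cycle: float,
    supportive_care_per_month: float,
    death_cost: float,
) -> CostStreams:
    """Post-progression and disease-management costs.

    Progressed occupancy splits into a treated fraction (``uptake``)
    accruing subsequent-therapy drug acquisition per cycle, and an
    untreated fraction accruing supportive care. Outpatient visits accrue
    for every alive cycle; the terminal-care cost is charged once per new
    death. The per-arm second-line AE management total is a one-off input
    (its components are not published at unit level).
    """
    if not 0.0 <= uptake <= 1.0:
        raise ValueError("uptake must lie in [0, 1]")
    n = cfg.n_cycles
    ps_occ = cycle_weights(trace.ps, cfg)
    alive_occ = cycle_weights(trace.alive, cfg)
    out = CostStreams()

    acq2 = np.zeros(n + 1)
    acq2[1:] = subsequent_drug_per_cycle * uptake * ps_occ
    out.add("second_line_acquisition", acq2)

    ae2 = np.zeros(n + 1)
    ae2[0] = ae_second_line
    out.add("ae_second_line", ae2)

    visits = np.zeros(n + 1)
    visits[1:] = outpatient_visit_per_cycle * alive_occ
    out.add("followup_visit", visits)

    supp = np.zeros(n + 1)
    per_cycle = supportive_care_per_month * cfg.cycle_length_days / (cfg.days_per_year / 12.0)
    supp[1:] = per_cycle * (1.0 - uptake) * ps_occ
    out.add("supportive_care", supp)

    death = np.zeros(n + 1)
    death[1:] = death_cost * trace.new_deaths
    out.add("death", death)
    return out


def total_discounted_cost(
    streams: CostStreams, cfg: ModelConfig
) -> tuple[float, dict[str, float]]:
    """Discount and sum the streams; the breakdown sums to the total exactly."""
    disc = discount_factors(cfg)
    dw = np.concatenate([[1.0], cycle_weights(disc, cfg)])
    breakdown = {}
    for cat in CATEGORIES:
        vec = streams.streams.get(cat)
        if vec is None:
            continue
        if vec.size != cfg.n_cycles + 1:
            raise ValueError(f"stream {cat!r} not aligned to the model horizon")
        breakdown[cat] = float(vec @ dw)
    return sum(breakdown.values()), breakdown
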