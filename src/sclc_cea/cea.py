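"""Incremental cost-effectiveness statistics and sensitivity analyses.

The base case compares the two first-line arms on discounted cost, life-
years and QALYs and reports incremental ratios. One-way deterministic
sensitivity analysis (DSA) re-evaluates the model at each parameter's low
and high bound; probabilistic sensitivity analysis (PSA) jointly samples
all parameters with published second-order distributions and yields the
cost-effectiveness acceptability curve (CEAC). Price analyses search for
the pembrolizumab unit price consistent with a willingness-to-pay target.

Survival-law parameters are held fixed in the PSA (no sampling
distributions are published for them); the cohort traces therefore only
need to be built once per arm, and each PSA iteration reduces to cheap
re-weighting of precomputed occupancy aggregates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as cfgmod
from .costs import (
    CATEGORIES,
    compute_dose,
    cycle_weights,
    subsequent_regimen_cycle_cost,
)
from .markov import CohortTrace, LifeYears, discount_factors, run_cohort
from .utilities import Qalys, UtilityBands, _band_masses, band_probabilities

PEMBRO_PRICE_PATH = "costs.prices_per_mg.pembrolizumab"


@dataclass
class ArmResult:
    arm: str
    cost: float
    cost_breakdown: dict
    ly: LifeYears
    qaly: Qalys
    trace: CohortTrace | None = None


@dataclass
class CEAResult:
    intervention: ArmResult
    comparator: ArmResult
    d_cost: float = field(init=False)
    d_ly: float = field(init=False)
    d_qaly: float = field(init=False)

    def __post_init__(self):
        self.d_cost = self.intervention.cost - self.comparator.cost
        self.d_ly = self.intervention.ly.total - self.comparator.ly.total
        self.d_qaly = self.intervention.qaly.total - self.comparator.qaly.total

    @property
    def dominated(self) -> bool:
        """More costly and less effective."""
        return self.d_cost > 0 and self.d_qaly < 0

    @property
    def dominant(self) -> bool:
        """Less costly and more effective."""
        return self.d_cost < 0 and self.d_qaly > 0

    @property
    def icer_per_qaly(self) -> float | None:
        return None if self.d_qaly <= 0 else self.d_cost / self.d_qaly

    @property
    def icer_per_ly(self) -> float | None:
        return None if self.d_ly <= 0 else self.d_cost / self.d_ly


def compute_icer(comparator: ArmResult, intervention: ArmResult) -> CEAResult:
    return CEAResult(intervention=intervention, comparator=comparator)


def net_monetary_benefit(result: CEAResult | tuple[float, float], wtp: float) -> float:
    """Incremental net monetary benefit dE * wtp - dC at the given WTP."""
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    if isinstance(result, CEAResult):
        d_cost, d_qaly = result.d_cost, result.d_qaly
    else:
        d_cost, d_qaly = result
    return d_qaly * wtp - d_cost


# ---------------------------------------------------------------------------
# Fast evaluation basis: everything that depends on the survival laws only


@dataclass
class _ArmBasis:
    arm: str
    trace: CohortTrace
    cw_pfs_cum: np.ndarray  # cumulative discounted PFS occupancy by cycle cap
    cw_ps_sum: float
    cw_alive_sum: float
    deaths_disc: float
    band_accrual_pfs: np.ndarray  # (4,) discounted year-weighted band-mass occupancy
    band_accrual_ps: np.ndarray
    cond_band_accrual_pfs: np.ndarray
    cond_band_accrual_ps: np.ndarray


def _arm_basis(cfg: dict, arm: str) -> _ArmBasis:
    mc = cfgmod.model_config(cfg)
    sp_os = cfgmod.survival_params(cfg, arm, "os")
    sp_pfs = cfgmod.survival_params(cfg, arm, "pfs")
    trace = run_cohort(sp_os, sp_pfs, mc)
    disc = discount_factors(mc)
    dw = cycle_weights(disc, mc)
    cw_pfs = cycle_weights(trace.pfs * disc, mc)
    cw_ps = cycle_weights(trace.ps * disc, mc)
    cw_alive = cycle_weights(trace.alive * disc, mc)
    bands = cfgmod.utility_bands(cfg)  # edges fixed; band *values* sampled later
    t = np.arange(mc.n_cycles + 1, dtype=float)
    masses = _band_masses(sp_os, t, bands, mc)  # (n+1, 4)
    yf = mc.year_fraction
    acc = {}
    for weighting in ("baseline", "conditional"):
        if weighting == "conditional":
            s0 = trace.pfs + trace.ps  # equals S_os by the telescoping identity
            w = band_probabilities(sp_os, t, bands, mc) if np.all(s0 > 0) else masses
        else:
            w = masses
        for state, occ in (("pfs", trace.pfs), ("ps", trace.ps)):
            rows = occ[:, None] * w * disc[:, None]
            acc[(weighting, state)] = 0.5 * (rows[:-1] + rows[1:]).sum(axis=0) * yf \
                if mc.half_cycle == "standard" else rows[:-1].sum(axis=0) * yf
    return _ArmBasis(
        arm=arm,
        trace=trace,
        cw_pfs_cum=np.concatenate([[0.0], np.cumsum(cw_pfs)]),
        cw_ps_sum=float(cw_ps.sum()),
        cw_alive_sum=float(cw_alive.sum()),
        deaths_disc=float(trace.new_deaths @ dw),
        band_accrual_pfs=acc[("baseline", "pfs")],
        band_accrual_ps=acc[("baseline", "ps")],
        cond_band_accrual_pfs=acc[("conditional", "pfs")],
        cond_band_accrual_ps=acc[("conditional", "ps")],
    )


def _evaluate_with_basis(cfg: dict, basis: _ArmBasis) -> ArmResult:
    mc = cfgmod.model_config(cfg)
    arm = basis.arm
    costs = cfg["costs"]
    prices = costs["prices_per_mg"]
    profile = cfgmod.patient_profile(cfg)
    regimen = cfgmod.first_line_regimen(cfg, arm)
    n = mc.n_cycles

    breakdown = dict.fromkeys(CATEGORIES, 0.0)
    for comp in regimen.components:
        cap = comp.max_cycles if comp.max_cycles is not None else n
        if comp.drug == "pembrolizumab" and costs["pembro_duration_policy"] == "fixed_median7":
            cap = min(cap, int(costs["pembro_median_cycles"]))
        per_cycle = (
            comp.weight
            * compute_dose(comp.rule, profile)
            * comp.rule.days_per_cycle
            * prices[comp.drug]
        )
        breakdown["first_line_acquisition"] += per_cycle * basis.cw_pfs_cum[min(cap, n)]
    breakdown["drug_administration"] = costs["admin_bundle"][arm]
    breakdown["ae_first_line"] = costs["ae_first_line"][arm]
    breakdown["ae_second_line"] = (
        costs["subsequent_bundle"][arm] * costs["ae_second_line_multiplier"][arm]
    )
    uptake = costs["subsequent_uptake"][arm]
    if costs["subsequent_drug_mode"] == "nccn":
        rate = subsequent_regimen_cycle_cost(
            cfgmod.subsequent_regimens(cfg),
            prices,
            profile,
            costs["infusion_first_hour"],
            costs["infusion_additional_hour"],
        )
    else:
        rate = costs["subsequent_drug_per_cycle"][arm]
    breakdown["second_line_acquisition"] = rate * uptake * basis.cw_ps_sum
    breakdown["followup_visit"] = costs["outpatient_visit_per_cycle"] * basis.cw_alive_sum
    per_cycle_supportive = (
        costs["supportive_care_per_month"] * mc.cycle_length_days / (mc.days_per_year / 12.0)
    )
    breakdown["supportive_care"] = per_cycle_supportive * (1.0 - uptake) * basis.cw_ps_sum
    breakdown["death"] = costs["death_cost"] * basis.deaths_disc

    bands = cfgmod.utility_bands(cfg)
    u = np.asarray(bands.values)
    if cfg["model"]["utility_weighting"] == "conditional":
        q_pfs = float(basis.cond_band_accrual_pfs @ u)
        q_ps = float(basis.cond_band_accrual_ps @ u)
    else:
        q_pfs = float(basis.band_accrual_pfs @ u)
        q_ps = float(basis.band_accrual_ps @ u)

    from .markov import life_years

    ly = life_years(basis.trace, mc)
    return ArmResult(
        arm=arm,
        cost=float(sum(breakdown.values())),
        cost_breakdown=breakdown,
        ly=ly,
        qaly=Qalys(q_pfs + q_ps, q_pfs, q_ps),
        trace=basis.trace,
    )


def evaluate_arm(cfg: dict, arm: str, basis: _ArmBasis | None = None) -> ArmResult:
    """Full evaluation of one arm: trace, discounted LYs/QALYs and costs."""
    if basis is None:
        basis = _arm_basis(cfg, arm)
    return _evaluate_with_basis(cfg, basis)


def evaluate(cfg: dict, bases: dict | None = None) -> CEAResult:
    """Evaluate both arms under one configuration and form the increments."""
    comp_arm = cfg["comparison"]["comparator"]
    int_arm = cfg["comparison"]["intervention"]
    if bases is None:
        bases = {}
    comparator = evaluate_arm(cfg, comp_arm, bases.get(comp_arm))
    intervention = evaluate_arm(cfg, int_arm, bases.get(int_arm))
    return compute_icer(comparator, intervention)


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis


def run_dsa(cfg: dict, ranges: dict | None = None) -> pd.DataFrame:
    """One-way DSA: re-run the full model at each parameter bound.

    Returns tornado rows (parameter, low/high bound, ICER at each bound,
    spread) sorted by descending spread. Bounds that break the model are
    flagged rather than raised.
    """
    if ranges is None:
        ranges = cfg["dsa"]["ranges"]
    base = evaluate(cfg)
    rows = []
    for path, (low, high) in ranges.items():
        icers = {}
        ok = True
        for label, bound in (("low", low), ("high", high)):
            try:
                res = evaluate(cfgmod.with_param(cfg, path, bound))
                icers[label] = res.icer_per_qaly
                if icers[label] is None:
                    ok = False
            except (ValueError, ArithmeticError):
                icers[label] = np.nan
                ok = False
        spread = abs(icers["high"] - icers["low"]) if ok else np.nan
        rows.append(
            {
                "parameter": path,
                "low": low,
                "high": high,
                "icer_low": icers["low"] if icers["low"] is not None else np.nan,
                "icer_high": icers["high"] if icers["high"] is not None else np.nan,
                "spread": spread,
                "valid": ok,
            }
        )
    out = pd.DataFrame(rows).sort_values("spread", ascending=False, ignore_index=True)
    out.attrs["base_icer"] = base.icer_per_qaly
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


def sample_parameters(cfg: dict, n_iter: int, rng: np.random.Generator) -> pd.DataFrame:
    """Joint independent draws of every PSA parameter.

    Gamma parameters use (shape, rate) with rate defaulting to
    shape / base-value so the distribution mean equals the base case; beta
    parameters analogously derive b from the shape a and the base mean.
    """
    cols = {}
    for path, dist in cfg["psa"]["distributions"].items():
        base = cfgmod.get_param(cfg, path)
        shape = dist["shape"]
        if dist["family"] == "gamma":
            rate = dist.get("rate") or (shape / base if base > 0 else None)
            if rate is None:  # zero-price parameter: keep degenerate at base
                cols[path] = np.full(n_iter, base)
            else:
                cols[path] = rng.gamma(shape, 1.0 / rate, size=n_iter)
        else:
            b = dist.get("b") or shape * (1.0 - base) / base
            cols[path] = rng.beta(shape, b, size=n_iter)
    return pd.DataFrame(cols)


def run_psa(
    cfg: dict,
    n_iter: int | None = None,
    seed: int = 0,
    params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Monte-Carlo PSA: n_iter full model evaluations under joint draws.

    Returns one row per iteration with the sampled parameter values and
    per-arm discounted costs and QALYs plus the increments. The seed is
    recorded in ``DataFrame.attrs``; a fixed seed reproduces the draws
    bit-for-bit.
    """
    if n_iter is None:
        n_iter = int(cfg["psa"]["n_iterations"])
    rng = np.random.default_rng(seed)
    if params is None:
        params = sample_parameters(cfg, n_iter, rng)
    bases = {arm: _arm_basis(cfg, arm) for arm in cfgmod.ARMS}
    int_arm = cfg["comparison"]["intervention"]
    comp_arm = cfg["comparison"]["comparator"]
    work = copy.deepcopy(cfg)
    records = []
    for i in range(len(params)):
        for path in params.columns:
            cfgmod.set_param(work, path, float(params.iloc[i][path]))
        res = evaluate(work, bases=bases)
        records.append(
            {
                f"cost_{int_arm}": res.intervention.cost,
                f"qaly_{int_arm}": res.intervention.qaly.total,
                f"cost_{comp_arm}": res.comparator.cost,
                f"qaly_{comp_arm}": res.comparator.qaly.total,
                "d_cost": res.d_cost,
                "d_qaly": res.d_qaly,
            }
        )
    out = pd.concat([params.reset_index(drop=True), pd.DataFrame(records)], axis=1)
    out.attrs["seed"] = seed
    return out


def ce_probability(draws: pd.DataFrame, wtp: float) -> float:
    """Fraction of PSA draws with strictly positive incremental NMB."""
    return float(np.mean(draws["d_qaly"].to_numpy() * wtp - draws["d_cost"].to_numpy() > 0))


def ceac(draws: pd.DataFrame, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if len(draws) == 0:
        raise ValueError("no PSA draws supplied")
    if wtp_grid is None:
        wtp_grid = np.arange(0, 400_001, 5_000)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = draws["d_qaly"].to_numpy()[:, None]
    dc = draws["d_cost"].to_numpy()[:, None]
    prob = np.mean(dq * wtp_grid[None, :] - dc > 0, axis=0)
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})


def ceac_crossing(curve: pd.DataFrame, level: float = 0.5) -> float | None:
    """Smallest grid WTP at which the CEAC reaches the given level."""
    hit = curve.loc[curve["probability"] >= level, "wtp"]
    return None if hit.empty else float(hit.iloc[0])


# ---------------------------------------------------------------------------
# Pembrolizumab price analyses


@dataclass
class PriceThreshold:
    price: float
    pct_reduction: float
    base_price: float
    target_wtp: float


def price_threshold(cfg: dict, target_wtp: float | None = None, tol: float = 100.0) -> PriceThreshold:
    """Pembrolizumab unit price at which the base-case ICER meets the WTP.

    Bisects on the price until the deterministic ICER is within ``tol``
    USD/QALY of the target. If the ICER at the full price is already below
    the target, a zero reduction is returned.
    """
    from scipy import optimize

    mc = cfgmod.model_config(cfg)
    if target_wtp is None:
        target_wtp = mc.wtp
    base_price = cfgmod.get_param(cfg, PEMBRO_PRICE_PATH)
    bases = {arm: _arm_basis(cfg, arm) for arm in cfgmod.ARMS}

    def icer_at(price: float) -> float:
        res = evaluate(cfgmod.with_param(cfg, PEMBRO_PRICE_PATH, price), bases=bases)
        icer = res.icer_per_qaly
        return np.inf if icer is None else icer

    if icer_at(base_price) <= target_wtp:
        return PriceThreshold(base_price, 0.0, base_price, target_wtp)
    if icer_at(0.0) > target_wtp:
        raise ValueError("ICER exceeds the target even at a zero pembrolizumab price")
    price = optimize.brentq(lambda p: icer_at(p) - target_wtp, 0.0, base_price, xtol=1e-6)
    # honour the ICER-scale tolerance contract
    assert abs(icer_at(price) - target_wtp) <= tol
    return PriceThreshold(price, 100.0 * (1.0 - price / base_price), base_price, target_wtp)


def psa_price_sweep(
    cfg: dict,
    price_grid,
    wtp: float | None = None,
    n_iter: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """PSA cost-effectiveness probability across pembrolizumab prices.

    The price's sampling distribution mean is rescaled to each grid price
    (the sampler centres on the configured base value); common random
    numbers are used across grid points.
    """
    mc = cfgmod.model_config(cfg)
    if wtp is None:
        wtp = mc.wtp
    rows = []
    for price in np.asarray(price_grid, dtype=float):
        sub = cfgmod.with_param(cfg, PEMBRO_PRICE_PATH, float(price))
        draws = run_psa(sub, n_iter=n_iter, seed=seed)
        rows.append({"price": float(price), "probability": ce_probability(draws, wtp)})
    return pd.DataFrame(rows)
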