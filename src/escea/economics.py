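"""Costing and utility accumulation over a cohort trace.

Cost components: first-line drug acquisition (anthropometric dosing with
per-kg, per-BSA, Calvert AUC or flat rules), one-off grade 3/4 adverse-event
management at model entry, per-cycle routine follow-up and best supportive
care while progression-free, per-cycle subsequent anticancer therapy and BSC
after progression, and a one-off palliative-care cost at death.  Health
outcomes are quality-adjusted life-years using state utilities (progression-
free vs progressed) minus a one-off frequency-weighted AE disutility.

Both costs and QALYs are discounted at an annual rate applied continuously
per cycle, d_k = (1 + r)^(-k * L / 365.25) for cycle length L days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .markov import DAYS_PER_YEAR, CohortTrace, CycleGrid
from .survival import HazardRatio

__all__ = [
    "Population",
    "DosingRule",
    "AEItem",
    "UtilitySet",
    "EconSettings",
    "CEResult",
    "calvert_dose",
    "drug_cost_per_cycle",
    "ae_burden",
    "discount_factor",
    "accumulate",
]


@dataclass(frozen=True)
class Population:
    """Anthropometrics of the modelled cohort (Chinese ES-SCLC patients)."""

    weight_male_kg: float = 69.6
    weight_female_kg: float = 59.0
    prop_male: float = 0.5
    bsa_m2: float = 1.72
    crcl_ml_min: float = 70.0

    def __post_init__(self) -> None:
        if min(self.weight_male_kg, self.weight_female_kg, self.bsa_m2) <= 0:
            raise ValueError("anthropometrics must be positive")
        if self.crcl_ml_min < 0:
            raise ValueError("creatinine clearance must be non-negative")
        if not 0.0 <= self.prop_male <= 1.0:
            raise ValueError("prop_male must lie in [0, 1]")

    @property
    def mean_weight_kg(self) -> float:
        return self.prop_male * self.weight_male_kg + (1 - self.prop_male) * self.weight_female_kg


@dataclass(frozen=True)
class DosingRule:
    """Per-cycle dosing and price for one drug.

    ``dose_value`` is interpreted by ``basis``: mg/kg (per_kg), mg/m^2
    (per_bsa), a carboplatin AUC target (auc_calvert), or total mg (flat).
    ``price_per_pack`` is USD per pack of ``pack_size_mg``; by default exact
    milligrams are billed (no vial wastage); ``ceil_to_pack=True`` rounds
    each administration up to whole packs.
    """

    drug: str
    basis: str
    dose_value: float
    price_per_pack: float
    pack_size_mg: float
    max_cycles: int | None = None  # None = until progression
    phase: str = "until_progression"
    ceil_to_pack: bool = False

    def __post_init__(self) -> None:
        if self.basis not in ("per_kg", "per_bsa", "auc_calvert", "flat"):
            raise ValueError(f"unknown dosing basis {self.basis!r}")
        if self.phase not in ("induction_only", "until_progression"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.dose_value <= 0:
            raise ValueError("dose_value must be positive")
        if self.price_per_pack < 0 or self.pack_size_mg <= 0:
            raise ValueError("invalid price or pack size")
        if self.phase == "induction_only" and self.max_cycles is None:
            raise ValueError("induction_only rules need max_cycles")


@dataclass(frozen=True)
class AEItem:
    """One grade 3/4 adverse event: frequency under chemotherapy, episode
    management cost, utility decrement and duration."""

    name: str
    freq_chemo: float
    unit_cost: float
    disutility: float
    duration_days: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq_chemo <= 1.0:
            raise ValueError("AE frequency must lie in [0, 1]")
        if not 0.0 <= self.disutility <= 1.0:
            raise ValueError("disutility must lie in [0, 1]")
        if self.unit_cost < 0 or self.duration_days < 0:
            raise ValueError("cost and duration must be non-negative")


@dataclass(frozen=True)
class UtilitySet:
    u_pfd: float = 0.856
    u_pd: float = 0.768

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_pd <= self.u_pfd <= 1.0:
            raise ValueError("require 0 <= u_pd <= u_pfd <= 1")


@dataclass(frozen=True)
class EconSettings:
    """Discounting, thresholds and non-drug cost inputs (USD)."""

    discount_rate_annual: float = 0.05
    wtp_low: float = 15217.00
    wtp_high: float = 38042.49
    cny_per_usd: float = 7.0467
    palliative_cost: float = 0.0  # one-off at death
    followup_cost_per_cycle: float = 0.0  # PFD state
    bsc_cost_per_cycle: float = 0.0  # PFD and PD states
    subsequent_cost_per_cycle: float = 0.0  # PD state

    def __post_init__(self) -> None:
        if self.discount_rate_annual < 0:
            raise ValueError("discount rate must be non-negative")
        for name in ("palliative_cost", "followup_cost_per_cycle",
                     "bsc_cost_per_cycle", "subsequent_cost_per_cycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def usd(self, cny: float) -> float:
        """Convert a CNY amount to USD at the fixed exchange rate."""
        return cny / self.cny_per_usd


@dataclass(frozen=True)
class CEResult:
    """Discounted totals for one strategy."""

    strategy: str
    total_cost: float
    total_qalys: float
    total_lys: float | None = None

    def __post_init__(self) -> None:
        if self.total_cost < 0 or self.total_qalys < 0:
            raise ValueError("totals must be non-negative")
        if self.total_lys is not None and self.total_qalys > self.total_lys + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


# ---------------------------------------------------------------------------


def calvert_dose(auc: float, crcl_ml_min: float) -> float:
    """Carboplatin dose in mg: AUC * (CrCl + 25)."""
    if auc <= 0:
        raise ValueError("AUC target must be positive")
    if crcl_ml_min < 0:
        raise ValueError("creatinine clearance must be non-negative")
    return auc * (crcl_ml_min + 25.0)


def _dose_mg(rule: DosingRule, pop: Population) -> float:
    if rule.basis == "per_kg":
        return rule.dose_value * pop.mean_weight_kg
    if rule.basis == "per_bsa":
        return rule.dose_value * pop.bsa_m2
    if rule.basis == "auc_calvert":
        return calvert_dose(rule.dose_value, pop.crcl_ml_min)
    if rule.basis == "flat":
        return rule.dose_value
    raise ValueError(f"unknown dosing basis {rule.basis!r}")


def drug_cost_per_cycle(rules: Sequence[DosingRule], pop: Population, cycle: int) -> float:
    """USD drug acquisition cost for one cycle (0-based index)."""
    total = 0.0
    for rule in rules:
        if rule.max_cycles is not None and cycle >= rule.max_cycles:
            continue
        mg = _dose_mg(rule, pop)
        if rule.ceil_to_pack:
            total += np.ceil(mg / rule.pack_size_mg) * rule.price_per_pack
        else:
            total += mg / rule.pack_size_mg * rule.price_per_pack
    return float(total)


def drug_cost_vector(rules: Sequence[DosingRule], pop: Population, n_cycles: int) -> np.ndarray:
    """Per-cycle drug costs for cycles 0..n_cycles-1 (vectorised form of
    :func:`drug_cost_per_cycle`)."""
    out = np.zeros(n_cycles)
    for rule in rules:
        mg = _dose_mg(rule, pop)
        if rule.ceil_to_pack:
            cost = float(np.ceil(mg / rule.pack_size_mg) * rule.price_per_pack)
        else:
            cost = mg / rule.pack_size_mg * rule.price_per_pack
        stop = n_cycles if rule.max_cycles is None else min(rule.max_cycles, n_cycles)
        out[:stop] += cost
    return out


def ae_burden(items: Sequence[AEItem], hr_ae: HazardRatio | float = 1.0) -> tuple[float, float]:
    """One-off AE management cost and QALY loss.

    Frequencies observed under chemotherapy are scaled by the grade 3/4 AE
    hazard ratio of the strategy (capped at 1) and combined as
    frequency-weighted sums; the QALY loss weights each disutility by the
    event duration in years.
    """
    point = hr_ae.point if isinstance(hr_ae, HazardRatio) else float(hr_ae)
    if point <= 0:
        raise ValueError("AE hazard ratio must be positive")
    cost = 0.0
    qaly_loss = 0.0
    for item in items:
        f = min(1.0, item.freq_chemo * point)
        cost += f * item.unit_cost
        qaly_loss += f * item.disutility * item.duration_days / DAYS_PER_YEAR
    return cost, qaly_loss


def discount_factor(k, r: float, grid: CycleGrid | None = None):
    """Discount factor (1+r)^(-k*L/365.25) at cycle k (scalar or array)."""
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    grid = grid or CycleGrid()
    exponent = -np.asarray(k) * grid.cycle_length_days / DAYS_PER_YEAR
    out = (1.0 + r) ** exponent
    return float(out) if np.ndim(k) == 0 else out


def accumulate(
    trace: CohortTrace,
    drug_costs: Sequence[float] | np.ndarray,
    utilities: UtilitySet,
    settings: EconSettings,
    ae: tuple[float, float] = (0.0, 0.0),
    grid: CycleGrid | None = None,
    strategy: str = "",
) -> CEResult:
    """Discounted cost and QALY totals over the trace.

    ``drug_costs`` gives the per-cycle drug acquisition cost while
    progression-free (length n_cycles).  State occupancy is taken at cycle
    start (no half-cycle correction); the one-off AE burden from
    :func:`ae_burden` enters undiscounted at cycle 0.
    """
    grid = grid or CycleGrid()
    n = grid.n_cycles
    if trace.occupancy.shape[0] != n + 1:
        raise ValueError("trace length does not match the cycle grid")
    drug = np.asarray(drug_costs, dtype=float)
    if drug.shape != (n,):
        raise ValueError(f"drug_costs must have length {n}")

    pfd = trace.pfd[:n]
    pd_ = trace.pd_state[:n]
    newdeaths = np.diff(trace.dead)
    d = discount_factor(np.arange(n), settings.discount_rate_annual, grid)
    dt_years = grid.cycle_years

    ae_cost, ae_qaly_loss = ae
    cost = float(
        np.sum(
            d
            * (
                pfd * (drug + settings.followup_cost_per_cycle + settings.bsc_cost_per_cycle)
                + pd_ * (settings.subsequent_cost_per_cycle + settings.bsc_cost_per_cycle)
                + newdeaths * settings.palliative_cost
            )
        )
        + ae_cost
    )
    qalys = float(
        np.sum(d * dt_years * (pfd * utilities.u_pfd + pd_ * utilities.u_pd)) - ae_qaly_loss
    )
    lys = float(np.sum(dt_years * (pfd + pd_)))
    return CEResult(strategy=strategy, total_cost=cost, total_qalys=max(qalys, 0.0), total_lys=lys)
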