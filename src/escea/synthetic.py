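"""Synthetic inputs: simulated cohorts with known log-logistic parameters,
a digitizer stand-in, the published strategy-level (cost, QALY) table, and a
complete demonstration parameter workbook.

The demonstration workbook is a stand-in for the original model's input
tables, which are not publicly deposited: dosing schedules, prices,
adverse-event frequencies/costs and non-drug costs are synthetic but
realistic for Chinese oncology practice, while the constants that *are*
published (state utilities, anthropometrics, exchange rate, discount rate,
willingness-to-pay range, cycle length and horizon) are taken verbatim and
kept in a read-only registry so their provenance is machine-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np

from .economics import AEItem, CEResult, DosingRule, EconSettings, Population, UtilitySet
from .ipd import DigitizedKM, KMCurve, PseudoIPD, km_estimate
from .markov import CycleGrid
from .pipeline import StrategyDef, Workbook
from .survival import HazardRatio, ParametricSurvival

__all__ = [
    "PAPER_CONSTANTS",
    "TABLE1",
    "gen_ipd",
    "digitize",
    "table1_fixture",
    "demo_workbook",
    "SyntheticScenario",
]

#: Published constants (source-reported values, not tunable).
PAPER_CONSTANTS = MappingProxyType(
    {
        "u_pfd": 0.856,
        "u_pd": 0.768,
        "weight_male_kg": 69.6,
        "weight_female_kg": 59.0,
        "bsa_m2": 1.72,
        "crcl_ml_min": 70.0,
        "cny_per_usd": 7.0467,
        "discount_rate_annual": 0.05,
        "wtp_low": 15217.00,
        "wtp_high": 38042.49,
        "cycle_length_days": 21.0,
        "horizon_years": 20.0,
    }
)

#: Published base-case strategy totals: (strategy, discounted USD cost,
#: discounted QALYs).  Values immutable; chemotherapy is the cheapest.
TABLE1 = (
    ("chemotherapy", 21409.67, 1.02657),
    ("adebrelimab+chemotherapy", 60235.07, 1.33257),
    ("serplulimab+chemotherapy", 60519.52, 1.51286),
    ("atezolizumab+chemotherapy", 73236.05, 1.26971),
    ("durvalumab+chemotherapy", 90534.88, 1.28249),
    ("durvalumab+tremelimumab+chemotherapy", 155946.55, 1.19217),
)


def table1_fixture() -> list[CEResult]:
    """The six published (cost, QALY) pairs as CEResult records."""
    return [CEResult(strategy=n, total_cost=c, total_qalys=q) for n, c, q in TABLE1]


# ---------------------------------------------------------------------------
# cohort simulation


def gen_ipd(
    theta: float,
    kappa: float,
    n: int,
    censoring: tuple[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    arm_label: str = "synthetic",
    endpoint: str = "OS",
) -> PseudoIPD:
    """Simulate a right-censored cohort from the log-logistic model
    S(t) = 1/(1 + exp(theta) t^kappa) by inverse-CDF sampling.

    ``censoring`` is None (no censoring), ``("uniform", hi)`` for uniform
    censoring on (0, hi), or ``("admin", T)`` for administrative censoring
    at T.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if n < 1:
        raise ValueError("need n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)  # u = S(t)
    event_times = ((1.0 / u - 1.0) * np.exp(-theta)) ** (1.0 / kappa)
    if censoring is None:
        times, events = event_times, np.ones(n, dtype=int)
    else:
        kind, val = censoring
        if kind == "uniform":
            cens = rng.uniform(0.0, val, size=n)
        elif kind == "admin":
            cens = np.full(n, float(val))
        else:
            raise ValueError(f"unknown censoring scheme {kind!r}")
        events = (event_times <= cens).astype(int)
        times = np.minimum(event_times, cens)
    times = np.maximum(times, 1e-9)
    return PseudoIPD(times=times, events=events, arm_label=arm_label, endpoint=endpoint)


def digitize(
    ipd: PseudoIPD, grid: np.ndarray, arm_label: str | None = None
) -> DigitizedKM:
    """Stand-in for manual curve digitization: sample the cohort's KM curve
    at grid times and build the matching number-at-risk table."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
    max_follow = float(ipd.times.max())
    inside = grid <= max_follow
    if not np.all(inside):
        import warnings

        warnings.warn("digitization grid extends beyond follow-up; truncated")
        grid = grid[inside]
    curve = km_estimate(ipd)
    surv = curve.at(grid)
    points = [(0.0, 1.0)]
    last = 1.0
    for t, s in zip(grid[1:], surv[1:]):
        s = min(s, last)
        if s <= 0:
            break
        points.append((float(t), float(s)))
        last = s
    risk = [(float(t), int(np.sum(ipd.times >= t))) for t in grid[: len(points)]]
    return DigitizedKM(
        arm_label=arm_label or ipd.arm_label,
        endpoint=ipd.endpoint,
        points=tuple(points),
        risk_table=tuple(risk),
    )


# ---------------------------------------------------------------------------
# scenario / workbook


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully specified synthetic world for end-to-end exercises."""

    seed: int
    theta_pfs: float
    kappa_pfs: float
    theta_os: float
    kappa_os: float
    cohort_size: int
    censoring: tuple[str, float]
    workbook: Workbook

    def __post_init__(self) -> None:
        median_os = float(np.exp(-self.theta_os / self.kappa_os))
        if not 8.0 <= median_os <= 16.0:
            raise ValueError(
                f"chemotherapy OS median {median_os:.2f} months outside the "
                "plausible 8-16 month band"
            )


# Synthetic hazard ratios versus chemotherapy (point, 95% CI).  Orders of
# magnitude follow published first-line ES-SCLC immunochemotherapy trials;
# exact values are synthetic.
_STRATEGY_HRS = {
    "serplulimab+chemotherapy": {"pfs": (0.48, 0.39, 0.60), "os": (0.63, 0.49, 0.82), "ae": (1.05, 0.90, 1.25)},
    "adebrelimab+chemotherapy": {"pfs": (0.67, 0.54, 0.83), "os": (0.72, 0.58, 0.90), "ae": (1.03, 0.88, 1.20)},
    "atezolizumab+chemotherapy": {"pfs": (0.77, 0.62, 0.96), "os": (0.82, 0.64, 1.05), "ae": (1.10, 0.92, 1.32)},
    "durvalumab+chemotherapy": {"pfs": (0.80, 0.65, 0.99), "os": (0.75, 0.60, 0.94), "ae": (1.02, 0.86, 1.21)},
    "durvalumab+tremelimumab+chemotherapy": {"pfs": (0.84, 0.67, 1.05), "os": (0.82, 0.65, 1.03), "ae": (1.30, 1.05, 1.62)},
}

# Synthetic per-pack prices (USD) and pack sizes (mg).
_PRICES = {
    "etoposide": (4.0, 100.0),
    "carboplatin": (12.0, 450.0),
    "serplulimab": (820.0, 100.0),
    "adebrelimab": (790.0, 600.0),
    "atezolizumab": (4600.0, 1200.0),
    "durvalumab": (1750.0, 500.0),
    "tremelimumab": (5200.0, 300.0),
}

# Synthetic grade 3/4 adverse-event table for the chemotherapy backbone:
# (frequency, unit cost USD, disutility, duration days).
_AE_TABLE = (
    ("neutropenia", 0.36, 420.0, 0.090, 16.0),
    ("anemia", 0.21, 510.0, 0.073, 25.0),
    ("thrombocytopenia", 0.15, 690.0, 0.108, 20.0),
    ("leukopenia", 0.17, 380.0, 0.090, 14.0),
    ("nausea_vomiting", 0.05, 210.0, 0.048, 7.0),
    ("fatigue", 0.04, 150.0, 0.073, 21.0),
)


def _chemo_backbone(induction_cycles: int = 4) -> tuple[DosingRule, ...]:
    etop_price, etop_pack = _PRICES["etoposide"]
    carb_price, carb_pack = _PRICES["carboplatin"]
    return (
        # etoposide 100 mg/m^2 on days 1-3 -> 300 mg/m^2 per cycle
        DosingRule("etoposide", "per_bsa", 300.0, etop_price, etop_pack,
                   max_cycles=induction_cycles, phase="induction_only"),
        DosingRule("carboplatin", "auc_calvert", 5.0, carb_price, carb_pack,
                   max_cycles=induction_cycles, phase="induction_only"),
    )


def _ici_rules(name: str) -> tuple[DosingRule, ...]:
    if name == "serplulimab+chemotherapy":
        p, pk = _PRICES["serplulimab"]
        return (DosingRule("serplulimab", "per_kg", 4.5, p, pk),)
    if name == "adebrelimab+chemotherapy":
        p, pk = _PRICES["adebrelimab"]
        return (DosingRule("adebrelimab", "per_kg", 20.0, p, pk),)
    if name == "atezolizumab+chemotherapy":
        p, pk = _PRICES["atezolizumab"]
        return (DosingRule("atezolizumab", "flat", 1200.0, p, pk),)
    if name == "durvalumab+chemotherapy":
        p, pk = _PRICES["durvalumab"]
        return (DosingRule("durvalumab", "flat", 1500.0, p, pk),)
    if name == "durvalumab+tremelimumab+chemotherapy":
        pd_, pkd = _PRICES["durvalumab"]
        pt, pkt = _PRICES["tremelimumab"]
        return (
            DosingRule("durvalumab", "flat", 1500.0, pd_, pkd),
            # tremelimumab 75 mg for up to 4 doses alongside induction
            DosingRule("tremelimumab", "flat", 75.0, pt, pkt,
                       max_cycles=4, phase="induction_only"),
        )
    raise KeyError(name)


def demo_workbook(seed: int = 0) -> Workbook:
    """A complete synthetic configuration running the whole pipeline.

    Reference chemotherapy curves are log-logistic with (theta, kappa) =
    (-2.5, 1.8) for PFS (median about 4.0 months) and (-4.0, 1.6) for OS
    (median about 12.2 months), consistent with first-line chemotherapy
    outcomes in extensive-stage SCLC.  The seed is recorded in the label;
    the workbook itself is deterministic.
    """
    chemo = StrategyDef(
        name="chemotherapy",
        hr_pfs=HazardRatio.identity("PFS"),
        hr_os=HazardRatio.identity("OS"),
        hr_ae=HazardRatio.identity("AE"),
        dosing=_chemo_backbone(),
    )
    strategies = [chemo]
    for name, hrs in _STRATEGY_HRS.items():
        strategies.append(
            StrategyDef(
                name=name,
                hr_pfs=HazardRatio(*hrs["pfs"], endpoint="PFS"),
                hr_os=HazardRatio(*hrs["os"], endpoint="OS"),
                hr_ae=HazardRatio(*hrs["ae"], endpoint="AE"),
                dosing=_chemo_backbone() + _ici_rules(name),
            )
        )
    settings = EconSettings(
        discount_rate_annual=PAPER_CONSTANTS["discount_rate_annual"],
        wtp_low=PAPER_CONSTANTS["wtp_low"],
        wtp_high=PAPER_CONSTANTS["wtp_high"],
        cny_per_usd=PAPER_CONSTANTS["cny_per_usd"],
        palliative_cost=1800.0,
        followup_cost_per_cycle=75.0,
        bsc_cost_per_cycle=130.0,
        subsequent_cost_per_cycle=850.0,
    )
    return Workbook(
        pfs_model=ParametricSurvival("loglogistic", (-2.5, 1.8)),
        os_model=ParametricSurvival("loglogistic", (-4.0, 1.6)),
        strategies=tuple(strategies),
        population=Population(
            weight_male_kg=PAPER_CONSTANTS["weight_male_kg"],
            weight_female_kg=PAPER_CONSTANTS["weight_female_kg"],
            prop_male=0.5,
            bsa_m2=PAPER_CONSTANTS["bsa_m2"],
            crcl_ml_min=PAPER_CONSTANTS["crcl_ml_min"],
        ),
        utilities=UtilitySet(PAPER_CONSTANTS["u_pfd"], PAPER_CONSTANTS["u_pd"]),
        settings=settings,
        ae_items=tuple(AEItem(*row) for row in _AE_TABLE),
        grid=CycleGrid(PAPER_CONSTANTS["cycle_length_days"], PAPER_CONSTANTS["horizon_years"]),
        label=f"demo_case(seed={seed})",
    )


def demo_scenario(seed: int = 0, cohort_size: int = 300) -> SyntheticScenario:
    """Synthetic world bundling the demo workbook with a simulated
    chemotherapy cohort specification."""
    wb = demo_workbook(seed)
    return SyntheticScenario(
        seed=seed,
        theta_pfs=-2.5,
        kappa_pfs=1.8,
        theta_os=-4.0,
        kappa_os=1.6,
        cohort_size=cohort_size,
        censoring=("uniform", 30.0),
        workbook=wb,
    )
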