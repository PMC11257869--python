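"""Deterministic and probabilistic sensitivity analysis.

One-way DSA reruns the model with each parameter at the ends of its
plausible range (95% CI for hazard ratios, 0-8% for the discount rate,
+/-25% of baseline otherwise) and ranks parameters by the spread of the
resulting ICER (tornado ordering).  A threshold search locates the
parameter value at which the ICER crosses a willingness-to-pay level by
bisection, after verifying monotonicity at the interval endpoints.

The PSA draws all parameters jointly and independently from standard
distributions (gamma for costs, beta for probabilities and utilities,
lognormal for hazard ratios, uniform as a fallback), evaluates the model
per draw, and summarises the draws as cost-effectiveness acceptability
curves: the probability each strategy has the highest net monetary benefit
across a willingness-to-pay grid.

Distribution parameterisation: the mean is anchored at the base value and
the standard deviation at (high - low) / (2 * 1.96); hazard-ratio lognormals
match the 95% CI on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .economics import CEResult
from .frontier import FrontierResult, frontier

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "CEAC",
    "dsa_oneway",
    "threshold_search",
    "psa",
    "ceac",
    "subgroup_run",
]

_DISTRIBUTIONS = ("gamma", "beta", "lognormal", "uniform")


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, plausible range, distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.distribution not in _DISTRIBUTIONS:
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires a [0, 1] quantity")
        if self.distribution in ("lognormal", "gamma") and self.low <= 0 and self.base > 0:
            # gamma tolerates low == 0; lognormal needs strictly positive bounds
            if self.distribution == "lognormal":
                raise ValueError(f"{self.name}: lognormal requires positive bounds")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / (2.0 * 1.96)

    def sampler(self) -> Callable[[np.random.Generator, int], np.ndarray]:
        """Vectorised sampler; validated eagerly at setup."""
        base, sd = self.base, self.sd
        if sd == 0.0 or self.low == self.high:
            return lambda rng, n: np.full(n, base)
        if self.distribution == "uniform":
            lo, hi = self.low, self.high
            return lambda rng, n: rng.uniform(lo, hi, size=n)
        if self.distribution == "gamma":
            if base <= 0:
                raise ValueError(f"{self.name}: gamma requires a positive base")
            shape = (base / sd) ** 2
            scale = sd**2 / base
            return lambda rng, n: rng.gamma(shape, scale, size=n)
        if self.distribution == "beta":
            if not 0 < base < 1:
                raise ValueError(f"{self.name}: beta requires base in (0, 1)")
            nu = base * (1 - base) / sd**2 - 1.0
            if nu <= 0:
                raise ValueError(f"{self.name}: beta variance too large for its mean")
            a, b = base * nu, (1 - base) * nu
            return lambda rng, n: rng.beta(a, b, size=n)
        if self.distribution == "lognormal":
            mu = math.log(base)
            sigma = (math.log(self.high) - math.log(self.low)) / (2.0 * 1.96)
            return lambda rng, n: rng.lognormal(mu, sigma, size=n)
        raise ValueError(self.distribution)


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    icer_at_low: float
    icer_at_high: float
    failed: bool = False

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def dsa_oneway(
    specs: Sequence[ParamSpec], runner: Callable[[dict], float]
) -> list[TornadoEntry]:
    """One-way DSA: rerun the model with each parameter at its low and high
    bound (all others at base); entries sorted by descending ICER spread.

    ``runner`` maps {param name: value} overrides to an ICER.  A runner
    failure at an endpoint flags the entry instead of dropping it.
    """
    entries: list[TornadoEntry] = []
    for spec in specs:
        vals = {}
        failed = False
        for bound in ("low", "high"):
            try:
                vals[bound] = float(runner({spec.name: getattr(spec, bound)}))
            except Exception:  # noqa: BLE001 - surfaced via the flag
                vals[bound] = math.nan
                failed = True
        entries.append(
            TornadoEntry(spec.name, vals["low"], vals["high"], failed=failed)
        )
    return sorted(
        entries, key=lambda e: (-1.0 if e.failed else e.spread), reverse=True
    )


def threshold_search(
    spec: ParamSpec,
    wtp: float,
    runner: Callable[[dict], float],
    rel_tol: float = 1e-6,
    max_iter: int = 200,
) -> float | None:
    """Bisection for the parameter value where the ICER equals the
    willingness-to-pay level.

    Requires the ICER to be monotone over [low, high]; checked by comparing
    the endpoint values (a non-bracketing monotone interval returns None, a
    sign pattern inconsistent with monotonicity raises).
    """
    f_low = runner({spec.name: spec.low}) - wtp
    f_high = runner({spec.name: spec.high}) - wtp
    if f_low == 0.0:
        return spec.low
    if f_high == 0.0:
        return spec.high
    if f_low * f_high > 0:
        return None  # no crossing within the interval
    f_base = runner({spec.name: spec.base}) - wtp
    if not (min(f_low, f_high) <= f_base <= max(f_low, f_high)):
        raise ValueError(
            f"{spec.name}: ICER is not monotone over [{spec.low}, {spec.high}]; "
            "use a grid search instead"
        )
    lo, hi, f_lo = spec.low, spec.high, f_low
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = runner({spec.name: mid}) - wtp
        if f_mid == 0.0 or (hi - lo) <= rel_tol * max(abs(mid), 1e-12):
            return mid
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws: parameter matrix and per-strategy (cost, QALY)."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    param_names: tuple[str, ...]
    param_draws: np.ndarray  # (n_draws, n_params)
    seed: int

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def to_frame(self):
        import pandas as pd

        frames = []
        for j, s in enumerate(self.strategies):
            frames.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(self.n_draws),
                        "strategy": s,
                        "cost": self.costs[:, j],
                        "qalys": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def psa(
    specs: Sequence[ParamSpec],
    runner: Callable[[dict], Mapping[str, tuple[float, float]]],
    n_draws: int = 10_000,
    seed: int = 20240705,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Parameters are drawn jointly and independently; the model runner is
    evaluated once per draw.  Reproducible for a given seed.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    samplers = [(spec.name, spec.sampler()) for spec in specs]  # validates setup
    rng = np.random.default_rng(seed)
    draws = np.column_stack([s(rng, n_draws) for _, s in samplers]) if samplers else np.empty((n_draws, 0))
    strategies: tuple[str, ...] | None = None
    costs = qalys = None
    for i in range(n_draws):
        overrides = {name: float(draws[i, j]) for j, (name, _) in enumerate(samplers)}
        out = runner(overrides)
        if strategies is None:
            strategies = tuple(out.keys())
            costs = np.empty((n_draws, len(strategies)))
            qalys = np.empty((n_draws, len(strategies)))
        for j, s in enumerate(strategies):
            costs[i, j], qalys[i, j] = out[s]
    return PSAResult(
        strategies=strategies,
        costs=costs,
        qalys=qalys,
        param_names=tuple(n for n, _ in samplers),
        param_draws=draws,
        seed=seed,
    )


@dataclass(frozen=True)
class CEAC:
    """Acceptability: probability each strategy is optimal per WTP level."""

    wtp_grid: np.ndarray
    strategies: tuple[str, ...]
    probabilities: np.ndarray  # (n_wtp, n_strategies), rows sum to 1

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, w in enumerate(self.wtp_grid):
            for j, s in enumerate(self.strategies):
                rows.append({"wtp": w, "strategy": s, "probability": self.probabilities[i, j]})
        return pd.DataFrame(rows)


def default_wtp_grid() -> np.ndarray:
    """0 to 60,000 USD/QALY in 500-unit steps (spans the decision range)."""
    return np.arange(0.0, 60_000.0 + 1, 500.0)


def ceac(samples: PSAResult, wtp_grid: Sequence[float] | np.ndarray) -> CEAC:
    """Probability of maximal net monetary benefit per WTP; ties split
    equally among the tied strategies."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    if samples.n_draws < 1:
        raise ValueError("need at least one PSA draw")
    n_s = len(samples.strategies)
    probs = np.zeros((wtp_grid.size, n_s))
    for i, w in enumerate(wtp_grid):
        nmb = w * samples.qalys - samples.costs  # (draws, strategies)
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    return CEAC(wtp_grid=wtp_grid, strategies=samples.strategies, probabilities=probs)


def _hr_spec(name: str, hr) -> ParamSpec:
    lo = hr.ci_low if hr.ci_low is not None else hr.point * 0.75
    hi = hr.ci_high if hr.ci_high is not None else hr.point * 1.25
    return ParamSpec(name, hr.point, lo, hi, "lognormal")


def _pm25(name: str, base: float, distribution: str, cap: float | None = None) -> ParamSpec:
    lo, hi = base * 0.75, base * 1.25
    if cap is not None:
        hi = min(hi, cap)
    return ParamSpec(name, base, lo, hi, distribution)


def default_param_specs(workbook, strategy: str) -> list[ParamSpec]:
    """Plausible ranges for the one-way DSA of ``strategy`` versus the
    reference arm: hazard-ratio 95% CIs, discount rate 0-8%, +/-25%
    elsewhere."""
    strat = workbook.strategy(strategy)
    specs = [
        _hr_spec(f"strategy.{strategy}.hr_os", strat.hr_os),
        _hr_spec(f"strategy.{strategy}.hr_pfs", strat.hr_pfs),
        _hr_spec(f"strategy.{strategy}.hr_ae", strat.hr_ae),
        ParamSpec("settings.discount_rate_annual",
                  workbook.settings.discount_rate_annual, 0.0, 0.08, "uniform"),
        _pm25("population.weight_male_kg", workbook.population.weight_male_kg, "gamma"),
        _pm25("population.weight_female_kg", workbook.population.weight_female_kg, "gamma"),
        _pm25("utilities.u_pfd", workbook.utilities.u_pfd, "beta", cap=1.0),
        _pm25("utilities.u_pd", workbook.utilities.u_pd, "beta", cap=workbook.utilities.u_pfd),
        _pm25("settings.bsc_cost_per_cycle", workbook.settings.bsc_cost_per_cycle, "gamma"),
        _pm25("settings.subsequent_cost_per_cycle",
              workbook.settings.subsequent_cost_per_cycle, "gamma"),
        _pm25("settings.palliative_cost", workbook.settings.palliative_cost, "gamma"),
    ]
    # price of each drug given beyond the shared backbone
    backbone = {r.drug for r in workbook.strategy(
        workbook.strategies[0].name).dosing}
    for rule in strat.dosing:
        if rule.drug not in backbone:
            specs.append(_pm25(f"strategy.{strategy}.price.{rule.drug}",
                               rule.price_per_pack, "gamma"))
    return specs


def psa_param_specs(workbook) -> list[ParamSpec]:
    """Joint uncertainty set for the PSA: every strategy's PFS/OS/AE hazard
    ratios (lognormal on their CIs), state utilities (beta) and non-drug
    costs (gamma)."""
    specs: list[ParamSpec] = [
        _pm25("utilities.u_pfd", workbook.utilities.u_pfd, "beta", cap=1.0),
        _pm25("utilities.u_pd", workbook.utilities.u_pd, "beta", cap=workbook.utilities.u_pfd),
        _pm25("settings.bsc_cost_per_cycle", workbook.settings.bsc_cost_per_cycle, "gamma"),
        _pm25("settings.subsequent_cost_per_cycle",
              workbook.settings.subsequent_cost_per_cycle, "gamma"),
        _pm25("settings.palliative_cost", workbook.settings.palliative_cost, "gamma"),
    ]
    reference = workbook.strategies[0].name
    for strat in workbook.strategies:
        if strat.name == reference:
            continue
        specs.append(_hr_spec(f"strategy.{strat.name}.hr_pfs", strat.hr_pfs))
        specs.append(_hr_spec(f"strategy.{strat.name}.hr_os", strat.hr_os))
        specs.append(_hr_spec(f"strategy.{strat.name}.hr_ae", strat.hr_ae))
    return specs


def subgroup_run(
    workbook,
    subgroup_hrs: Mapping[str, Mapping[str, Mapping[str, float]]],
    population_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, tuple[list[CEResult], FrontierResult]]:
    """Re-run the base case per subgroup with subgroup-specific hazard
    ratios (and, for gender subgroups, sex-specific weight).

    ``subgroup_hrs`` maps subgroup -> strategy -> {"pfs": hr, "os": hr} (an
    optional "ae" entry overrides the AE hazard ratio).  Strategies missing
    from a subgroup keep their overall HRs; a subgroup entry naming an
    unknown strategy is skipped with a warning.  ``population_overrides``
    maps subgroup -> Population field overrides (e.g. prop_male 1.0 for the
    male subgroup).
    """
    import logging

    from .pipeline import run_base_case, set_param

    log = logging.getLogger(__name__)
    out: dict[str, tuple[list[CEResult], FrontierResult]] = {}
    known = {s.name for s in workbook.strategies}
    for sub, table in subgroup_hrs.items():
        wb = workbook
        skip = False
        for strat_name, hrs in table.items():
            if strat_name not in known:
                log.warning("subgroup %s: unknown strategy %s skipped", sub, strat_name)
                skip = True
                continue
            for endpoint, key in (("pfs", "hr_pfs"), ("os", "hr_os"), ("ae", "hr_ae")):
                if endpoint in hrs:
                    wb = set_param(wb, f"strategy.{strat_name}.{key}", float(hrs[endpoint]))
        if population_overrides and sub in population_overrides:
            for fld, val in population_overrides[sub].items():
                wb = set_param(wb, f"population.{fld}", float(val))
        results = run_base_case(wb)
        out[sub] = (results, frontier(results))
    return out
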