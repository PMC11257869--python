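"""End-to-end base-case pipeline: a parameter workbook tying together the
reference survival curves, strategy hazard ratios and dosing, adverse-event
tables, utilities and economic settings, plus the runner that turns a
workbook into per-strategy discounted cost/QALY totals.

The workbook is plain data (YAML round-trippable).  Sensitivity analyses
re-run the same pipeline with single parameters overridden through a small
dotted-path grammar, e.g.::

    settings.discount_rate_annual
    population.weight_male_kg
    utilities.u_pfd
    strategy.<name>.hr_os            (hazard-ratio point estimate)
    strategy.<name>.price.<drug>     (price per pack)
    ae.<ae name>.unit_cost / freq_chemo / disutility
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .economics import (
    AEItem,
    CEResult,
    DosingRule,
    EconSettings,
    Population,
    UtilitySet,
    accumulate,
    ae_burden,
    drug_cost_vector,
)
from .markov import CohortTrace, CycleGrid, state_occupancy
from .survival import HazardRatio, ParametricSurvival, apply_hr

__all__ = ["StrategyDef", "Workbook", "run_strategy", "run_base_case",
           "set_param", "make_icer_runner", "make_psa_runner"]


@dataclass(frozen=True)
class StrategyDef:
    """One treatment arm: relative effects versus the reference curves and
    first-line dosing rules."""

    name: str
    hr_pfs: HazardRatio
    hr_os: HazardRatio
    hr_ae: HazardRatio
    dosing: tuple[DosingRule, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dosing", tuple(self.dosing))


@dataclass(frozen=True)
class Workbook:
    """Complete model configuration."""

    pfs_model: ParametricSurvival
    os_model: ParametricSurvival
    strategies: tuple[StrategyDef, ...]
    population: Population = Population()
    utilities: UtilitySet = UtilitySet()
    settings: EconSettings = EconSettings()
    ae_items: tuple[AEItem, ...] = ()
    grid: CycleGrid = CycleGrid()
    label: str = "workbook"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))
        object.__setattr__(self, "ae_items", tuple(self.ae_items))
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strategy names")

    def strategy(self, name: str) -> StrategyDef:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Workbook":
        return _workbook_from_plain(d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "Workbook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _workbook_from_plain(d: dict) -> Workbook:
    def hr(h):
        return HazardRatio(**h)

    strategies = tuple(
        StrategyDef(
            name=s["name"],
            hr_pfs=hr(s["hr_pfs"]),
            hr_os=hr(s["hr_os"]),
            hr_ae=hr(s["hr_ae"]),
            dosing=tuple(DosingRule(**r) for r in s.get("dosing", [])),
        )
        for s in d["strategies"]
    )
    return Workbook(
        pfs_model=ParametricSurvival(
            d["pfs_model"]["family"], tuple(d["pfs_model"]["params"]),
            d["pfs_model"].get("time_unit", "months"),
        ),
        os_model=ParametricSurvival(
            d["os_model"]["family"], tuple(d["os_model"]["params"]),
            d["os_model"].get("time_unit", "months"),
        ),
        strategies=strategies,
        population=Population(**d.get("population", {})),
        utilities=UtilitySet(**d.get("utilities", {})),
        settings=EconSettings(**d.get("settings", {})),
        ae_items=tuple(AEItem(**a) for a in d.get("ae_items", [])),
        grid=CycleGrid(**d.get("grid", {})),
        label=d.get("label", "workbook"),
    )


# ---------------------------------------------------------------------------
# running


def run_strategy(wb: Workbook, strat: StrategyDef) -> tuple[CEResult, CohortTrace]:
    """Base-case totals and trace for one strategy."""
    s_pfs = lambda t: apply_hr(wb.pfs_model, strat.hr_pfs, t)  # noqa: E731
    s_os = lambda t: apply_hr(wb.os_model, strat.hr_os, t)  # noqa: E731
    trace = state_occupancy(s_pfs, s_os, wb.grid)
    drug = drug_cost_vector(strat.dosing, wb.population, wb.grid.n_cycles)
    ae = ae_burden(wb.ae_items, strat.hr_ae)
    result = accumulate(trace, drug, wb.utilities, wb.settings, ae=ae,
                        grid=wb.grid, strategy=strat.name)
    return result, trace


def run_base_case(wb: Workbook) -> list[CEResult]:
    """Run every strategy in the workbook; order preserved."""
    return [run_strategy(wb, s)[0] for s in wb.strategies]


# ---------------------------------------------------------------------------
# parameter overrides


def set_param(wb: Workbook, path: str, value: float) -> Workbook:
    """Return a copy of the workbook with one parameter replaced.

    See the module docstring for the path grammar.
    """
    # all workbook components are frozen dataclasses, so functional updates
    # via dataclasses.replace never mutate the input
    parts = path.split(".")
    if parts[0] in ("settings", "population", "utilities"):
        if len(parts) != 2:
            raise ValueError(f"bad parameter path {path!r}")
        section = getattr(wb, parts[0])
        if parts[0] == "utilities":
            # keep the logical ordering u_pd <= u_pfd when one utility is
            # varied on its own (joint draws may otherwise cross)
            u_pfd, u_pd = section.u_pfd, section.u_pd
            if parts[1] == "u_pfd":
                u_pfd = value
                u_pd = min(u_pd, u_pfd)
            elif parts[1] == "u_pd":
                u_pd = min(value, u_pfd)
            else:
                raise ValueError(f"bad parameter path {path!r}")
            new = dataclasses.replace(section, u_pfd=u_pfd, u_pd=u_pd)
        else:
            new = dataclasses.replace(section, **{parts[1]: value})
        return dataclasses.replace(wb, **{parts[0]: new})
    if parts[0] == "strategy":
        if len(parts) == 3 and parts[2] in ("hr_pfs", "hr_os", "hr_ae"):
            _, name, which = parts
            strat = wb.strategy(name)
            old: HazardRatio = getattr(strat, which)
            new_hr = HazardRatio(
                point=value,
                ci_low=min(value, old.ci_low) if old.ci_low is not None else None,
                ci_high=max(value, old.ci_high) if old.ci_high is not None else None,
                endpoint=old.endpoint, subgroup=old.subgroup,
            )
            new_strat = dataclasses.replace(strat, **{which: new_hr})
        elif len(parts) == 4 and parts[2] == "price":
            _, name, _, drug = parts
            strat = wb.strategy(name)
            rules = []
            hit = False
            for r in strat.dosing:
                if r.drug == drug:
                    rules.append(dataclasses.replace(r, price_per_pack=value))
                    hit = True
                else:
                    rules.append(r)
            if not hit:
                raise KeyError(f"strategy {name!r} has no drug {drug!r}")
            new_strat = dataclasses.replace(strat, dosing=tuple(rules))
        else:
            raise ValueError(f"bad parameter path {path!r}")
        strategies = tuple(new_strat if s.name == new_strat.name else s for s in wb.strategies)
        return dataclasses.replace(wb, strategies=strategies)
    if parts[0] == "ae" and len(parts) == 3:
        _, name, fld = parts
        items = []
        hit = False
        for item in wb.ae_items:
            if item.name == name:
                items.append(dataclasses.replace(item, **{fld: value}))
                hit = True
            else:
                items.append(item)
        if not hit:
            raise KeyError(f"no adverse event named {name!r}")
        return dataclasses.replace(wb, ae_items=tuple(items))
    raise ValueError(f"bad parameter path {path!r}")


def apply_overrides(wb: Workbook, overrides: dict[str, float]) -> Workbook:
    for path, value in overrides.items():
        wb = set_param(wb, path, value)
    return wb


def make_icer_runner(wb: Workbook, strategy: str, comparator: str) -> Callable[[dict], float]:
    """Runner returning the pairwise ICER of ``strategy`` vs ``comparator``
    after applying parameter overrides — the model function used by the
    deterministic sensitivity analysis and threshold search."""
    from .frontier import icer

    def runner(overrides: dict[str, float]) -> float:
        wb2 = apply_overrides(wb, overrides)
        a = run_strategy(wb2, wb2.strategy(strategy))[0]
        b = run_strategy(wb2, wb2.strategy(comparator))[0]
        return icer(a, b)

    return runner


def make_psa_runner(wb: Workbook) -> Callable[[dict], dict[str, tuple[float, float]]]:
    """Runner returning {strategy: (cost, qalys)} for all strategies under
    parameter overrides — the model function sampled by the PSA."""

    def runner(overrides: dict[str, float]) -> dict[str, tuple[float, float]]:
        wb2 = apply_overrides(wb, overrides)
        return {
            r.strategy: (r.total_cost, r.total_qalys) for r in run_base_case(wb2)
        }

    return runner
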