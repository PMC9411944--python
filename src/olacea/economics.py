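"""Cost and QALY accrual over a cohort trace, and incremental results.

Costing conventions (all money in 2020 USD):

* Olaparib is dosed 300 mg twice daily = four 150 mg tablets/day; the drug
  cost per monthly cycle is ``unit price x 4 x 30.4375`` (365.25/12 days).
* Follow-up and radiology accrue in the progression-free state; salvage
  chemotherapy accrues in the progressed state; terminal care is charged
  once per incident death at that cycle's discount factor.
* BRCA1/2 testing and serious-adverse-event (SAE) management are one-off
  charges at model entry, undiscounted, booked under the PFS column.
* QALYs = sum over cycles of occupancy x state utility x discount / 12.
* Body surface area (BSA) scales the salvage cost linearly relative to the
  1.72 m^2 reference patient; at base case the factor is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .markov import Arm, CohortTrace, ModelConfig, half_cycle_corrected_occupancy, run_cohort

__all__ = [
    "Parameter",
    "EconomicInputs",
    "StrategyResult",
    "IncrementalResult",
    "DAYS_PER_CYCLE",
    "TABLETS_PER_DAY",
    "REFERENCE_BSA",
    "olaparib_cost_per_cycle",
    "sae_one_off_cost",
    "accrue",
    "icer",
    "run_strategies",
]

DAYS_PER_CYCLE = 365.25 / 12.0
TABLETS_PER_DAY = 4
REFERENCE_BSA = 1.72

SAE_KEYS = ("anemia", "neutropenia", "nausea", "fatigue")

Distribution = Literal["triangle", "beta", "fixed"]


@dataclass(frozen=True)
class Parameter:
    """A model input with its deterministic-sensitivity range and PSA family."""

    base: float
    low: float
    high: float
    distribution: Distribution = "fixed"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"bounds must bracket the base value: {self.low} <= {self.base} <= {self.high}"
            )
        if self.distribution not in ("triangle", "beta", "fixed"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    @property
    def degenerate(self) -> bool:
        return self.high == self.low

    def fixed(self) -> "Parameter":
        """A copy collapsed to its base value (range zero, fixed family)."""
        return Parameter(self.base, self.base, self.base, "fixed")


def _p(base, low, high, dist) -> Parameter:
    return Parameter(base, low, high, dist)


@dataclass(frozen=True)
class EconomicInputs:
    """All cost, risk and utility inputs with sensitivity ranges.

    Defaults are the base-case values for the Chinese healthcare setting;
    ranges are +/-20% for costs and risks, 0-8% for the discount rate.
    """

    olaparib_price_per_150mg: Parameter = _p(14.78, 11.82, 17.74, "triangle")
    brca_testing: Parameter = _p(507.25, 405.80, 608.70, "triangle")
    followup_per_cycle: Parameter = _p(35.63, 28.50, 42.76, "triangle")
    radiology_per_cycle: Parameter = _p(64.73, 51.78, 77.68, "triangle")
    salvage_per_cycle: Parameter = _p(270.20, 216.16, 324.24, "triangle")
    terminal_care: Parameter = _p(2212.80, 1770.24, 2655.36, "triangle")
    sae_unit_costs: Dict[str, Parameter] = field(default_factory=lambda: {
        "anemia": _p(531.70, 425.36, 638.04, "triangle"),
        "neutropenia": _p(530.80, 424.64, 636.96, "triangle"),
        "nausea": _p(40.00, 32.00, 48.00, "triangle"),
        "fatigue": _p(110.30, 88.24, 132.36, "triangle"),
    })
    sae_risks_olaparib: Dict[str, Parameter] = field(default_factory=lambda: {
        "anemia": _p(0.19, 0.152, 0.228, "beta"),
        "neutropenia": _p(0.05, 0.04, 0.06, "beta"),
        "nausea": _p(0.03, 0.023, 0.036, "beta"),
        "fatigue": _p(0.04, 0.032, 0.048, "beta"),
    })
    sae_risks_placebo: Dict[str, Parameter] = field(default_factory=lambda: {
        "anemia": _p(0.02, 0.016, 0.024, "beta"),
        "neutropenia": _p(0.04, 0.032, 0.048, "beta"),
        "nausea": _p(0.00, 0.00, 0.00, "beta"),
        "fatigue": _p(0.02, 0.016, 0.024, "beta"),
    })
    utility_pfs: Parameter = _p(0.81, 0.729, 0.891, "beta")
    utility_pd: Parameter = _p(0.74, 0.666, 0.814, "beta")
    bsa: Parameter = _p(1.72, 1.38, 2.06, "triangle")
    discount_rate: Parameter = _p(0.03, 0.00, 0.08, "fixed")

    def __post_init__(self) -> None:
        for name in ("sae_unit_costs", "sae_risks_olaparib", "sae_risks_placebo"):
            m = getattr(self, name)
            if set(m) != set(SAE_KEYS):
                raise ValueError(f"{name} must have keys {SAE_KEYS}, got {sorted(m)}")
        for key, par in self.iter_parameters():
            if "utility" in key or "risk" in key:
                if not (0.0 <= par.low and par.high <= 1.0):
                    raise ValueError(f"{key} must lie in [0, 1]")
            elif key != "discount_rate" and par.low < 0:
                raise ValueError(f"{key} must be non-negative")

    def iter_parameters(self):
        """Yield (flat_name, Parameter) pairs over every scalar input."""
        for name in ("olaparib_price_per_150mg", "brca_testing", "followup_per_cycle",
                     "radiology_per_cycle", "salvage_per_cycle", "terminal_care",
                     "utility_pfs", "utility_pd", "bsa", "discount_rate"):
            yield name, getattr(self, name)
        for key in SAE_KEYS:
            yield f"sae_cost_{key}", self.sae_unit_costs[key]
        for key in SAE_KEYS:
            yield f"sae_risk_olaparib_{key}", self.sae_risks_olaparib[key]
        for key in SAE_KEYS:
            yield f"sae_risk_placebo_{key}", self.sae_risks_placebo[key]

    def with_value(self, name: str, value: float) -> "EconomicInputs":
        """A copy with one parameter's base set to ``value`` (range collapsed)."""
        newpar = Parameter(value, value, value, "fixed")
        if name.startswith("sae_cost_"):
            key = name[len("sae_cost_"):]
            return replace(self, sae_unit_costs={**self.sae_unit_costs, key: newpar})
        if name.startswith("sae_risk_olaparib_"):
            key = name[len("sae_risk_olaparib_"):]
            return replace(self, sae_risks_olaparib={**self.sae_risks_olaparib, key: newpar})
        if name.startswith("sae_risk_placebo_"):
            key = name[len("sae_risk_placebo_"):]
            return replace(self, sae_risks_placebo={**self.sae_risks_placebo, key: newpar})
        if not hasattr(self, name):
            raise KeyError(name)
        return replace(self, **{name: newpar})


@dataclass(frozen=True)
class StrategyResult:
    """Discounted per-state and total costs and QALYs for one arm."""

    arm: str
    cost_pfs: float
    cost_pd: float
    qaly_pfs: float
    qaly_pd: float

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_pd

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_pd

    def to_dict(self) -> Dict[str, float]:
        return {
            "arm": self.arm,
            "cost_pfs": self.cost_pfs,
            "cost_pd": self.cost_pd,
            "cost_total": self.cost_total,
            "qaly_pfs": self.qaly_pfs,
            "qaly_pd": self.qaly_pd,
            "qaly_total": self.qaly_total,
        }


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental cost, effectiveness, and their ratio (or a dominance flag)."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    flag: Literal["ratio", "dominant", "dominated", "undefined"]

    def to_dict(self) -> Dict[str, object]:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "flag": self.flag,
        }


def olaparib_cost_per_cycle(inputs: EconomicInputs,
                            price_multiplier: float = 1.0) -> float:
    """Drug cost per monthly cycle: price per 150 mg x 4 tablets/day x days/cycle."""
    price = inputs.olaparib_price_per_150mg.base * price_multiplier
    if price < 0:
        raise ValueError("price must be non-negative")
    return price * TABLETS_PER_DAY * DAYS_PER_CYCLE


def sae_one_off_cost(risks: Mapping[str, float], unit_costs: Mapping[str, float]) -> float:
    """Expected one-off SAE management cost: sum of incidence x cost per event."""
    if set(risks) != set(unit_costs):
        raise ValueError(f"risk/cost keys differ: {sorted(risks)} vs {sorted(unit_costs)}")
    return float(sum(risks[k] * unit_costs[k] for k in risks))


def accrue(trace: CohortTrace, arm_name: str, inputs: EconomicInputs,
           config: ModelConfig, price_multiplier: float = 1.0) -> StrategyResult:
    """Accrue discounted costs and QALYs over a cohort trace for one arm."""
    if trace.horizon != config.horizon:
        raise ValueError(
            f"trace horizon {trace.horizon} != config horizon {config.horizon}"
        )
    pfs_occ, pd_occ = half_cycle_corrected_occupancy(trace, config.half_cycle_correction)
    d = trace.discount_factors[1:]
    is_olaparib = arm_name.lower() == "olaparib"

    drug = olaparib_cost_per_cycle(inputs, price_multiplier) if is_olaparib else 0.0
    pfs_cycle_cost = drug + inputs.followup_per_cycle.base + inputs.radiology_per_cycle.base
    bsa_factor = inputs.bsa.base / REFERENCE_BSA
    pd_cycle_cost = inputs.salvage_per_cycle.base * bsa_factor

    risks = inputs.sae_risks_olaparib if is_olaparib else inputs.sae_risks_placebo
    one_off = inputs.brca_testing.base + sae_one_off_cost(
        {k: v.base for k, v in risks.items()},
        {k: v.base for k, v in inputs.sae_unit_costs.items()},
    )

    cost_pfs = float(np.sum(pfs_cycle_cost * pfs_occ * d)) + one_off
    cost_pd = float(np.sum(pd_cycle_cost * pd_occ * d)
                    + np.sum(inputs.terminal_care.base * trace.incident_deaths[1:] * d))
    qaly_pfs = float(np.sum(pfs_occ * inputs.utility_pfs.base * d) / 12.0)
    qaly_pd = float(np.sum(pd_occ * inputs.utility_pd.base * d) / 12.0)
    return StrategyResult(arm_name, cost_pfs, cost_pd, qaly_pfs, qaly_pd)


def icer(a: StrategyResult, b: StrategyResult) -> IncrementalResult:
    """Incremental result of strategy ``a`` versus comparator ``b``."""
    dc = a.cost_total - b.cost_total
    dq = a.qaly_total - b.qaly_total
    if dq == 0.0:
        return IncrementalResult(dc, dq, None, "undefined")
    if dc < 0.0 and dq > 0.0:
        return IncrementalResult(dc, dq, None, "dominant")
    if dc > 0.0 and dq < 0.0:
        return IncrementalResult(dc, dq, None, "dominated")
    return IncrementalResult(dc, dq, dc / dq, "ratio")


def run_strategies(arms: Mapping[str, Arm], inputs: EconomicInputs,
                   config: ModelConfig, price_multiplier: float = 1.0,
                   ) -> Dict[str, StrategyResult]:
    """Run the cohort model and accrual for every arm; key by arm name."""
    out = {}
    for name, arm in arms.items():
        # the discount rate lives in EconomicInputs for sensitivity purposes
        cfg = config
        if config.annual_discount_rate != inputs.discount_rate.base:
            from dataclasses import replace as _replace

            cfg = _replace(config, annual_discount_rate=inputs.discount_rate.base)
        trace = run_cohort(arm, cfg)
        out[name] = accrue(trace, name, inputs, cfg, price_multiplier)
    return out


def results_table(results: Mapping[str, StrategyResult],
                  incremental: IncrementalResult) -> pd.DataFrame:
    """Two-arm results in a tidy frame mirroring the published layout."""
    rows = [r.to_dict() for r in results.values()]
    df = pd.DataFrame(rows).set_index("arm")
    df.loc["incremental"] = {
        "cost_total": incremental.delta_cost,
        "qaly_total": incremental.delta_qaly,
    }
    df.loc["icer"] = {"cost_total": incremental.icer if incremental.icer is not None
                      else float("nan")}
    return df
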