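"""One-way (tornado) analysis, price-discount scenarios, and probabilistic
sensitivity analysis (PSA) with cost-effectiveness acceptability curves.

Sampling families for the PSA follow common health-technology-assessment
practice: triangle distributions for costs and body surface area (min =
lower bound, mode = base case, max = upper bound) and beta distributions for
utilities and adverse-event risks.  The beta shapes come from matching
moments to mean = base case and SD = (high - low)/3.92, i.e. the published
range is read as a 95% interval.  The discount rate is held fixed in the
PSA.  Per draw, "cost-effective" at willingness-to-pay lambda means
non-negative net monetary benefit, lambda * dQALY - dCost >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .economics import (
    EconomicInputs,
    IncrementalResult,
    Parameter,
    icer,
    run_strategies,
)
from .markov import Arm, ModelConfig, run_cohort

__all__ = [
    "TornadoRow",
    "PsaDraw",
    "Ceac",
    "one_way",
    "scenario_price_discount",
    "sample_parameters",
    "run_psa",
    "ceac",
]

DEFAULT_WTP_GRID = np.arange(0.0, 150_001.0, 1000.0)


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class PsaDraw:
    """One PSA iteration: the sampled inputs and its incremental outcome."""

    inputs: EconomicInputs
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class Ceac:
    wtp_grid: np.ndarray
    prob_cost_effective: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid,
                             "probability": self.prob_cost_effective})


def _base_icer(arms, inputs, config, price_multiplier=1.0) -> float:
    res = run_strategies(arms, inputs, config, price_multiplier)
    inc = icer(res["olaparib"], res["placebo"])
    return inc.icer if inc.icer is not None else float("nan")


def one_way(arms: Mapping[str, Arm], base_inputs: EconomicInputs,
            config: ModelConfig) -> List[TornadoRow]:
    """Recompute the ICER with each parameter at its low and high bound.

    All other parameters stay at base.  Rows come back sorted by descending
    ICER spread, ready for a tornado diagram.
    """
    rows = []
    for name, par in base_inputs.iter_parameters():
        lo = _base_icer(arms, base_inputs.with_value(name, par.low), config)
        hi = _base_icer(arms, base_inputs.with_value(name, par.high), config)
        rows.append(TornadoRow(name, lo, hi))
    rows.sort(key=lambda r: r.spread, reverse=True)
    return rows


def tornado_frame(rows: Sequence[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "icer_low": [r.icer_low for r in rows],
            "icer_high": [r.icer_high for r in rows],
            "spread": [r.spread for r in rows],
        }
    )


def scenario_price_discount(multiplier: float, arms: Mapping[str, Arm],
                            inputs: EconomicInputs,
                            config: ModelConfig) -> IncrementalResult:
    """Incremental result with the olaparib unit price scaled by ``multiplier``."""
    if multiplier <= 0:
        raise ValueError("price multiplier must be positive")
    res = run_strategies(arms, inputs, config, price_multiplier=multiplier)
    return icer(res["olaparib"], res["placebo"])


def _beta_from_moments(mean: float, sd: float) -> Optional[tuple]:
    if mean <= 0.0 or mean >= 1.0 or sd <= 0.0:
        return None
    var = sd * sd
    if var >= mean * (1.0 - mean):
        return None
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _sample_one(par: Parameter, rng: np.random.Generator) -> float:
    if par.degenerate or par.distribution == "fixed":
        return par.base
    if par.distribution == "triangle":
        c = (par.base - par.low) / (par.high - par.low)
        return float(stats.triang.ppf(rng.random(), c, loc=par.low,
                                      scale=par.high - par.low))
    # beta: mean = base, SD from the range read as a 95% interval
    sd = (par.high - par.low) / 3.92
    ab = _beta_from_moments(par.base, sd)
    if ab is None:
        warnings.warn(
            f"beta moments infeasible for base={par.base}, sd={sd:.4g}; "
            "holding parameter fixed",
            RuntimeWarning,
            stacklevel=3,
        )
        return par.base
    return float(stats.beta.ppf(rng.random(), *ab))


def sample_parameters(inputs: EconomicInputs,
                      rng: np.random.Generator) -> EconomicInputs:
    """Draw one full parameter set from the PSA distributions."""
    out = inputs
    for name, par in inputs.iter_parameters():
        if name == "discount_rate":
            continue  # fixed in the PSA
        out = out.with_value(name, _sample_one(par, rng))
    return out


def run_psa(arms: Mapping[str, Arm], inputs: EconomicInputs, config: ModelConfig,
            n_iterations: int = 1000, seed: int = 0,
            price_multiplier: float = 1.0) -> List[PsaDraw]:
    """Monte-Carlo PSA: sample inputs, re-run both arms, record increments.

    The cohort traces do not depend on the sampled economic parameters
    (survival parameters are not varied), so they are computed once and the
    accrual step alone is repeated per iteration.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    from .economics import accrue

    traces = {name: run_cohort(arm, config) for name, arm in arms.items()}
    draws: List[PsaDraw] = []
    for _ in range(n_iterations):
        sampled = sample_parameters(inputs, rng)
        res = {
            name: accrue(traces[name], name, sampled, config, price_multiplier)
            for name in arms
        }
        inc = icer(res["olaparib"], res["placebo"])
        draws.append(PsaDraw(sampled, inc.delta_cost, inc.delta_qaly))
    return draws


def psa_frame(draws: Sequence[PsaDraw]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "iteration": np.arange(len(draws)),
            "delta_cost": [d.delta_cost for d in draws],
            "delta_qaly": [d.delta_qaly for d in draws],
        }
    )


def prob_cost_effective(draws: Sequence[PsaDraw], wtp: float) -> float:
    """Fraction of draws with non-negative net monetary benefit at ``wtp``."""
    dc = np.array([d.delta_cost for d in draws])
    dq = np.array([d.delta_qaly for d in draws])
    return float(np.mean(wtp * dq - dc >= 0.0))


def ceac(draws: Sequence[PsaDraw],
         wtp_grid: Optional[np.ndarray] = None) -> Ceac:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    if len(draws) == 0:
        raise ValueError("need at least one PSA draw")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wtp_grid must be strictly increasing")
    dc = np.array([d.delta_cost for d in draws])
    dq = np.array([d.delta_qaly for d in draws])
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    return Ceac(grid, np.mean(nmb >= 0.0, axis=1))


def plot_tornado(rows: Sequence[TornadoRow], base_icer: float, path) -> None:
    """Horizontal-bar tornado diagram (largest spread on top)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = sorted(rows, key=lambda r: r.spread)
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(rows) + 1.5))
    for i, r in enumerate(rows):
        lo, hi = sorted((r.icer_low, r.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r.parameter for r in rows], fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(draws: Sequence[PsaDraw], wtp: float, path) -> None:
    """Incremental cost-effectiveness plane with the WTP threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dq = np.array([d.delta_qaly for d in draws])
    dc = np.array([d.delta_cost for d in draws])
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=6, alpha=0.4)
    xs = np.linspace(min(0, dq.min()), dq.max() * 1.05, 50)
    ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP = ${wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: Ceac, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp_grid, curve.prob_cost_effective)
    ax.set_xlabel("Willingness-to-pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
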