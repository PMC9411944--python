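"""Synthetic trial data: pseudo-IPD, Kaplan-Meier curves, digitized fixtures.

This module generates the kind of data the fitting stage consumes in
practice — survival-curve coordinates digitized from published Kaplan-Meier
plots — with a known ground truth, so that parameter recovery can be tested
end-to-end.  The generative model per patient is

    event time  T ~ Weibull(scale, shape)   via inverse CDF,
    censor time C ~ Exponential(random_censor_rate)  (optional),
    administrative censoring at ``accrual_censor_months``,

with observed time min(T, C, admin) and event indicator T <= min(C, admin).
Defaults mirror the source trial's arm sizes (196 olaparib / 99 placebo)
and an administrative cut-off of 65 months, beyond both arms' median
overall survival, so simulated curves carry realistic censored tails.

Digitization of a plotted curve is emulated by reading the Kaplan-Meier
step function on a regular time grid and rounding survival to two decimal
places; no pixel-level noise model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival import PseudoIPD, SurvivalCurvePoints, WeibullParams

__all__ = ["TrialSimSpec", "simulate_ipd", "km_estimate", "make_digitized_fixture"]

DEFAULT_ADMIN_CENSOR_MONTHS = 65.0


@dataclass(frozen=True)
class TrialSimSpec:
    """Specification of one simulated trial arm/endpoint."""

    n_patients: int
    weibull: WeibullParams
    accrual_censor_months: float = DEFAULT_ADMIN_CENSOR_MONTHS
    random_censor_rate: float = 0.0  # exponential rate per month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.accrual_censor_months > 0:
            raise ValueError("accrual_censor_months must be positive")
        if self.random_censor_rate < 0:
            raise ValueError("random_censor_rate must be non-negative")


def simulate_ipd(spec: TrialSimSpec) -> PseudoIPD:
    """Draw event/censoring times for one arm; reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n_patients)
    # inverse CDF of S(t) = exp(-lam t^gam):  t = (-ln U / lam)^(1/gam)
    t_event = (-np.log(u) / spec.weibull.scale) ** (1.0 / spec.weibull.shape)
    t_cens = np.full(spec.n_patients, spec.accrual_censor_months)
    if spec.random_censor_rate > 0:
        t_cens = np.minimum(
            t_cens, rng.exponential(1.0 / spec.random_censor_rate, spec.n_patients)
        )
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    observed = np.maximum(observed, 1e-9)  # guard against zero times
    return PseudoIPD(observed, event)


def km_estimate(ipd: PseudoIPD) -> SurvivalCurvePoints:
    """Product-limit (Kaplan-Meier) survival estimate with at-risk counts.

    Returns one row per distinct event time (plus t=0 with S=1); censored
    records reduce the risk set but add no step.
    """
    if len(ipd) == 0:
        raise ValueError("empty input")
    order = np.argsort(ipd.time, kind="stable")
    t = ipd.time[order]
    e = ipd.event[order]
    n = len(t)
    uniq, first_idx, inverse = np.unique(t, return_index=True, return_inverse=True)
    deaths = np.bincount(inverse, weights=e)        # events at each distinct time
    at_risk = n - first_idx                         # at risk just before each time
    has_event = deaths > 0
    s = np.cumprod(1.0 - deaths[has_event] / at_risk[has_event])
    times = np.concatenate([[0.0], uniq[has_event]])
    surv = np.concatenate([[1.0], s])
    risk = np.concatenate([[n], at_risk[has_event]])
    return SurvivalCurvePoints(times, surv, risk)


def _step_lookup(curve: SurvivalCurvePoints, grid: np.ndarray) -> np.ndarray:
    # right-continuous step function: S(t) = last value at time <= t
    idx = np.searchsorted(curve.times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(curve.times) - 1)
    return curve.survival[idx]


def make_digitized_fixture(spec: TrialSimSpec, grid_step: float = 1.0,
                           round_decimals: int | None = 2,
                           path=None) -> SurvivalCurvePoints:
    """Emulate digitizing a plotted Kaplan-Meier curve onto a regular grid.

    Simulates the arm, computes the product-limit estimate, samples it at
    multiples of ``grid_step`` up to the administrative cut-off, and rounds
    survival to ``round_decimals`` places (None disables rounding).  When
    ``path`` is given the curve is also written as CSV.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    ipd = simulate_ipd(spec)
    km = km_estimate(ipd)
    grid = np.arange(0.0, spec.accrual_censor_months + grid_step / 2, grid_step)
    s = _step_lookup(km, grid)
    if round_decimals is not None:
        s = np.round(s, round_decimals)
        s = np.minimum.accumulate(s)  # re-impose monotonicity after rounding
    n_risk = np.array([(ipd.time >= g).sum() for g in grid])
    curve = SurvivalCurvePoints(grid, s, n_risk)
    if path is not None:
        curve.to_csv(path)
    return curve
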