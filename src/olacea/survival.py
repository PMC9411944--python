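"""Weibull survival curves, per-cycle transition probabilities, and curve fitting.

The survival model used throughout the package is the two-parameter Weibull
in scale/shape form,

    S(t) = exp(-lambda * t**gamma),

with *t* in months, ``lambda`` (scale) in units of month**-gamma and
``gamma`` (shape) dimensionless.  ``gamma > 1`` gives an increasing hazard,
``gamma = 1`` reduces to the exponential.  This parameterisation is the one
used for survival extrapolation in state-transition models, and differs from
the (t/lambda)**rho form used by e.g. lifelines; conversion helpers are not
provided because all published parameters we consume are on this scale.

Two fitting routes are offered:

* ``fit_weibull`` on pseudo individual-patient data (IPD): right-censored
  maximum likelihood, standard errors from the observed information matrix.
* ``fit_weibull`` on digitized survival-curve points: (weighted) least
  squares on the complementary-log-log scale, where the model is linear:
  log(-log S(t)) = log(lambda) + gamma * log(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WeibullParams",
    "SurvivalCurvePoints",
    "PseudoIPD",
    "weibull_survival",
    "weibull_cycle_transition_prob",
    "annual_prob_to_cycle_prob",
    "fit_weibull",
]


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape Weibull parameters with optional uncertainty.

    Attributes
    ----------
    scale : float
        lambda > 0, per month**gamma.
    shape : float
        gamma > 0, dimensionless.
    scale_se, shape_se : float
        Standard errors (0 when unknown).
    scale_ci, shape_ci : tuple of float, optional
        95% confidence intervals (low, high).
    """

    scale: float
    shape: float
    scale_se: float = 0.0
    shape_se: float = 0.0
    scale_ci: Optional[Tuple[float, float]] = None
    shape_ci: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError(f"shape must be positive and finite, got {self.shape}")
        if self.scale_se < 0 or self.shape_se < 0:
            raise ValueError("standard errors must be non-negative")
        for ci in (self.scale_ci, self.shape_ci):
            if ci is not None and not ci[0] <= ci[1]:
                raise ValueError(f"CI bounds must be ordered, got {ci}")

    def median(self) -> float:
        """Median survival time (ln 2 / lambda)**(1/gamma), in months."""
        return float((np.log(2.0) / self.scale) ** (1.0 / self.shape))


@dataclass(frozen=True)
class SurvivalCurvePoints:
    """A digitized survival curve: step-function coordinates (time, S(t))."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape:
            raise ValueError("times and survival must have equal length")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.n_at_risk is not None:
            n = np.asarray(self.n_at_risk)
            object.__setattr__(self, "n_at_risk", n)
            if n.shape != t.shape:
                raise ValueError("n_at_risk must match times in length")
            if np.any(n < 0):
                raise ValueError("n_at_risk must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_months": self.times, "survival": self.survival})
        if self.n_at_risk is not None:
            df["n_at_risk"] = self.n_at_risk
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalCurvePoints":
        df = pd.read_csv(path)
        n = df["n_at_risk"].to_numpy() if "n_at_risk" in df.columns else None
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy(), n)


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed/simulated individual patient data: (time, event) records."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        if t.shape != e.shape:
            raise ValueError("time and event must have equal length")
        if np.any(t <= 0):
            raise ValueError("times must be positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy())


def weibull_survival(t, params: WeibullParams):
    """Survival probability S(t) = exp(-lambda * t**gamma).

    Evaluated in log space; accepts scalars or arrays of times (months).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    with np.errstate(divide="ignore"):
        log_s = -params.scale * np.power(t, params.shape)
    out = np.exp(log_s)
    return float(out) if out.ndim == 0 else out


def weibull_cycle_transition_prob(t, params: WeibullParams):
    """Conditional probability of the event during cycle t, given event-free at t-1.

    P(t) = 1 - S(t)/S(t-1) = 1 - exp(lambda*(t-1)**gamma - lambda*t**gamma),
    for integer cycle index t >= 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("cycle index t must be >= 1")
    lam, gam = params.scale, params.shape
    out = 1.0 - np.exp(lam * np.power(t - 1.0, gam) - lam * np.power(t, gam))
    return float(out) if out.ndim == 0 else out


def annual_prob_to_cycle_prob(p_annual: float, cycles_per_year: float = 12.0) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Assumes a constant hazard within the year: the cycle probability q
    satisfies (1-q)**cycles_per_year = 1 - p_annual.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be in [0, 1], got {p_annual}")
    if cycles_per_year <= 0:
        raise ValueError("cycles_per_year must be positive")
    return float(1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year))


def _fit_ipd_mle(ipd: PseudoIPD) -> WeibullParams:
    # Right-censored Weibull log-likelihood in (log lambda, log gamma); the
    # log parameterisation keeps the optimizer unconstrained and the Hessian
    # well-scaled.  SEs on the natural scale follow by the delta method.
    t = ipd.time
    e = ipd.event.astype(float)
    n_events = e.sum()
    if n_events == 0:
        raise ValueError("all observations are censored: cannot fit")
    log_t = np.log(t)

    def nll(theta):
        lam, gam = np.exp(theta)
        # log f = log(lam*gam) + (gam-1) log t - lam t^gam ; log S = -lam t^gam
        return -(np.sum(e * (np.log(lam * gam) + (gam - 1.0) * log_t))
                 - np.sum(lam * np.power(t, gam)))

    # Moment-flavoured start: exponential rate at gamma=1.
    lam0 = max(n_events / np.sum(t), 1e-8)
    res = optimize.minimize(nll, x0=np.log([lam0, 1.0]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    res = optimize.minimize(nll, x0=res.x, method="BFGS")
    theta = res.x
    lam, gam = np.exp(theta)

    # Observed information: finite-difference Hessian of nll at the optimum.
    h = 1e-5
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            hess[i, j] = (nll(theta + ei + ej) - nll(theta + ei - ej)
                          - nll(theta - ei + ej) + nll(theta - ei - ej)) / (4 * h * h)
    cov_log = np.linalg.inv(hess)
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    lam_se, gam_se = lam * se_log[0], gam * se_log[1]  # delta method
    z = stats.norm.ppf(0.975)
    lam_ci = (lam * np.exp(-z * se_log[0]), lam * np.exp(z * se_log[0]))
    gam_ci = (gam * np.exp(-z * se_log[1]), gam * np.exp(z * se_log[1]))
    return WeibullParams(lam, gam, lam_se, gam_se, lam_ci, gam_ci)


def _fit_curve_points(points: SurvivalCurvePoints) -> WeibullParams:
    # cloglog regression: log(-log S) = log lambda + gamma log t, weighted by
    # at-risk counts when the digitized table carries them.
    import statsmodels.api as sm

    mask = (points.times > 0) & (points.survival > 0) & (points.survival < 1)
    t = points.times[mask]
    s = points.survival[mask]
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct time points with S in (0,1)")
    y = np.log(-np.log(s))
    X = sm.add_constant(np.log(t))
    if points.n_at_risk is not None:
        w = points.n_at_risk[mask].astype(float)
        w = np.where(w > 0, w, 0.0)
    else:
        w = np.ones_like(t)
    fit = sm.WLS(y, X, weights=w).fit()
    log_lam, gam = fit.params
    lam = float(np.exp(log_lam))
    gam = float(gam)
    if not (lam > 0 and gam > 0):
        raise ValueError("curve-point fit produced non-positive parameters")
    se = fit.bse
    lam_se = lam * float(se[0])  # delta method from log-scale intercept
    gam_se = float(se[1])
    z = stats.norm.ppf(0.975)
    return WeibullParams(
        lam, gam, lam_se, gam_se,
        (lam * np.exp(-z * se[0]), lam * np.exp(z * se[0])),
        (gam - z * gam_se, gam + z * gam_se),
    )


def fit_weibull(data: Union[PseudoIPD, SurvivalCurvePoints]) -> WeibullParams:
    """Fit Weibull scale/shape parameters to survival data.

    ``PseudoIPD`` input uses right-censored maximum likelihood with
    observed-information standard errors; ``SurvivalCurvePoints`` input uses
    (weighted) least squares on the complementary-log-log scale.

    Requires at least 10 observations/points and, for IPD, at least one event.
    """
    if isinstance(data, PseudoIPD):
        if len(data) < 10:
            raise ValueError("need at least 10 observations")
        return _fit_ipd_mle(data)
    if isinstance(data, SurvivalCurvePoints):
        if len(data.times) < 10:
            raise ValueError("need at least 10 curve points")
        return _fit_curve_points(data)
    raise TypeError(f"unsupported data type: {type(data)!r}")
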