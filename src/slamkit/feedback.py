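"""Positive-feedback accumulation model for protein at the furrow canal.

An exploratory, deliberately minimal ODE contrasting two accumulation
hypotheses for a protein P at its target compartment:

* feedback: dP/dt = (alpha + beta·P) · (1 − P/Pmax)
* linear:   dP/dt = alpha · (1 − P/Pmax)

alpha (a.u./min) is basal, protein-independent delivery; beta (1/min) lumps
the feedback loop (protein recruits its own mRNA, boosting local synthesis)
into a single coefficient; the saturation factor (1 − P/Pmax) turns
accumulation off as full levels Pmax are approached. With beta = 0 the modes
coincide. In the Pmax → inf limit the feedback solution is the exponential
P(t) = (P0 + alpha/beta)·e^(beta·t) − alpha/beta, which the integrator must
reproduce (convergence check).

Integration is deterministic fixed-step classical Runge–Kutta (RK4). The
``switchiness`` score — max instantaneous slope over mean slope of the rise —
quantifies how step-like a trace is (1 for a straight-line rise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FeedbackParams",
    "SimTrace",
    "simulate_accumulation",
    "switchiness",
    "match_linear_alpha",
]

MODES = ("feedback", "linear")


@dataclass(frozen=True)
class FeedbackParams:
    """Model parameters; units: a.u. for protein amounts, minutes for time."""

    alpha: float = 0.2  # basal accumulation rate, a.u./min
    beta: float = 0.6  # feedback coefficient, 1/min
    Pmax: float = 100.0  # saturation level, a.u. (may be math.inf)
    P0: float = 0.0  # initial protein, a.u.
    T: float = 15.0  # duration, min
    dt: float = 0.01  # integration step, min

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not self.Pmax > 0:
            raise ValueError("Pmax must be > 0")
        if not (0 <= self.P0 < self.Pmax):
            raise ValueError("require 0 <= P0 < Pmax")
        if not self.dt > 0 or not self.T > 0:
            raise ValueError("T and dt must be > 0")


@dataclass(frozen=True)
class SimTrace:
    times: np.ndarray  # minutes
    P: np.ndarray  # a.u.


class StepSizeError(RuntimeError):
    """dt too large: the trajectory overshot Pmax by more than 1%."""


def _rhs(P: float, params: FeedbackParams, mode: str) -> float:
    sat = 1.0 if math.isinf(params.Pmax) else 1.0 - P / params.Pmax
    rate = params.alpha + (params.beta * P if mode == "feedback" else 0.0)
    return rate * sat


def simulate_accumulation(params: FeedbackParams, mode: str = "feedback") -> SimTrace:
    """Integrate the chosen accumulation mode with fixed-step RK4."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    n = int(round(params.T / params.dt))
    times = np.linspace(0.0, n * params.dt, n + 1)
    P = np.empty(n + 1)
    P[0] = params.P0
    dt = params.dt
    for i in range(n):
        p = float(P[i])
        try:
            k1 = _rhs(p, params, mode)
            k2 = _rhs(p + dt / 2 * k1, params, mode)
            k3 = _rhs(p + dt / 2 * k2, params, mode)
            k4 = _rhs(p + dt * k3, params, mode)
            step = p + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        except OverflowError as err:  # runaway intermediate stage
            raise StepSizeError(f"integration diverged at t={times[i]:.3f}; reduce dt") from err
        P[i + 1] = step
        if not math.isfinite(step) or (
            not math.isinf(params.Pmax) and step > params.Pmax * 1.01
        ):
            raise StepSizeError(
                f"P overshot Pmax by >1% at t={times[i + 1]:.3f}; reduce dt"
            )
    return SimTrace(times=times, P=P)


def switchiness(trace: SimTrace) -> float:
    """(max instantaneous slope) / (mean slope of the rise); >= 1.

    The mean slope is the net rise divided by the trace span. Requires >= 3
    points and a net increase; flat traces are undefined.
    """
    t, P = trace.times, trace.P
    if t.size < 3:
        raise ValueError("need >= 3 points")
    net = P[-1] - P[0]
    if net <= 0:
        raise ValueError("switchiness undefined for a trace with no net increase")
    slopes = np.diff(P) / np.diff(t)
    return float(slopes.max() / (net / (t[-1] - t[0])))


def match_linear_alpha(params: FeedbackParams, target_PT: float) -> FeedbackParams:
    """Linear-mode parameters reaching the same endpoint P(T) = target_PT.

    Uses the closed-form linear-mode solution
    P(t) = Pmax − (Pmax − P0)·exp(−alpha·t/Pmax). Only meaningful while the
    endpoint is strictly below Pmax.
    """
    if math.isinf(params.Pmax):
        alpha = (target_PT - params.P0) / params.T
    else:
        if not (params.P0 < target_PT < params.Pmax):
            raise ValueError("endpoint must lie strictly between P0 and Pmax")
        alpha = (
            -params.Pmax
            / params.T
            * math.log((params.Pmax - target_PT) / (params.Pmax - params.P0))
        )
    return replace(params, alpha=alpha, beta=0.0)


# Documented sweep for the feedback-vs-linear contrast: the feedback-dominated
# regime (beta*Pmax well above alpha), with the window inside or just reaching
# saturation. Outside this regime the two models coincide by construction and
# the contrast carries no information.
SWITCHINESS_GRID = tuple(
    FeedbackParams(alpha=a, beta=b, Pmax=pm, P0=p0, T=15.0, dt=0.01)
    for a in (0.1, 0.2, 0.5)
    for b in (0.3, 0.6, 1.0)
    for pm in (50.0, 100.0)
    for p0 in (0.0, 2.0)
)
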