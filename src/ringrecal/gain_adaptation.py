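"""Gain-update rules, error dynamics, and recalibration-condition checkers.

With a constant visual gain, the reduced model can be rewritten in error
coordinates ``theta~ = theta* - theta`` (wrapped positional error) and
``k~ = k* - k0`` (gain error)::

    dtheta~/dt = -beta(theta~) + k~ * v - kac(theta) * v
    dk~/dt     = -g0(k0, theta~, v)

A gain-update rule ``g0`` achieves *complete* recalibration only if it moves
``k0`` in the direction of the product ``theta~ * v`` near the origin
(necessary sign condition); allowing a steady-state error ``theta~_inf``
generalizes the condition to ``sign(g0) == sign((theta~ - theta~_inf) * v)``.
A positive slope of ``g0`` with respect to ``theta~ * v`` at its zero set is
sufficient for (possibly partial) recalibration.  These conditions are
verified numerically here rather than symbolically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .angles import wrap_difference
from .reduced_model import FeedbackFunction

__all__ = [
    "GainRule",
    "ErrorState",
    "gain_rule_linear",
    "gain_rule_velocity_biased",
    "gain_rule_cubic",
    "gain_rule_sign_flipped",
    "error_dynamics_step",
    "check_necessary_condition",
    "check_sufficient_condition",
    "check_rule",
    "mechanistic_probe_report",
]


@dataclass
class GainRule:
    """A pluggable gain-update rule ``dk0/dt = g0(k0, theta~, v)``."""

    g0: Callable[[float, float, float], float]
    params: dict = field(default_factory=dict)
    label: str = "rule"

    def __call__(self, k0, theta_tilde, v):
        return self.g0(k0, theta_tilde, v)


def gain_rule_linear(mu: float) -> GainRule:
    """Simplest recalibrating rule: ``g0 = mu * theta~ * v`` (complete recalibration)."""
    if mu <= 0:
        raise ValueError("learning rate mu must be positive")
    return GainRule(
        g0=lambda k0, err, v: mu * err * v, params={"mu": mu}, label="linear"
    )


def gain_rule_velocity_biased(mu: float, eta: float) -> GainRule:
    """Rule with a velocity-squared bias: ``g0 = mu * (eta*k0*v^2 + theta~*v)``.

    Mimics the plastic network, where the rotation rings' error code is
    contaminated by their velocity modulation; for ``eta > 0`` recalibration
    is partial, settling at ``theta~_inf ~= eta * v`` under constant velocity.
    """
    if mu <= 0:
        raise ValueError("learning rate mu must be positive")
    return GainRule(
        g0=lambda k0, err, v: mu * (eta * k0 * v**2 + err * v),
        params={"mu": mu, "eta": eta},
        label="velocity_biased",
    )


def gain_rule_cubic(mu: float) -> GainRule:
    """Cubic rule ``g0 = mu * (theta~ * v)^3``: necessary condition only.

    Its slope with respect to ``theta~ * v`` vanishes at the origin, so it
    fails the sufficient condition despite matching signs.
    """
    if mu <= 0:
        raise ValueError("learning rate mu must be positive")
    return GainRule(
        g0=lambda k0, err, v: mu * (err * v) ** 3, params={"mu": mu}, label="cubic"
    )


def gain_rule_sign_flipped(mu: float) -> GainRule:
    """Anti-rule ``g0 = -mu * theta~ * v``; violates the necessary condition."""
    if mu <= 0:
        raise ValueError("learning rate mu must be positive")
    return GainRule(
        g0=lambda k0, err, v: -mu * err * v, params={"mu": mu}, label="sign_flipped"
    )


@dataclass
class ErrorState:
    """Positional and gain error of the recalibration dynamics."""

    theta_tilde: float = 0.0
    k_tilde: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        self.theta_tilde = float(wrap_difference(self.theta_tilde))


def error_dynamics_step(
    state: ErrorState,
    v: float,
    beta: FeedbackFunction,
    kac_at_theta: float,
    rule: GainRule,
    k0: float,
    dt: float,
    method: str = "rk4",
) -> ErrorState:
    """One integration step of the error dynamics.

    ``k0`` is the current spatial-average gain (so the rule can depend on it);
    within the step it is co-updated consistently with ``k~`` since
    ``k0 = k* - k~``.  The RK4 stages mirror ``simulate_reduced`` exactly, so
    the two integrators agree to machine precision under the change of
    variables ``theta~ = theta* - theta``, ``k~ = k* - k0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    def deriv(y):
        err, ktl = y
        d_err = -beta(wrap_difference(err)) + ktl * v - kac_at_theta * v
        # within-step gain consistent with the gain error: k0_stage = k0 - (ktl - k~_0)
        d_ktl = -rule.g0(k0 - (ktl - state.k_tilde), wrap_difference(err), v)
        return np.array([d_err, d_ktl])

    y = np.array([state.theta_tilde, state.k_tilde])
    if method == "rk4":
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    elif method == "euler":
        y = y + dt * deriv(y)
    else:
        raise ValueError("method must be 'rk4' or 'euler'")
    return ErrorState(theta_tilde=y[0], k_tilde=y[1], t=state.t + dt)


# ---------------------------------------------------------------------------
# Condition checkers


def _sign(x: float, tol: float = 0.0) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


def check_necessary_condition(
    rule: GainRule,
    v_values=None,
    theta_tilde_inf=0.0,
    k0: float = 1.0,
    neighborhood: float = 0.5,
    n_points: int = 21,
) -> dict:
    """Check the sign requirement ``sign(g0) == sign((theta~ - theta~_inf) * v)``.

    Evaluates the rule on a grid of velocities and positional errors in a
    neighborhood of the steady-state error (which may be a constant or a
    callable of ``v``, e.g. ``eta * v`` for partially recalibrating rules).
    Grid points where either factor is exactly zero are excluded.  Returns a
    report fragment with the pass flag and any failing grid points.
    """
    if v_values is None:
        v_values = np.linspace(-1.0, 1.0, 9)
    v_values = [float(v) for v in np.atleast_1d(v_values) if v != 0.0]
    inf_of_v = theta_tilde_inf if callable(theta_tilde_inf) else (lambda v: float(theta_tilde_inf))
    failures = []
    n_checked = 0
    for v in v_values:
        err_inf = float(inf_of_v(v))
        errs = err_inf + np.linspace(-neighborhood, neighborhood, n_points)
        for err in errs:
            lhs = _sign(rule.g0(k0, err, v), tol=1e-14)
            rhs = _sign((err - err_inf) * v, tol=1e-14)
            if rhs == 0:
                continue
            n_checked += 1
            if lhs != rhs:
                failures.append({"v": v, "theta_tilde": float(err), "g0_sign": lhs})
    return {
        "rule": rule.label,
        "passed": len(failures) == 0,
        "n_checked": n_checked,
        "failures": failures[:20],
        "grid": {
            "v_values": v_values,
            "neighborhood": neighborhood,
            "n_points": n_points,
        },
    }


def check_sufficient_condition(
    rule: GainRule,
    v0: float,
    k0: float = 1.0,
    step: float = 1e-4,
    tol: float = 1e-8,
) -> dict:
    """Check the slope condition ``d g0 / d(theta~ v) > 0`` at the rule's zero set.

    Locates the zero of ``g0`` in ``theta~`` near the origin (for the given
    ``v0`` and ``k0``), then estimates the slope by central difference.
    """
    if v0 == 0.0:
        raise ValueError("v0 must be nonzero")

    f = lambda err: rule.g0(k0, err, v0)
    err_zero = 0.0
    if f(0.0) != 0.0:
        lo, hi = -np.pi / 2, np.pi / 2
        try:
            if f(lo) * f(hi) < 0:
                err_zero = float(optimize.brentq(f, lo, hi))
        except ValueError:
            pass
    slope = (f(err_zero + step) - f(err_zero - step)) / (2.0 * step) / v0
    return {
        "rule": rule.label,
        "passed": bool(slope > tol),
        "slope": float(slope),
        "theta_tilde_zero": float(err_zero),
        "v0": float(v0),
    }


def check_rule(
    rule: GainRule,
    v_values=None,
    theta_tilde_inf=0.0,
    v0: float = 0.5,
    k0: float = 1.0,
) -> dict:
    """Full ConditionReport for a rule: complete/generalized necessary + sufficient."""
    necessary_complete = check_necessary_condition(
        rule, v_values=v_values, theta_tilde_inf=0.0, k0=k0
    )
    necessary_generalized = check_necessary_condition(
        rule, v_values=v_values, theta_tilde_inf=theta_tilde_inf, k0=k0
    )
    sufficient = check_sufficient_condition(rule, v0=v0, k0=k0)
    return {
        "rule": rule.label,
        "params": dict(rule.params),
        "necessary_complete": necessary_complete,
        "necessary_generalized": necessary_generalized,
        "sufficient_slope": sufficient,
    }


# ---------------------------------------------------------------------------
# Mechanistic probes


def estimate_steady_error(trajectory, window_frac: float = 0.1) -> float:
    """Trailing-window circular mean of ``theta_tilde`` (steady-state estimate)."""
    frame = trajectory.frame if hasattr(trajectory, "frame") else trajectory
    err = frame["theta_tilde"].to_numpy()
    n_tail = max(1, int(round(window_frac * err.shape[0])))
    tail = err[-n_tail:]
    return float(np.arctan2(np.mean(np.sin(tail)), np.mean(np.cos(tail))))


def mechanistic_probe_report(trajectory, seed: int = 0, min_samples: int = 50) -> dict:
    """Rank-correlation probes of the error-rate codes in a simulation.

    Computes Spearman correlations between (a) CW/CCW rotation-ring mean
    rates and the instantaneous positional error ``theta~`` (the error code
    required for plasticity in the velocity pathway), and (b) slow candidate
    variables (the gain trace, if present) and the time-integral of
    ``theta~`` (the code required for plasticity elsewhere).  A seeded
    time-shuffle control is reported alongside each correlation.
    """
    frame = trajectory.frame if hasattr(trajectory, "frame") else trajectory
    if len(frame) < min_samples:
        raise ValueError(f"trajectory too short: need >= {min_samples} samples")
    rng = np.random.default_rng(seed)
    err = frame["theta_tilde"].to_numpy()
    t = frame["t"].to_numpy()
    report: dict = {"n_samples": int(len(frame))}

    def _spearman(x, y):
        rho = stats.spearmanr(x, y).statistic
        return float(rho) if np.isfinite(rho) else 0.0

    instantaneous = {}
    for col, key in [("mean_rate_cw", "cw"), ("mean_rate_ccw", "ccw")]:
        if col in frame.columns:
            rates = frame[col].to_numpy()
            instantaneous[key] = {
                "spearman_vs_error": _spearman(rates, err),
                "shuffled_control": _spearman(rates, rng.permutation(err)),
            }
    if instantaneous:
        report["instantaneous_error_code"] = instantaneous

    integral = {}
    err_integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (err[1:] + err[:-1]) * np.diff(t))]
    )
    for col in ("k0", "gain_estimate", "mean_rate_c"):
        if col in frame.columns:
            vals = frame[col].to_numpy()
            integral[col] = {
                "spearman_vs_error_integral": _spearman(vals, err_integral),
                "shuffled_control": _spearman(vals, rng.permutation(err_integral)),
            }
    if integral:
        report["integral_error_code"] = integral
    return report
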