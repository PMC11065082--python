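"""Generators for velocity profiles and visual-landmark protocols.

The simulated environment is a circular track of unit circumference mapped
1:1 onto the ring's angular coordinate, so the animal's velocity is expressed
directly in rad/s and the PI gain is dimensionless.  Velocity profiles are
sampled traces with exact zeros during pauses; landmark protocols specify a
piecewise-constant visual gain ``k*`` and on/off intervals.  All stochastic
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_core import NetworkParams

__all__ = [
    "VelocityProfile",
    "VisualProtocol",
    "make_velocity_profile",
    "velocity_neuron_rates",
    "make_visual_protocol",
]

#: Default pause windows of the pause-resume profile (s): 30-s stops around
#: minutes 5 and 20 of a 30-minute session.
DEFAULT_PAUSES = ((300.0, 330.0), (1200.0, 1230.0))


@dataclass
class VelocityProfile:
    """Sampled animal velocity trace ``v(t)`` in rad/s on the unit-circumference track."""

    times: np.ndarray
    v: np.ndarray
    kind: str = "custom"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.times.shape != self.v.shape:
            raise ValueError("times and v must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        """Linearly interpolated velocity at time ``t`` (exact 0 inside pauses)."""
        return np.interp(t, self.times, self.v)

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame({"t": self.times, "v": self.v}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind="from_csv"):
        import pandas as pd

        df = pd.read_csv(path)
        return cls(times=df["t"].to_numpy(), v=df["v"].to_numpy(), kind=kind)


def make_velocity_profile(
    kind: str,
    duration: float = 1800.0,
    mean_v: float = 0.5,
    seed: int = 0,
    sample_dt: float = 0.05,
    pauses=DEFAULT_PAUSES,
) -> VelocityProfile:
    """Build a velocity fixture of one of three kinds.

    ``constant``: ``v = mean_v`` throughout.
    ``pause_resume``: ``mean_v`` with exact zero-velocity intervals (defaults:
    ``[300, 330]`` and ``[1200, 1230]`` s of a 30-minute session).
    ``smoothed_random``: positive, low-pass filtered (~0.1 Hz cutoff)
    Ornstein-Uhlenbeck-style fluctuation around ``mean_v`` with the same
    pauses; a behavioral *fixture*, not a locomotion model.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = np.arange(0.0, duration + 0.5 * sample_dt, sample_dt)
    if kind == "constant":
        v = np.full_like(times, mean_v)
        pauses = ()
    elif kind == "pause_resume":
        v = np.full_like(times, mean_v)
    elif kind == "smoothed_random":
        rng = np.random.default_rng(seed)
        tau = 1.0 / (2.0 * np.pi * 0.1)  # ~0.1 Hz low-pass
        x = np.empty_like(times)
        x[0] = 0.0
        sig = 0.5 * mean_v
        a = np.exp(-sample_dt / tau)
        noise = rng.standard_normal(times.shape[0]) * sig * np.sqrt(1 - a**2)
        for i in range(1, times.shape[0]):
            x[i] = a * x[i - 1] + noise[i]
        v = np.maximum(mean_v + x, 0.0)
    else:
        raise ValueError(f"unknown velocity profile kind: {kind!r}")
    for start, stop in pauses:
        # insert exact boundary samples so linear interpolation is exactly
        # zero throughout the closed pause interval
        for edge in (float(start), float(stop)):
            idx = int(np.searchsorted(times, edge))
            if idx >= times.shape[0] or times[idx] != edge:
                times = np.insert(times, idx, edge)
                v = np.insert(v, idx, 0.0)
        v[(times >= start) & (times <= stop)] = 0.0
    return VelocityProfile(
        times=times,
        v=v,
        kind=kind,
        seed=seed,
        meta={"mean_v": mean_v, "pauses": tuple(tuple(map(float, p)) for p in pauses)},
    )


def velocity_neuron_rates(v: float, params: NetworkParams) -> tuple[float, float]:
    """Rectified (CW, CCW) velocity-neuron rates: ``(u_cw0 - a*v, u_ccw0 + a*v)``."""
    return (
        max(0.0, params.u_cw0 - params.alpha_cw * v),
        max(0.0, params.u_ccw0 + params.alpha_ccw * v),
    )


@dataclass
class VisualProtocol:
    """Visual gain schedule and landmark on/off intervals.

    ``k_star`` is either a constant or a list of ``(t_start, value)`` pairs
    defining a piecewise-constant schedule from t=0.  ``off_intervals`` are
    non-overlapping ``(start, stop)`` windows with the landmarks extinguished
    (no visual current; ``theta*`` continues to advance silently).
    """

    k_star: float | tuple = 1.0
    off_intervals: tuple = ()

    def __post_init__(self):
        ivals = sorted(tuple(map(float, p)) for p in self.off_intervals)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping off-intervals: {(a0, a1)} and {(b0, b1)}")
        for a0, a1 in ivals:
            if a1 <= a0:
                raise ValueError(f"empty off-interval {(a0, a1)}")
        self.off_intervals = tuple(ivals)

    def k_star_at(self, t: float) -> float:
        if np.isscalar(self.k_star):
            return float(self.k_star)
        value = None
        for t_start, val in self.k_star:
            if t >= t_start:
                value = val
        if value is None:
            raise ValueError(f"k_star schedule does not cover t={t}")
        return float(value)

    def active_at(self, t: float) -> bool:
        return not any(a0 <= t < a1 for a0, a1 in self.off_intervals)


def make_visual_protocol(k_star=1.0, landmark_off_intervals=(), horizon=None) -> VisualProtocol:
    """Validated landmark protocol; off-intervals must fit within ``horizon`` if given."""
    if horizon is not None:
        for a0, a1 in landmark_off_intervals:
            if a0 < 0 or a1 > horizon:
                raise ValueError(f"off-interval {(a0, a1)} outside horizon [0, {horizon}]")
    return VisualProtocol(k_star=k_star, off_intervals=tuple(landmark_off_intervals))
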