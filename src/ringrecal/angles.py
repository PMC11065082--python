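"""Circular-coordinate helpers.

Convention used throughout the package: angles in radians, positions on the
ring in ``[0, 2*pi)``, counter-clockwise positive, signed differences wrapped
to ``(-pi, pi]``.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_position(x):
    """Wrap an angle (scalar or array) into ``[0, 2*pi)``."""
    out = np.mod(x, TWO_PI)
    # np.mod can round up to the period itself for tiny negative inputs
    return np.where(out >= TWO_PI, 0.0, out)[()] if np.ndim(out) == 0 else np.where(out >= TWO_PI, 0.0, out)


def wrap_difference(x):
    """Wrap an angular difference into ``(-pi, pi]``."""
    return np.pi - np.mod(np.pi - np.asarray(x), TWO_PI)


def circular_mean(x, weights=None):
    """Circular mean of angles, returned in ``[0, 2*pi)``."""
    x = np.asarray(x, dtype=float)
    if weights is None:
        s, c = np.sin(x).sum(), np.cos(x).sum()
    else:
        w = np.asarray(weights, dtype=float)
        s, c = (w * np.sin(x)).sum(), (w * np.cos(x)).sum()
    if s == 0.0 and c == 0.0:
        raise ValueError("circular mean undefined for zero resultant")
    return float(np.mod(np.arctan2(s, c), TWO_PI))


def unwrap_trajectory(theta):
    """Unwrap a sampled circular trajectory into a continuous real-valued one."""
    return np.unwrap(np.asarray(theta, dtype=float))
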