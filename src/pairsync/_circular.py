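"""Circular (phase-angle) helpers shared across modules.

All phases are radians. The wrapping convention is the half-open interval
(-pi, pi], matching the range of ``numpy.angle`` so that analytic-signal
phases and wrapped model phases are directly comparable.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap(phi):
    """Wrap angle(s) to (-pi, pi]; -pi maps to +pi."""
    w = np.mod(phi, TWO_PI)  # [0, 2*pi)
    if np.ndim(w):
        w = np.asarray(w).copy()
        w[w > np.pi] -= TWO_PI
        return w
    return w - TWO_PI if w > np.pi else w


def circular_distance(a, b):
    """Absolute wrapped distance between angles, in [0, pi]."""
    return np.abs(wrap(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def circular_mean(phi):
    """Mean direction of a sample of angles, in (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    return float(np.angle(np.mean(np.exp(1j * phi))))
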