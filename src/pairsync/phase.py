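"""Instantaneous phase extraction from behavioral state series.

The 0/0.5/1 state series is treated as a crude oscillation between feeding
(0) and vigilance (1). It is smoothed with a zero-phase lowpass filter at
2.78 Hz -- the fastest plausible head-oscillation rate, from a maximal head
angular velocity of 1000 deg/s (1000/360 = 2.78 cycles/s) -- then centered
at 0.5 and passed through the Hilbert transform. The angle of the analytic
signal gives the instantaneous phase, wrapped to (-pi, pi]; unwrapping uses
the smallest-jump rule (add +/-2*pi whenever a step exceeds pi).

Filter realization: finite impulse response, Kaiser window sized for >= 40 dB
stopband attenuation over the transition band [cutoff, 1.25*cutoff], applied
forward and backward (``filtfilt``) so transitions are not shifted in time.

The analytic signal is distorted near the series edges; a configurable
``edge_trim_s`` (default 0.5 s) marks the margins to exclude from any
regression on the phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from ._circular import TWO_PI, wrap
from .events import StateSeries

DEFAULT_CUTOFF_HZ = 2.78
DEFAULT_CENTER = 0.5
DEFAULT_EDGE_TRIM_S = 0.5


class BoutTooShortError(ValueError):
    """Series shorter than the filter warm-up length."""


class NoOscillationError(ValueError):
    """Signal is constant after centering; phase is undefined."""


@dataclass
class PhaseSeries:
    """Framewise instantaneous phase of one oscillator.

    ``wrapped`` lies in (-pi, pi]; ``unwrapped`` is the cumulative phase with
    the 2*pi jumps removed.
    """

    rate_hz: float
    wrapped: np.ndarray
    unwrapped: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.wrapped = np.asarray(self.wrapped, dtype=float)
        self.unwrapped = np.asarray(self.unwrapped, dtype=float)
        if self.wrapped.shape != self.unwrapped.shape:
            raise ValueError("wrapped and unwrapped must have equal length")

    def __len__(self) -> int:
        return self.wrapped.size


@dataclass
class PhaseDifferenceSeries:
    """Pairwise phase difference Phi = theta_2 - theta_1 over frames."""

    rate_hz: float
    phi: np.ndarray
    phi_wrapped: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.phi_wrapped = np.asarray(self.phi_wrapped, dtype=float)
        if self.phi.shape != self.phi_wrapped.shape:
            raise ValueError("phi and phi_wrapped must have equal length")

    def __len__(self) -> int:
        return self.phi.size

    @property
    def dt_s(self) -> float:
        return 1.0 / self.rate_hz


@lru_cache(maxsize=32)
def lowpass_taps(rate_hz: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Kaiser-window FIR taps for the standard lowpass contract.

    >= 40 dB stopband beyond 1.25*cutoff, passband edge at the cutoff;
    the -6 dB point sits mid-transition.
    """
    nyq = rate_hz / 2.0
    width = 0.25 * cutoff_hz
    numtaps, beta = sps.kaiserord(40.0, width / nyq)
    numtaps |= 1  # odd length, symmetric type-I filter
    return sps.firwin(numtaps, (cutoff_hz + 0.125 * cutoff_hz) / nyq,
                      window=("kaiser", beta))


def lowpass(series, rate_hz: float | None = None,
            cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase lowpass filter a state series (or raw array).

    Output length equals input length; DC is preserved. Raises
    :class:`BoutTooShortError` when the series cannot accommodate the
    forward-backward filter's edge padding.
    """
    if isinstance(series, StateSeries):
        values, rate_hz = series.values, series.rate_hz
    else:
        values = np.asarray(series, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for raw arrays")
    if rate_hz <= 2.0 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    taps = lowpass_taps(float(rate_hz), float(cutoff_hz))
    padlen = 3 * len(taps)
    if values.size <= padlen:
        raise BoutTooShortError(
            f"bout too short to filter ({values.size} frames <= warm-up {padlen})")
    return sps.filtfilt(taps, [1.0], values, padlen=padlen)


def analytic_phase(filtered, rate_hz: float, center: float = DEFAULT_CENTER,
                   source_id: str = "") -> PhaseSeries:
    """Instantaneous phase of the analytic signal of (series - center).

    For a pure cosine input the unwrapped phase advances linearly at the
    cosine's angular frequency. A constant input has no defined phase and is
    rejected.
    """
    x = np.asarray(filtered, dtype=float) - center
    if x.size < 4:
        raise ValueError("series too short for the analytic signal")
    if np.ptp(x) < 1e-12:
        raise NoOscillationError("no oscillation: series constant after centering")
    wrapped = np.angle(sps.hilbert(x))
    unwrapped = np.unwrap(wrapped)
    return PhaseSeries(rate_hz=rate_hz, wrapped=wrapped, unwrapped=unwrapped,
                       source_id=source_id)


def state_series_phase(series: StateSeries, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                       center: float = DEFAULT_CENTER) -> PhaseSeries:
    """Convenience: lowpass + analytic phase for a StateSeries."""
    return analytic_phase(lowpass(series, cutoff_hz=cutoff_hz),
                          series.rate_hz, center=center,
                          source_id=series.individual_id)


def phase_difference(p1: PhaseSeries, p2: PhaseSeries) -> PhaseDifferenceSeries:
    """Phi = theta_2 - theta_1, unwrapped, plus its wrapped form."""
    if len(p1) != len(p2):
        raise ValueError("phase series length mismatch")
    if p1.rate_hz != p2.rate_hz:
        raise ValueError("phase series rate mismatch")
    phi = p2.unwrapped - p1.unwrapped
    return PhaseDifferenceSeries(rate_hz=p1.rate_hz, phi=phi, phi_wrapped=wrap(phi),
                                 source_id=f"{p2.source_id}-{p1.source_id}")


def count_oscillations(p: PhaseSeries) -> float:
    """Net number of complete cycles, (unwrapped end - start)/2*pi, >= 0."""
    return max(0.0, float(p.unwrapped[-1] - p.unwrapped[0]) / TWO_PI)


def edge_trim_slice(n: int, rate_hz: float,
                    edge_trim_s: float = DEFAULT_EDGE_TRIM_S) -> slice:
    """Index slice excluding the edge-distorted margins of a phase series."""
    k = int(round(edge_trim_s * rate_hz))
    if 2 * k >= n:
        return slice(0, n)
    return slice(k, n - k)
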