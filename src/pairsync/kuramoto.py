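"""Two-oscillator Kuramoto machinery: simulation, fitting, bifurcation
analysis, time to anti-phase synchrony and the mean-absolute-error metric.

Model. Two phase oscillators theta_1, theta_2 obey

    dtheta_1/dt = w_1 + (K/2) sin(theta_2 - theta_1)
    dtheta_2/dt = w_2 + (K/2) sin(theta_1 - theta_2)

so the phase difference Phi = theta_2 - theta_1 follows

    dPhi/dt = Omega - K sin(Phi),    Omega = w_2 - w_1.

Negative K drives anti-phase locking (Phi -> near pi), positive K in-phase.
Setting dPhi/dt = 0 gives sin(Phi) = Omega/K; real equilibria exist only for
|K/Omega| >= 1, and saddle-node bifurcations sit at K/Omega = -1 and +1. The
anti-phase branch therefore becomes attainable exactly when K crosses the
critical coupling K_c = -|Omega|.

Units. Fitting works on raw phase-difference increments per second
(rad/frame divided by dt), the convention in which behavioral studies quote
K and Omega in "Hz". All internal dynamics use rad/s, numerically identical
to that convention; cycles/s are available via the ``*_cycles`` properties
(divide by 2*pi). Natural frequencies in :class:`KuramotoParams` are given
in cycles/s, as natural frequencies usually are, and converted internally.

Fitting. Discretizing with Euler's method at step dt,

    (Phi(t) - Phi(t-1))/dt = Omega - K sin(Phi(t-1)),

so ordinary least squares of the left side on sin(Phi(t-1)) yields
K = -slope and Omega = intercept. On noiseless Euler-simulated data the
regression inverts the update exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate as spi
from scipy import stats as spst

from ._circular import TWO_PI, circular_distance, wrap
from .phase import (DEFAULT_EDGE_TRIM_S, PhaseDifferenceSeries, PhaseSeries,
                    edge_trim_slice)

DEFAULT_DT_S = 0.04  # 25 fps video
SYNC_TOL_RAD = 0.01  # "arrived" when within this of the stable equilibrium


def head_speed_to_cycles(deg_per_s: float, deg_per_cycle: float = 360.0) -> float:
    """Convert a head angular velocity to oscillation cycles per second.

    A maximal head speed of 1000 deg/s corresponds to 2.78 cycles/s, the
    lowpass cutoff used in phase extraction.
    """
    return deg_per_s / deg_per_cycle


def frame_rate_to_dt(fps: float) -> float:
    """Euler step implied by a video frame rate: 25 fps -> 0.04 s."""
    return 1.0 / fps


class DegenerateRegressorError(ValueError):
    """sin(Phi) carries no variation; the regression is unidentifiable."""


@dataclass
class KuramotoParams:
    """Ground-truth parameters for simulating the two-oscillator model.

    ``omega1_cycles``/``omega2_cycles`` are natural frequencies in cycles/s;
    ``K`` is the coupling constant in the fitted (rad/s) convention.
    """

    omega1_cycles: float
    omega2_cycles: float
    K: float
    duration_s: float
    dt_s: float = DEFAULT_DT_S
    theta0: tuple[float, float] = (0.0, np.pi / 2)

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.duration_s < self.dt_s:
            raise ValueError("duration_s must be at least one step")

    @property
    def Omega(self) -> float:
        """Natural-frequency difference w_2 - w_1 in rad/s."""
        return TWO_PI * (self.omega2_cycles - self.omega1_cycles)


NOT_REACHED = "not reached"


@dataclass
class KuramotoFit:
    """Per-bout estimates from the phase-difference regression.

    ``K`` and ``Omega`` are in the fitted rad/s convention; ``Kc = -|Omega|``.
    ``T_s`` is the predicted time to anti-phase synchrony (None when K >= Kc,
    i.e. synchrony unattainable; +inf when the initial phase sits exactly on
    the unstable equilibrium). ``T_source`` records whether the closed form
    or the integration oracle produced it.
    """

    K: float
    Omega: float
    Kc: float
    T_s: float | None
    mae_rad: float
    slope: float
    intercept: float
    rmse: float
    n_frames_used: int
    T_source: str = "closed_form"
    stderr_slope: float = np.nan
    stderr_intercept: float = np.nan

    @property
    def K_cycles(self) -> float:
        return self.K / TWO_PI

    @property
    def Omega_cycles(self) -> float:
        return self.Omega / TWO_PI

    @property
    def antiphase_attainable(self) -> bool:
        return self.K < self.Kc

    @property
    def T_reached(self) -> bool:
        return self.T_s is not None and np.isfinite(self.T_s)


def simulate_classic(params: KuramotoParams, return_phi: bool = True):
    """Forward-Euler simulation of the two coupled oscillators.

    Returns (theta1, theta2) as :class:`PhaseSeries`, plus the Phi series
    when ``return_phi``. With K = 0 each phase advances linearly at its
    natural frequency.
    """
    if abs(params.K) * params.dt_s > 0.5:
        warnings.warn("|K|*dt > 0.5: Euler step too coarse for stability",
                      RuntimeWarning, stacklevel=2)
    n = int(round(params.duration_s / params.dt_s)) + 1
    w1 = TWO_PI * params.omega1_cycles
    w2 = TWO_PI * params.omega2_cycles
    K, dt = params.K, params.dt_s
    th1 = np.empty(n)
    th2 = np.empty(n)
    th1[0], th2[0] = params.theta0
    for f in range(1, n):
        d = th2[f - 1] - th1[f - 1]
        s = np.sin(d)
        th1[f] = th1[f - 1] + dt * (w1 + 0.5 * K * s)
        th2[f] = th2[f - 1] + dt * (w2 - 0.5 * K * s)
    rate = 1.0 / dt
    p1 = PhaseSeries(rate_hz=rate, wrapped=wrap(th1), unwrapped=th1, source_id="osc1")
    p2 = PhaseSeries(rate_hz=rate, wrapped=wrap(th2), unwrapped=th2, source_id="osc2")
    if not return_phi:
        return p1, p2
    phi = th2 - th1
    return p1, p2, PhaseDifferenceSeries(rate_hz=rate, phi=phi, phi_wrapped=wrap(phi))


def fit_classic(phi: PhaseDifferenceSeries, dt_s: float | None = None,
                edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
                min_pairs: int = 10) -> KuramotoFit:
    """Estimate (K, Omega) by OLS on the Euler-discretized phase dynamics.

    The response is the per-second unwrapped phase-difference increment; the
    regressor is sin of the wrapped Phi one frame earlier. K = -slope,
    Omega = intercept. K_c, T and the MAE are filled in from the fitted
    parameters.
    """
    dt = dt_s if dt_s is not None else phi.dt_s
    sl = edge_trim_slice(len(phi), 1.0 / dt, edge_trim_s)
    phi_u = phi.phi[sl]
    phi_w = phi.phi_wrapped[sl]
    if phi_u.size - 1 < min_pairs:
        raise ValueError(f"too few frames after trimming ({phi_u.size})")
    y = np.diff(phi_u) / dt
    x = np.sin(phi_w[:-1])
    if np.ptp(x) < 1e-12:
        raise DegenerateRegressorError("degenerate regressor: sin(Phi) is constant")
    res = spst.linregress(x, y)
    K = -res.slope
    Omega = res.intercept
    resid = y - (res.intercept + res.slope * x)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    Kc = critical_coupling(Omega)
    T_s, T_source = (None, NOT_REACHED)
    if K < Kc:
        T_s, T_source = time_to_antiphase(phi_w[0], Omega, K)
    pred = predict_phi(phi_u[0], Omega, K, phi_u.size, dt)
    return KuramotoFit(
        K=K, Omega=Omega, Kc=Kc, T_s=T_s, T_source=T_source,
        mae_rad=mae(phi_u, pred), slope=res.slope, intercept=res.intercept,
        rmse=rmse, n_frames_used=int(phi_u.size),
        stderr_slope=float(res.stderr), stderr_intercept=float(res.intercept_stderr),
    )


def critical_coupling(Omega: float) -> float:
    """K_c = -|Omega|: anti-phase synchrony is attainable iff K < K_c."""
    return -abs(Omega)


def equilibrium_curve(control: np.ndarray | None = None):
    """Equilibria of dPhi/dt = Omega - K sin(Phi) versus K/Omega.

    For |K/Omega| >= 1 the equation sin(Phi) = Omega/K has two circle
    solutions, Phi = arcsin(1/c) and its supplement; stability follows the
    sign of d(dPhi/dt)/dPhi = -K cos(Phi) (taking Omega > 0, so
    sign(K) = sign(c)). Returns a record array with fields
    ``control``, ``phi``, ``stable``. No rows are produced for |c| < 1.
    """
    if control is None:
        control = np.linspace(-5.0, 5.0, 1001)
    control = np.asarray(control, dtype=float)
    rows = []
    for c in control:
        if abs(c) < 1.0 or c == 0.0:
            continue
        base = float(np.arcsin(1.0 / c))
        for phi in (base, wrap(np.pi - base)):
            stable = np.sign(c) * np.cos(phi) > 0
            if abs(abs(c) - 1.0) < 1e-15:
                stable = False  # saddle-node: half-stable
            rows.append((c, phi, stable))
    return pd.DataFrame(rows, columns=["control", "phi", "stable"])


def saddle_node_point(sign: int = -1, bracket: tuple[float, float] = (-5.0, -1e-3),
                      tol: float = 1e-12) -> float:
    """Locate the control-parameter value where real equilibria appear.

    Bisects the existence condition (sin(Phi) = 1/c has a real solution,
    i.e. |1/c| <= 1) on the negative (anti-phase, default) or positive
    branch. Converges to -1 or +1 respectively.
    """
    def exists(c: float) -> bool:
        with np.errstate(invalid="ignore"):
            return np.isfinite(np.arcsin(1.0 / c))

    lo, hi = bracket if sign < 0 else (-bracket[1], -bracket[0])
    if sign > 0:
        lo, hi = 1e-3, 5.0
        # existence holds for c >= 1: bisect on [lo, hi] with exists(hi)
        assert exists(hi) and not exists(lo)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if exists(mid):
                hi = mid
            else:
                lo = mid
        return hi
    assert exists(lo) and not exists(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if exists(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _equilibria(Omega: float, K: float) -> tuple[float, float]:
    """(unstable, stable) wrapped equilibria for |K| > |Omega|, K != 0."""
    base = float(np.arcsin(Omega / K))
    phi_a = base                     # cos > 0 branch
    phi_b = float(wrap(np.pi - base))  # cos < 0 branch
    # stable where K cos(phi) > 0
    if K * np.cos(phi_a) > 0:
        return phi_b, phi_a
    return phi_a, phi_b


def _antiderivative(phi: float, Omega: float, K: float) -> float:
    """Continuous antiderivative F of 1/(Omega - K sin(Phi)), |K| > |Omega|.

    F(Phi) = (1/D) ln|(Omega tan(Phi/2) - K - D)/(Omega tan(Phi/2) - K + D)|
    with D = sqrt(K^2 - Omega^2); continuous across odd multiples of pi
    (both one-sided limits vanish) and singular only at the equilibria.
    """
    D = np.sqrt(K * K - Omega * Omega)
    if Omega == 0.0:
        # dPhi/dt = -K sin(Phi); antiderivative of 1/(-K sin) is
        # (-1/K) ln|tan(Phi/2)|
        return float(-np.log(np.abs(np.tan(phi / 2.0))) / K)
    t = np.tan(phi / 2.0)
    num = Omega * t - K - D
    den = Omega * t - K + D
    return float(np.log(np.abs(num / den)) / D)


def time_to_antiphase(phi_initial: float, Omega: float, K: float,
                      tol_rad: float = SYNC_TOL_RAD,
                      oracle_rtol: float = 0.05) -> tuple[float | None, str]:
    """Time for Phi to come within ``tol_rad`` of the stable equilibrium.

    Returns (T_s, source). When K >= K_c = -|Omega| anti-phase synchrony is
    unattainable and (None, "not reached") is returned. When the initial
    phase sits exactly on the unstable equilibrium, (inf, "unstable
    equilibrium") is returned. Otherwise the closed form (real rewriting of
    the arctan/log integral, see :func:`_antiderivative`) is checked against
    direct numerical integration of dPhi/dt = Omega - K sin(Phi); the closed
    form is reported when the two agree within ``oracle_rtol``, else the
    oracle value with source "oracle".
    """
    if K >= critical_coupling(Omega):
        return None, NOT_REACHED
    phi_i = float(wrap(phi_initial))
    unstable, stable = _equilibria(Omega, K)
    if circular_distance(phi_i, unstable) < 1e-12:
        return float("inf"), "unstable equilibrium"
    if circular_distance(phi_i, stable) <= tol_rad:
        return 0.0, "closed_form"
    direction = np.sign(Omega - K * np.sin(phi_i))
    # unwrapped target: nearest stable equilibrium in the flow direction
    delta = wrap(stable - phi_i)
    if np.sign(delta) != direction:
        delta += direction * TWO_PI
    target = phi_i + delta
    stop = target - direction * tol_rad
    T_closed = _antiderivative(stop, Omega, K) - _antiderivative(phi_i, Omega, K)
    T_oracle = _integrate_time(phi_i, stop, Omega, K)
    if T_oracle > 0 and abs(T_closed - T_oracle) <= oracle_rtol * T_oracle:
        return float(T_closed), "closed_form"
    return float(T_oracle), "oracle"


def _integrate_time(phi_i: float, phi_stop: float, Omega: float, K: float) -> float:
    """ODE oracle: integrate dPhi/dt = Omega - K sin(Phi) until phi_stop."""
    direction = np.sign(phi_stop - phi_i)

    def rhs(t, y):
        return [Omega - K * np.sin(y[0])]

    def arrived(t, y):
        return (y[0] - phi_stop) * direction

    arrived.terminal = True
    arrived.direction = 1
    t_max = 1e4 / max(abs(Omega - K), 1e-9)
    sol = spi.solve_ivp(rhs, (0.0, t_max), [phi_i], events=arrived,
                        rtol=1e-10, atol=1e-12, max_step=np.inf)
    if sol.t_events[0].size == 0:
        return float("inf")
    return float(sol.t_events[0][0])


def predict_phi(phi0: float, Omega: float, K: float, n: int, dt: float) -> np.ndarray:
    """Forward-Euler trajectory of Phi from phi0 under fitted parameters."""
    phi = np.empty(n)
    phi[0] = phi0
    for f in range(1, n):
        phi[f] = phi[f - 1] + dt * (Omega - K * np.sin(phi[f - 1]))
    return phi


def mae(observed, predicted) -> float:
    """Mean absolute wrapped difference between two Phi series, in radians."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("series length mismatch")
    return float(np.mean(circular_distance(observed, predicted)))
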