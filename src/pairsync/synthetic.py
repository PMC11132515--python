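"""Synthetic behavioral bouts: uncoupled controls and coupled ground truth.

Two generators cover everything the analysis pipeline consumes:

* Control bouts. Each individual is an independent alternating renewal
  process: starting from an assigned state (vigilant or feeding), it holds
  the state for an Exp(mu_state) draw, switches, draws again, and so on
  until the bout ends. The continuous trajectory is discretized at the
  frame rate into a {0, 1} state series (controls contain no 0.5 frames).
  Bout durations are themselves exponential (mean 53.32 s by default,
  floored at 10 s so the bouts survive the inclusion filter), and the
  standard design starts 25 bouts from each joint initial state VV, VF,
  FV, FF for a set of 100.

* Coupled bouts. The non-periodic Kuramoto simulator is run at a known
  K_true; each oscillator's wrapped phase is mapped to a state by region
  membership (vigilant half-circle -> 1.0, feeding half -> 0.0). The
  generator's internal phases are returned alongside the state series so
  downstream phase extraction can be validated end to end.

Default holding-time means are a realistic marmoset pair (feeding 5.06 s /
vigilance 3.17 s and 4.04 s / 3.10 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import BoutPair, StateSeries
from .nonperiodic import NPKParams, simulate_np

JOINT_STATES = ("VV", "VF", "FV", "FF")
DEFAULT_MUS = (3.17, 5.06, 3.10, 4.04)  # mu_V1, mu_F1, mu_V2, mu_F2 seconds


@dataclass
class ControlSimConfig:
    """Study conditions for a set of uncoupled control bouts."""

    mu_V1_s: float = DEFAULT_MUS[0]
    mu_F1_s: float = DEFAULT_MUS[1]
    mu_V2_s: float = DEFAULT_MUS[2]
    mu_F2_s: float = DEFAULT_MUS[3]
    bout_duration_mu_s: float = 53.32
    min_duration_s: float = 10.0
    n_bouts: int = 100
    initial_state_design: dict = field(
        default_factory=lambda: {s: 25 for s in JOINT_STATES})
    rate_hz: float = 25.0
    seed: int | None = None
    pair_id: str = "pair"

    def __post_init__(self):
        if sum(self.initial_state_design.values()) != self.n_bouts:
            raise ValueError("initial-state counts must sum to n_bouts")
        for mu in (self.mu_V1_s, self.mu_F1_s, self.mu_V2_s, self.mu_F2_s,
                   self.bout_duration_mu_s):
            if mu <= 0:
                raise ValueError("all means must be positive")


@dataclass
class GroundTruth:
    """Generation record stored with every coupled synthetic bout."""

    K_true: float
    mus: tuple[float, float, float, float] = DEFAULT_MUS
    theta0: tuple[float, float] = (0.0, np.pi / 2)
    seed: int | None = None


def _renewal_states(mu_V: float, mu_F: float, initial_state: str,
                    duration_s: float, rate_hz: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Discretized alternating renewal trajectory; 1 = vigilant, 0 = feeding."""
    mus = {"V": mu_V, "F": mu_F}
    state = initial_state
    switch_times = []  # times at which the state flips
    t = rng.exponential(mus[state])
    while t < duration_s:
        switch_times.append(t)
        state = "F" if state == "V" else "V"
        t += rng.exponential(mus[state])
    n = int(round(duration_s * rate_hz))
    frame_t = np.arange(n) / rate_hz
    n_switches = np.searchsorted(switch_times, frame_t, side="right")
    start_val = 1.0 if initial_state == "V" else 0.0
    return np.where(n_switches % 2 == 0, start_val, 1.0 - start_val)


def simulate_control_bout(config: ControlSimConfig, initial_joint_state: str,
                          duration_s: float, seed: int | None = None,
                          bout_id: str = "control") -> BoutPair:
    """One uncoupled control bout; the pair's series are independent.

    ``initial_joint_state`` is two letters, individual 1 then 2, e.g. "FV"
    starts individual 1 feeding and individual 2 vigilant. Individual 1's
    draws are consumed before individual 2's.
    """
    if initial_joint_state not in JOINT_STATES:
        raise ValueError(f"initial_joint_state must be one of {JOINT_STATES}")
    rng = np.random.default_rng(seed)
    va = _renewal_states(config.mu_V1_s, config.mu_F1_s, initial_joint_state[0],
                         duration_s, config.rate_hz, rng)
    vb = _renewal_states(config.mu_V2_s, config.mu_F2_s, initial_joint_state[1],
                         duration_s, config.rate_hz, rng)
    meta = {"pair_id": config.pair_id, "condition": "control",
            "initial_joint_state": initial_joint_state, "seed": seed}
    return BoutPair(
        bout_id=bout_id,
        series_a=StateSeries(individual_id=f"{config.pair_id}_1",
                             rate_hz=config.rate_hz, values=va),
        series_b=StateSeries(individual_id=f"{config.pair_id}_2",
                             rate_hz=config.rate_hz, values=vb),
        metadata=meta,
    )


def generate_control_set(config: ControlSimConfig) -> tuple[list[BoutPair], list[dict]]:
    """The full control design: n_bouts with exponential durations.

    Durations are i.i.d. Exp(bout_duration_mu_s) floored at min_duration_s;
    initial joint states follow the design counts in fixed order. Returns
    the bouts and a manifest recording every draw and child seed.
    """
    rng = np.random.default_rng(config.seed)
    bouts: list[BoutPair] = []
    manifest: list[dict] = []
    i = 0
    for state in JOINT_STATES:
        for _ in range(config.initial_state_design.get(state, 0)):
            duration = max(float(rng.exponential(config.bout_duration_mu_s)),
                           config.min_duration_s)
            child_seed = int(rng.integers(0, 2 ** 31 - 1))
            bout_id = f"{config.pair_id}_ctrl{i:03d}"
            bouts.append(simulate_control_bout(config, state, duration,
                                               seed=child_seed, bout_id=bout_id))
            manifest.append({"bout_id": bout_id, "initial_joint_state": state,
                             "duration_s": duration, "seed": child_seed})
            i += 1
    return bouts, manifest


def generate_coupled_bout(truth: GroundTruth, duration_s: float,
                          rate_hz: float = 25.0, pair_id: str = "pair",
                          bout_id: str = "coupled", redraw_mode: str = "both"):
    """One coupled bout from the non-periodic model at a known K_true.

    Returns (bout, (theta1, theta2), phi): the discretized state series plus
    the generator's internal phase series for end-to-end validation.
    """
    params = NPKParams(
        mu_V1_s=truth.mus[0], mu_F1_s=truth.mus[1],
        mu_V2_s=truth.mus[2], mu_F2_s=truth.mus[3],
        K=truth.K_true, duration_s=duration_s, dt_s=1.0 / rate_hz,
        theta0=truth.theta0, seed=truth.seed, redraw_mode=redraw_mode,
    )
    p1, p2, region, phi = simulate_np(params)
    meta = {"pair_id": pair_id, "condition": "coupled",
            "K_true": truth.K_true, "seed": truth.seed}
    bout = BoutPair(
        bout_id=bout_id,
        series_a=StateSeries(individual_id=f"{pair_id}_1", rate_hz=rate_hz,
                             values=region[:, 0].astype(float)),
        series_b=StateSeries(individual_id=f"{pair_id}_2", rate_hz=rate_hz,
                             values=region[:, 1].astype(float)),
        metadata=meta,
    )
    return bout, (p1, p2), phi


def insert_out_of_sight(bout: BoutPair, rate_per_min: float = 1.0,
                        mean_duration_s: float = 1.0,
                        seed: int | None = None) -> BoutPair:
    """Corrupt a bout with 0.5 segments to stress-test filtering.

    Segments arrive as a Poisson process (``rate_per_min`` per individual)
    with exponential lengths; corrupted frames keep engaged=True, emulating
    coded out-of-sight events inside a bout.
    """
    rng = np.random.default_rng(seed)
    new_series = []
    for s in (bout.series_a, bout.series_b):
        values = s.values.copy()
        engaged = np.ones(values.size, dtype=bool)
        n_events = rng.poisson(rate_per_min * s.duration_s / 60.0)
        for _ in range(n_events):
            start = rng.integers(0, values.size)
            length = max(1, int(round(rng.exponential(mean_duration_s) * s.rate_hz)))
            values[start:start + length] = 0.5
        new_series.append(StateSeries(individual_id=s.individual_id,
                                      rate_hz=s.rate_hz, values=values,
                                      t0_s=s.t0_s, engaged=engaged))
    return BoutPair(bout_id=bout.bout_id, series_a=new_series[0],
                    series_b=new_series[1], metadata=dict(bout.metadata))
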