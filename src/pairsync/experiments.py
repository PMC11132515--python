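"""Reusable study-scale experiments built from the pipeline primitives.

These functions reproduce the package's standard computational experiments
at the canonical study conditions: the uncoupled control null (700 bouts
from the default pair parameters, K regressed on Omega) and the coupled
synthetic study (non-periodic bouts at a known coupling, fitted by both the
classic regression and the sweep).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kuramoto as km
from . import nonperiodic as npk
from . import phase as ph
from . import synthetic as syn

DEFAULT_BOUT_DURATION_MU_S = 53.32
DEFAULT_MIN_DURATION_S = 10.0


def fit_bout_classic(bout, edge_trim_s: float = ph.DEFAULT_EDGE_TRIM_S):
    """Phase-extract one bout and fit the classic model.

    Returns (record dict, phi, theta0) or None when the bout cannot be
    processed or fails the inclusion filter (duration >= 10 s, at least one
    individual with >= 2 oscillations).
    """
    try:
        pa = ph.state_series_phase(bout.series_a)
        pb = ph.state_series_phase(bout.series_b)
        phi = ph.phase_difference(pa, pb)
        ca, cb = ph.count_oscillations(pa), ph.count_oscillations(pb)
        if bout.duration_s < DEFAULT_MIN_DURATION_S or not (ca >= 2 or cb >= 2):
            return None
        fit = km.fit_classic(phi, edge_trim_s=edge_trim_s)
    except (ph.BoutTooShortError, ph.NoOscillationError,
            km.DegenerateRegressorError, ValueError):
        return None
    rec = {"bout_id": bout.bout_id, "duration_s": bout.duration_s,
           "K": fit.K, "Omega": fit.Omega, "Kc": fit.Kc,
           "K_lt_Kc": fit.K < fit.Kc, "mae_classic": fit.mae_rad}
    return rec, phi, (pa.wrapped[0], pb.wrapped[0])


def control_fit_table(n_bouts: int = 700, seed: int = 0,
                      mus: tuple = syn.DEFAULT_MUS,
                      bout_duration_mu_s: float = DEFAULT_BOUT_DURATION_MU_S,
                      ) -> pd.DataFrame:
    """Fit the classic model to a set of uncoupled control bouts.

    Bouts come from the standard control design (equal counts of the four
    joint initial states, exponential durations floored at 10 s) and pass
    the bout-inclusion filter before fitting.
    """
    design = {s: n_bouts // 4 for s in syn.JOINT_STATES}
    for i, s in enumerate(syn.JOINT_STATES):
        if i < n_bouts % 4:
            design[s] += 1
    cfg = syn.ControlSimConfig(
        mu_V1_s=mus[0], mu_F1_s=mus[1], mu_V2_s=mus[2], mu_F2_s=mus[3],
        bout_duration_mu_s=bout_duration_mu_s, n_bouts=n_bouts,
        initial_state_design=design, seed=seed)
    bouts, _ = syn.generate_control_set(cfg)
    rows = []
    for bout in bouts:
        out = fit_bout_classic(bout)
        if out is not None:
            rows.append(out[0])
    return pd.DataFrame(rows)


def control_null_slope(n_bouts: int = 700, seed: int = 0) -> dict:
    """K-on-Omega regression across an uncoupled control set.

    Returns slope/intercept/RMSE, the number of fitted bouts, and a
    heteroscedasticity-robust (HC3) standard error for the slope -- the
    per-bout estimates are heavy-tailed, so the robust error is the honest
    uncertainty.
    """
    import statsmodels.api as sm

    table = control_fit_table(n_bouts=n_bouts, seed=seed)
    x = table["Omega"].to_numpy()
    y = table["K"].to_numpy()
    model = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3")
    resid = model.resid
    return {"slope": float(model.params[1]), "intercept": float(model.params[0]),
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "slope_se_hc3": float(model.bse[1]), "n": int(len(table)),
            "frac_K_lt_Kc": float(table["K_lt_Kc"].mean())}


def coupled_fit_table(n_bouts: int = 35, K_true: float = -1.5, seed: int = 0,
                      mus: tuple = syn.DEFAULT_MUS, sweep: bool = True,
                      bout_duration_mu_s: float = DEFAULT_BOUT_DURATION_MU_S,
                      ) -> pd.DataFrame:
    """Generate and fit coupled bouts at a known ground-truth coupling.

    Each retained bout carries the classic fit plus, when ``sweep``, the
    non-periodic sweep estimate K_npk and its minimum mean angular distance
    (the non-periodic MAE).
    """
    rng = np.random.default_rng(seed)
    rows = []
    attempts = 0
    while len(rows) < n_bouts and attempts < 4 * n_bouts:
        attempts += 1
        duration = max(float(rng.exponential(bout_duration_mu_s)),
                       DEFAULT_MIN_DURATION_S)
        theta0 = (float(rng.uniform(-np.pi, np.pi)),
                  float(rng.uniform(-np.pi, np.pi)))
        truth = syn.GroundTruth(K_true=K_true, mus=mus, theta0=theta0,
                                seed=int(rng.integers(2 ** 31 - 1)))
        bout, _, _ = syn.generate_coupled_bout(
            truth, duration, bout_id=f"coupled{attempts:03d}")
        out = fit_bout_classic(bout)
        if out is None:
            continue
        rec, phi, th0 = out
        rec["K_true"] = K_true
        if sweep:
            sw = npk.sweep_fit(phi, mus, th0,
                               seed=int(rng.integers(2 ** 31 - 1)))
            rec["K_npk"] = sw.K_hat
            rec["mae_npk"] = float(sw.mean_distance.min())
        rows.append(rec)
    return pd.DataFrame(rows)


def sweep_recovery_trials(K_true: float, n_trials: int = 50,
                          duration_s: float = 60.0, seed: int = 0,
                          mus: tuple = syn.DEFAULT_MUS) -> np.ndarray:
    """Self-recovery experiment: estimate K_hat for observations generated
    by the non-periodic model at K_true (held-out seeds). Returns the
    array of estimates."""
    rng = np.random.default_rng(seed)
    hats = np.empty(n_trials)
    for t in range(n_trials):
        theta0 = (float(rng.uniform(-np.pi, np.pi)),
                  float(rng.uniform(-np.pi, np.pi)))
        params = npk.NPKParams(
            mu_V1_s=mus[0], mu_F1_s=mus[1], mu_V2_s=mus[2], mu_F2_s=mus[3],
            K=K_true, duration_s=duration_s, theta0=theta0,
            seed=int(rng.integers(2 ** 31 - 1)))
        phi_obs = npk.simulate_np(params)[3]
        sw = npk.sweep_fit(phi_obs, mus, theta0,
                           seed=int(rng.integers(2 ** 31 - 1)))
        hats[t] = sw.K_hat
    return hats
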