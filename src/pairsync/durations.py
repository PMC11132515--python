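"""Exponential fits to behavioral state durations and related statistics.

Switches between vigilance and feeding are modeled as Poisson processes, so
the holding time in each state is exponential: f(x) = (1/mu) exp(-x/mu) with
maximum-likelihood estimate mu = sample mean. Within a pair, the similarity
of the two individuals' means is summarized by the ratio min/max in (0, 1]
("closer to 1" means more similar distributions, a sign of synchrony), and
the probability of obtaining a ratio as extreme as the one observed when
the animals were together is assessed against a bootstrap null built from
the alone-condition samples. The mean head-oscillation period of an
individual is mu_V + mu_F.

Only complete within-bout episodes should enter these fits; episodes
truncated by bout boundaries are excluded upstream (no censoring model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spst


@dataclass
class DurationSample:
    """Positive state durations of one individual/behavior/condition."""

    individual_id: str
    behavior: str
    condition: str
    durations_s: np.ndarray

    def __post_init__(self):
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if (self.durations_s <= 0).any():
            raise ValueError("durations must be positive")

    @property
    def n(self) -> int:
        return self.durations_s.size


@dataclass
class ExponentialFit:
    """MLE exponential fit: mu is the sample mean duration."""

    mu_s: float
    n: int
    log_likelihood: float


def fit_exponential(sample: DurationSample | np.ndarray) -> ExponentialFit:
    """Fit Exp(mu) by maximum likelihood; mu equals the sample mean."""
    x = sample.durations_s if isinstance(sample, DurationSample) else \
        np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two durations to fit")
    if (x <= 0).any():
        raise ValueError("durations must be positive")
    mu = float(np.mean(x))
    loglik = float(-x.size * (np.log(mu) + 1.0))
    return ExponentialFit(mu_s=mu, n=int(x.size), log_likelihood=loglik)


def mu_ratio(fit_a: ExponentialFit, fit_b: ExponentialFit) -> float:
    """min(mu_a, mu_b)/max(mu_a, mu_b) in (0, 1]; 1 iff equal means."""
    a, b = fit_a.mu_s, fit_b.mu_s
    if a <= 0 or b <= 0:
        raise ValueError("mu must be positive")
    return min(a, b) / max(a, b)


@dataclass
class BootstrapRatioTest:
    z: float
    p_normal: float
    p_empirical: float
    null_ratios: np.ndarray
    observed_ratio: float


def bootstrap_ratio_pvalue(alone_a: DurationSample, alone_b: DurationSample,
                           observed_ratio: float, n_boot: int = 1000,
                           seed: int | None = None) -> BootstrapRatioTest:
    """Bootstrap null for a together-condition mean-duration ratio.

    Each replicate resamples both individuals' alone-condition durations
    with replacement (same n), refits mu and recomputes the min/max ratio.
    The observed together-condition ratio is scored by its Z against the
    null (two-sided normal p, as well as an empirical two-sided quantile p
    for robustness). A degenerate null (zero spread) yields NaN z/p with a
    warning.
    """
    rng = np.random.default_rng(seed)
    xa = alone_a.durations_s
    xb = alone_b.durations_s
    if xa.size == 0 or xb.size == 0:
        raise ValueError("alone samples must be nonempty")
    ra = rng.choice(xa, size=(n_boot, xa.size), replace=True).mean(axis=1)
    rb = rng.choice(xb, size=(n_boot, xb.size), replace=True).mean(axis=1)
    null = np.minimum(ra, rb) / np.maximum(ra, rb)
    sd = float(np.std(null, ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate bootstrap null (zero spread); p undefined",
                      RuntimeWarning, stacklevel=2)
        z = p = float("nan")
    else:
        z = (observed_ratio - float(np.mean(null))) / sd
        p = 2.0 * float(spst.norm.sf(abs(z)))
    lo = float(np.mean(null <= observed_ratio))
    hi = float(np.mean(null >= observed_ratio))
    p_emp = min(1.0, 2.0 * min(lo, hi))
    return BootstrapRatioTest(z=z, p_normal=p, p_empirical=p_emp,
                              null_ratios=null, observed_ratio=observed_ratio)


def oscillation_period(mu_V: float, mu_F: float) -> float:
    """Mean head-oscillation period: mu_V + mu_F (seconds)."""
    if mu_V < 0 or mu_F < 0:
        raise ValueError("means must be nonnegative")
    return mu_V + mu_F


def condition_comparisons(mu_ratios: pd.DataFrame, periods: pd.DataFrame,
                          pair_periods: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group-level alone-vs-together comparisons.

    Parameters
    ----------
    mu_ratios : DataFrame with columns (pair_id, behavior, alone, together)
        Per-pair mean-duration ratios in the two conditions.
    periods : DataFrame with columns (individual_id, alone, together)
        Per-individual oscillation periods (mu_V + mu_F).
    pair_periods : DataFrame with columns (pair_id, condition, period_1,
        period_2), optional. Pair members' periods for the within-condition
        rank correlation.

    Returns a tidy table of two-sided Wilcoxon signed-rank tests (ratios per
    behavior; periods) and Spearman correlations per condition, each with
    statistic, p and n.
    """
    rows = []

    def signed_rank(name, alone, together, unit):
        alone = np.asarray(alone, dtype=float)
        together = np.asarray(together, dtype=float)
        n = alone.size
        if n < 5:
            warnings.warn(f"{name}: only {n} {unit}s; low power", RuntimeWarning,
                          stacklevel=3)
        if np.allclose(alone, together):
            stat, p = 0.0, 1.0
        else:
            res = spst.wilcoxon(alone, together, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"test": name, "method": "wilcoxon_signed_rank",
                     "statistic": stat, "p": p, "n": n})

    for behavior, g in mu_ratios.groupby("behavior"):
        signed_rank(f"mu_ratio_{behavior}", g["alone"], g["together"], "pair")
    signed_rank("oscillation_period", periods["alone"], periods["together"],
                "individual")
    if pair_periods is not None:
        for condition, g in pair_periods.groupby("condition"):
            rho, p = spst.spearmanr(g["period_1"], g["period_2"])
            rows.append({"test": f"pair_period_correlation_{condition}",
                         "method": "spearman", "statistic": float(rho),
                         "p": float(p), "n": len(g)})
    return pd.DataFrame(rows)


def durations_from_state_series(values: np.ndarray, rate_hz: float,
                                drop_truncated: bool = True) -> dict[str, np.ndarray]:
    """Extract complete vigilance/feeding episode durations from a series.

    Runs of 1.0 are vigilance episodes, runs of 0.0 feeding episodes; 0.5
    frames break runs. With ``drop_truncated`` the first and last run are
    discarded (their true duration is censored by the bout boundary).
    """
    values = np.asarray(values, dtype=float)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    keep = slice(1, -1) if drop_truncated else slice(None)
    out = {"vigilance": [], "feeding": []}
    for s, e in zip(starts[keep], ends[keep]):
        if values[s] == 1.0:
            out["vigilance"].append((e - s) / rate_hz)
        elif values[s] == 0.0:
            out["feeding"].append((e - s) / rate_hz)
    return {k: np.asarray(v) for k, v in out.items()}
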