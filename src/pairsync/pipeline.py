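"""End-to-end orchestration: bouts -> phases -> fits -> group statistics.

`run_full_analysis` drives the whole chain on synthetic data (or bouts
loaded from event tables prepared upstream): generate coupled "actual"
bouts and uncoupled control bouts per pair, extract phases, fit the classic
Kuramoto model per bout, infer the non-periodic coupling by parameter
sweep on the actual bouts, and aggregate into the group-level report:

* per-bout fit table (K, Omega, K_c, T, MAE, diagnostics) and discard log;
* per-pair summaries: mean K per fitting route, fraction of bouts with
  K < K_c;
* group tests: Wilcoxon signed-rank on the K < K_c fraction (actual vs
  control), Friedman across {control K, classic K, non-periodic K} with
  post-hoc Nemenyi, Wilcoxon on per-bout MAE (classic vs non-periodic);
* K-on-Omega regression per group with a permutation test of the slope
  difference. The permutation test replaces a smoothing-based analysis of
  covariance: group labels are shuffled and the absolute OLS slope
  difference recomputed, which answers "are the two regression lines
  unequal" without smoother-specific tuning.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spst

from . import events as ev
from . import kuramoto as km
from . import nonperiodic as npk
from . import phase as ph
from . import synthetic as syn

log = logging.getLogger("pairsync")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_pairs": 7,
    "actual_bouts_per_pair": 8,
    "control_bouts_per_pair": 100,
    "K_true": -1.5,           # coupling of the synthetic "actual" pairs (rad/s conv.)
    "mus": list(syn.DEFAULT_MUS),
    "bout_duration_mu_s": 53.32,
    "min_duration_s": 10.0,
    "rate_hz": 25.0,
    "cutoff_hz": ph.DEFAULT_CUTOFF_HZ,
    "center": ph.DEFAULT_CENTER,
    "edge_trim_s": ph.DEFAULT_EDGE_TRIM_S,
    "gap_threshold_s": 10.0,
    "K_min": npk.DEFAULT_K_MIN,
    "K_max": npk.DEFAULT_K_MAX,
    "K_step": npk.DEFAULT_K_STEP,
    "sweep_seeds": npk.DEFAULT_N_SEEDS,
    "n_permutations": 10000,
}

REQUIRED_KEYS = ("seed", "n_pairs", "rate_hz")


@dataclass
class AnalysisReport:
    """Aggregated outputs of one full pipeline run."""

    fit_table: pd.DataFrame
    discard_log: pd.DataFrame
    per_pair: pd.DataFrame
    group_tests: pd.DataFrame
    regression: pd.DataFrame
    slope_test: dict
    fraction_K_lt_Kc: dict
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fit_table": self.fit_table.to_dict(orient="records"),
            "discard_log": self.discard_log.to_dict(orient="records"),
            "per_pair": self.per_pair.to_dict(orient="records"),
            "group_tests": self.group_tests.to_dict(orient="records"),
            "regression": self.regression.to_dict(orient="records"),
            "slope_test": self.slope_test,
            "fraction_K_lt_Kc": self.fraction_K_lt_Kc,
            "config": self.config,
        }


def validate_config(config: dict | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    for key in REQUIRED_KEYS:
        if cfg.get(key) is None:
            raise KeyError(f"missing required config key: {key}")
    return cfg


def process_bout(bout: ev.BoutPair, cfg: dict) -> dict:
    """Phase-extract and classic-fit one bout; returns a fit record.

    Raises the underlying error when the bout cannot be processed (too
    short to filter, no oscillation, degenerate regressor); callers log
    these into the discard table.
    """
    pa = ph.state_series_phase(bout.series_a, cutoff_hz=cfg["cutoff_hz"],
                               center=cfg["center"])
    pb = ph.state_series_phase(bout.series_b, cutoff_hz=cfg["cutoff_hz"],
                               center=cfg["center"])
    phi = ph.phase_difference(pa, pb)
    fit = km.fit_classic(phi, edge_trim_s=cfg["edge_trim_s"])
    return {
        "bout_id": bout.bout_id,
        "pair_id": bout.metadata.get("pair_id"),
        "group": bout.metadata.get("condition", "actual"),
        "duration_s": bout.duration_s,
        "oscillations_a": ph.count_oscillations(pa),
        "oscillations_b": ph.count_oscillations(pb),
        "K": fit.K, "Omega": fit.Omega, "Kc": fit.Kc,
        "K_lt_Kc": fit.antiphase_attainable,
        "T_s": fit.T_s if fit.T_s is not None else np.nan,
        "T_source": fit.T_source,
        "mae_classic": fit.mae_rad,
        "rmse": fit.rmse, "n_frames_used": fit.n_frames_used,
        "_phi": phi, "_theta0": (pa.wrapped[0], pb.wrapped[0]),
    }


def run_full_analysis(config: dict | None = None,
                      out_dir: str | Path | None = None) -> AnalysisReport:
    """Execute the complete synthetic-data analysis. See module docstring."""
    cfg = validate_config(config)
    rng = np.random.default_rng(cfg["seed"])
    mus = tuple(cfg["mus"])
    records: list[dict] = []
    discards: list[dict] = []

    for p in range(cfg["n_pairs"]):
        pair_id = f"pair{p + 1}"
        # --- coupled ("actual") bouts ---
        for b in range(cfg["actual_bouts_per_pair"]):
            duration = max(float(rng.exponential(cfg["bout_duration_mu_s"])),
                           cfg["min_duration_s"])
            theta0 = (float(rng.uniform(-np.pi, np.pi)),
                      float(rng.uniform(-np.pi, np.pi)))
            truth = syn.GroundTruth(K_true=cfg["K_true"], mus=mus, theta0=theta0,
                                    seed=int(rng.integers(2 ** 31 - 1)))
            bout, _, _ = syn.generate_coupled_bout(
                truth, duration, rate_hz=cfg["rate_hz"], pair_id=pair_id,
                bout_id=f"{pair_id}_act{b:03d}")
            _process_into(bout, cfg, records, discards, rng)
        # --- control bouts ---
        ctrl_cfg = syn.ControlSimConfig(
            mu_V1_s=mus[0], mu_F1_s=mus[1], mu_V2_s=mus[2], mu_F2_s=mus[3],
            bout_duration_mu_s=cfg["bout_duration_mu_s"],
            min_duration_s=cfg["min_duration_s"],
            n_bouts=cfg["control_bouts_per_pair"],
            initial_state_design=_design(cfg["control_bouts_per_pair"]),
            rate_hz=cfg["rate_hz"], seed=int(rng.integers(2 ** 31 - 1)),
            pair_id=pair_id)
        bouts, _ = syn.generate_control_set(ctrl_cfg)
        for bout in bouts:
            _process_into(bout, cfg, records, discards, rng, sweep=False)

    fit_table = pd.DataFrame([{k: v for k, v in r.items() if not k.startswith("_")}
                              for r in records])
    discard_log = pd.DataFrame(discards, columns=["bout_id", "pair_id", "group",
                                                  "duration_s", "reason"])
    per_pair = _per_pair_summary(fit_table)
    group_tests = group_comparisons(per_pair, fit_table)
    regression, slope_test = k_vs_omega_regression(
        fit_table, n_permutations=cfg["n_permutations"],
        seed=int(rng.integers(2 ** 31 - 1)))
    frac = {
        "actual": _fraction(fit_table, "coupled"),
        "control": _fraction(fit_table, "control"),
    }
    report = AnalysisReport(fit_table=fit_table, discard_log=discard_log,
                            per_pair=per_pair, group_tests=group_tests,
                            regression=regression, slope_test=slope_test,
                            fraction_K_lt_Kc=frac, config=cfg)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _design(n: int) -> dict:
    base, extra = divmod(n, 4)
    return {s: base + (1 if i < extra else 0)
            for i, s in enumerate(syn.JOINT_STATES)}


def _process_into(bout, cfg, records, discards, rng, sweep: bool = True) -> None:
    base = {"bout_id": bout.bout_id, "pair_id": bout.metadata.get("pair_id"),
            "group": bout.metadata.get("condition"), "duration_s": bout.duration_s}
    try:
        rec = process_bout(bout, cfg)
    except (ph.BoutTooShortError, ph.NoOscillationError,
            km.DegenerateRegressorError, ValueError) as e:
        discards.append({**base, "reason": str(e)})
        return
    # inclusion filter: >=10 s and at least one individual >= 2 oscillations
    _, flog = ev.filter_bouts(
        [bout], {bout.bout_id: (rec["oscillations_a"], rec["oscillations_b"])},
        min_duration_s=cfg["min_duration_s"])
    if flog:
        discards.append({**base, "reason": flog[0]["reason"]})
        return
    if sweep:
        sw = npk.sweep_fit(rec.pop("_phi"), tuple(cfg["mus"]), rec.pop("_theta0"),
                           K_min=cfg["K_min"], K_max=cfg["K_max"],
                           step=cfg["K_step"], n_seeds=cfg["sweep_seeds"],
                           seed=int(rng.integers(2 ** 31 - 1)))
        rec["K_npk"] = sw.K_hat
        rec["mae_npk"] = float(sw.mean_distance.min())
    records.append(rec)


def _fraction(fit_table: pd.DataFrame, group: str) -> float:
    g = fit_table[fit_table["group"] == group]
    return float(g["K_lt_Kc"].mean()) if len(g) else float("nan")


def _per_pair_summary(fit_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pair_id, g in fit_table.groupby("pair_id"):
        actual = g[g["group"] == "coupled"]
        control = g[g["group"] == "control"]
        rows.append({
            "pair_id": pair_id,
            "control_K_mean": control["K"].mean() if len(control) else np.nan,
            "classic_K_mean": actual["K"].mean() if len(actual) else np.nan,
            "npk_K_mean": actual["K_npk"].mean()
            if "K_npk" in actual and len(actual) else np.nan,
            "frac_actual": actual["K_lt_Kc"].mean() if len(actual) else np.nan,
            "frac_control": control["K_lt_Kc"].mean() if len(control) else np.nan,
            "n_actual": len(actual), "n_control": len(control),
        })
    return pd.DataFrame(rows)


def nemenyi_posthoc(data: np.ndarray) -> pd.DataFrame:
    """Post-hoc Nemenyi test after Friedman on an (n_blocks, k) matrix.

    Within-block ranks are averaged per treatment; a pair's statistic is the
    mean-rank difference divided by sqrt(k(k+1)/(12 n)), referred to the
    studentized-range distribution with infinite degrees of freedom (the
    convention of PMCMR-style implementations). Returns the symmetric
    matrix of p-values.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ranks = spst.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            p[i, j] = p[j, i] = float(spst.studentized_range.sf(q, k, np.inf))
    return pd.DataFrame(p)


def group_comparisons(per_pair: pd.DataFrame,
                      fit_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group-level tests on the per-pair summaries (and per-bout MAEs)."""
    rows = []
    cols = ["control_K_mean", "classic_K_mean", "npk_K_mean"]
    complete = per_pair.dropna(subset=[c for c in cols if c in per_pair])

    fa = per_pair["frac_actual"].dropna()
    fc = per_pair["frac_control"].dropna()
    if len(fa) == len(fc) and len(fa) >= 2:
        diffs = fa.to_numpy() - fc.to_numpy()
        if np.allclose(diffs, 0):
            rows.append({"test": "fraction_K_lt_Kc", "method": "wilcoxon",
                         "statistic": 0.0, "p": 1.0, "n": len(fa)})
        else:
            res = spst.wilcoxon(fa, fc, alternative="two-sided")
            rows.append({"test": "fraction_K_lt_Kc", "method": "wilcoxon",
                         "statistic": float(res.statistic),
                         "p": float(res.pvalue), "n": len(fa)})
    if set(cols) <= set(complete.columns) and len(complete) >= 3:
        mat = complete[cols].to_numpy()
        if np.all(np.ptp(mat, axis=1) == 0):
            stat, p = 0.0, 1.0  # every block fully tied: no evidence of shift
        else:
            stat, p = spst.friedmanchisquare(*mat.T)
        rows.append({"test": "K_by_group", "method": "friedman",
                     "statistic": float(stat), "p": float(p), "n": len(complete)})
        pn = nemenyi_posthoc(mat)
        labels = ["control", "classic", "nonperiodic"]
        for i in range(3):
            for j in range(i + 1, 3):
                rows.append({"test": f"nemenyi_{labels[i]}_vs_{labels[j]}",
                             "method": "nemenyi",
                             "statistic": np.nan, "p": float(pn.iloc[i, j]),
                             "n": len(complete)})
    else:
        log.info("Friedman skipped: fewer than 3 complete pairs")
    if fit_table is not None and "mae_npk" in fit_table.columns:
        g = fit_table.dropna(subset=["mae_classic", "mae_npk"])
        if len(g) >= 5:
            res = spst.wilcoxon(g["mae_classic"], g["mae_npk"],
                                alternative="two-sided")
            rows.append({"test": "mae_classic_vs_npk", "method": "wilcoxon",
                         "statistic": float(res.statistic),
                         "p": float(res.pvalue), "n": len(g)})
    return pd.DataFrame(rows)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, RMSE of a simple least-squares line."""
    res = spst.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return float(res.slope), float(res.intercept), float(np.sqrt(np.mean(resid ** 2)))


def k_vs_omega_regression(fit_table: pd.DataFrame, group_col: str = "group",
                          groups: tuple[str, str] = ("coupled", "control"),
                          n_permutations: int = 10000,
                          seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-group OLS of K on Omega plus a permutation slope-difference test.

    The permutation null shuffles group labels and recomputes the absolute
    slope difference; p is the fraction of permuted differences at least as
    large as observed (with the +1 continuity correction).
    """
    rows = []
    arrays = {}
    for gname in groups:
        g = fit_table[fit_table[group_col] == gname]
        if len(g) < 3 or np.ptp(g["Omega"].to_numpy()) < 1e-12:
            log.info("regression skipped for group %s", gname)
            continue
        x = g["Omega"].to_numpy(dtype=float)
        y = g["K"].to_numpy(dtype=float)
        slope, intercept, rmse = _ols_line(x, y)
        arrays[gname] = (x, y)
        rows.append({"group": gname, "slope": slope, "intercept": intercept,
                     "rmse": rmse, "n": len(g)})
    regression = pd.DataFrame(rows)
    slope_test: dict = {"p": np.nan, "observed_diff": np.nan,
                        "n_permutations": 0}
    if len(arrays) == 2:
        (xa, ya), (xb, yb) = (arrays[g] for g in groups if g in arrays)
        observed = abs(_fast_slope(xa, ya) - _fast_slope(xb, yb))
        x = np.concatenate([xa, xb])
        y = np.concatenate([ya, yb])
        na = xa.size
        rng = np.random.default_rng(seed)
        count = 0
        idx = np.arange(x.size)
        for _ in range(n_permutations):
            rng.shuffle(idx)
            pa, pb = idx[:na], idx[na:]
            diff = abs(_fast_slope(x[pa], y[pa]) - _fast_slope(x[pb], y[pb]))
            if diff >= observed:
                count += 1
        slope_test = {"p": (count + 1) / (n_permutations + 1),
                      "observed_diff": float(observed),
                      "n_permutations": n_permutations}
    return regression, slope_test


def _fast_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    return float(np.dot(xm, y) / np.dot(xm, xm))


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.fit_table.to_csv(out / "fit_table.csv", index=False)
    report.discard_log.to_csv(out / "discard_log.csv", index=False)
    report.per_pair.to_csv(out / "per_pair.csv", index=False)
    report.group_tests.to_csv(out / "group_tests.csv", index=False)
    report.regression.to_csv(out / "k_vs_omega_regression.csv", index=False)
    summary = {
        "fraction_K_lt_Kc": report.fraction_K_lt_Kc,
        "slope_test": report.slope_test,
        "config": report.config,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, default=float))
    log.info("report written to %s", out)
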