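# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic-data experiments can show.

## State encoding and bout structure

Behavioral events are half-open intervals [onset, offset); a frame belongs
to an event iff its timestamp lies inside. Frames map to vigilance = 1.0,
feeding = 0.0, everything else = 0.5. The 0.5 code is deliberately
ambiguous in the numeric series — it covers both coded out-of-sight events
and uncoded gaps — so the encoder also records an *engagement* mask (frame
covered by any coded event). Bout segmentation uses the mask: a joint bout
is a maximal run in which both individuals are engaged, with interruptions
shorter than 10 s bridged and interruptions of 10.0 s or longer splitting
(the boundary splits, consistent with a "<10 s merges" rule). Out-of-sight
episodes therefore live *inside* bouts as transition states, while
behavioral breaks end them. Series built by hand without a mask fall back
to treating 0.5 as disengaged.

Bout inclusion: duration ≥ 10 s and at least one individual with ≥ 2
complete oscillations (net phase winding / 2π). Discarded bouts are logged
with reasons so every input bout is accounted for exactly once.

## Phase extraction

The 0/0.5/1 series is lowpass filtered and Hilbert-transformed; the
analytic-signal angle is the instantaneous phase θ(t) ∈ (−π, π].

* **Cutoff 2.78 Hz** — the maximal plausible head-oscillation rate
  (1000 °/s of head rotation = 2.78 cycles/s). The filter contract is a
  zero-phase FIR (Kaiser window, order from the transition band
  [cutoff, 1.25·cutoff]) with ≥ 40 dB stopband attenuation and ≤ 1 dB
  passband ripple, applied forward-backward so transitions are not shifted
  in time. A series must exceed the filter's padding length (3× the tap
  count, ≈ 9.7 s at 25 Hz) to be filterable; shorter bouts are rejected.
* **Centering 0.5** — the analytic signal is taken of (series − 0.5) so the
  trajectory rotates about the origin. An uncentered 0/1 signal has a DC
  offset comparable to its amplitude and yields degenerate, non-winding
  phases; the center is exposed as a config option.
* **Edge trim 0.5 s** — the analytic signal is distorted near the series
  ends, so the first and last 0.5 s are excluded from regression fitting
  (`edge_trim_s`). This is a package decision, not a property of the
  underlying procedure.
* Unwrapping uses the smallest-jump rule (±2π when a step exceeds π).

## Classic Kuramoto machinery

Dynamics: dΦ/dt = Ω − K sin Φ for the phase difference Φ = θ₂ − θ₁,
Ω = ω₂ − ω₁. All internal rates are rad/s. Fitted K and Ω are reported as
per-second phase increments — the convention in which the per-frame
regression "(Φ(t) − Φ(t−1))/0.04" is quoted in Hz in the behavioral
literature; `*_cycles` properties divide by 2π.

* **Fitting** — OLS of (Φₜ − Φₜ₋₁)/dt (unwrapped differences) on
  sin(wrapped Φₜ₋₁) with intercept; K = −slope, Ω = intercept. On
  noiseless Euler-simulated data the regression inverts the update to
  machine precision. A constant regressor (Φ fixed) is rejected as
  degenerate. Estimator caveats, both verified by tests: (1) additive
  measurement noise on a *locked* trajectory correlates with the regressor
  and biases K negative — only on drifting trajectories is the fit
  centered; (2) Hilbert-extracted phases are a smoothed, distorted proxy
  of any generative phase, so fitted K on simulated coupled bouts is
  strongly attenuated relative to the generator's coupling. Fitted values
  are comparable *across* bouts processed identically, which is how they
  are used.
* **Critical coupling** — K_c = −|Ω|; anti-phase locking attainable iff
  K < K_c. The equilibrium curve Φ = arcsin(1/(K/Ω)) (two circle branches,
  stability from the sign of −K cos Φ) has saddle-node bifurcations at
  K/Ω = ±1, located programmatically by bisection on the existence of real
  equilibria.
* **Time to anti-phase synchrony** — T = ∫ dΦ/(Ω − K sin Φ) from the
  initial Φ to the stable equilibrium. Because the integrand diverges at
  the equilibrium, "arrived" means within 0.01 rad of it. In the
  synchronizing regime Ω² − K² < 0, so the textbook arctan antiderivative
  is imaginary; the real form used is
  F(Φ) = (1/D)·ln|(Ω·tan(Φ/2) − K − D)/(Ω·tan(Φ/2) − K + D)| with
  D = √(K² − Ω²), which satisfies F′ = 1/(Ω − K sin Φ) and is continuous
  across Φ = π (both one-sided limits vanish), so no branch bookkeeping is
  needed between equilibria. Every closed-form value is cross-checked
  against direct ODE integration (`solve_ivp`, rtol 1e−10) and replaced by
  the oracle value (flagged) if they disagree by more than 5%; starting
  exactly on the unstable equilibrium reports T = ∞.
* **MAE** — mean absolute *wrapped* difference between observed Φ and the
  trajectory forward-simulated from the fitted (K, Ω) starting at the
  observed Φ(0).

## Non-periodic Kuramoto model

Each oscillator's natural frequency is 2π/(τ_V + τ_F) rad/s, where τ_V,
τ_F are exponential draws (means μ_V, μ_F) refreshed whenever the wrapped
phase crosses between the two half-circles (−π/2, π/2] and its complement;
initial draws happen at t = 0. Forward Euler at dt = 0.04 s. Two redraw
conventions are provided: `both` (default — both τ's redraw at every
crossing, the piecewise definition read literally) and `entered` (only the
entered state's τ). A zero-variance stub (`deterministic_tau`) reduces the
model framewise-exactly to a classic oscillator of frequency
1/(μ_V + μ_F) cycles/s, which anchors the implementation.

Note a structural property of this model: the rate is constant within a
cycle and the transition points split the circle in half, so each
behavioral region occupies half of every cycle *regardless* of the μ
ratio; only the distribution of τ_V + τ_F matters to the dynamics. A
variant in which state p is traversed at rate π/τ_p (making state p last
exactly τ_p, like the alternating-renewal control process) behaves
equivalently in every inference experiment we ran; the literal form is
implemented.

**Sweep inference.** The coupling of an observed bout is estimated by
simulating the model from the observed initial phases over the bout
duration for each K on the inclusive grid −5.0 … 0.0 (step 0.1, 51
values), 10 seeds per K, scoring each K by the mean angular distance
(mean pointwise |wrapped difference|, in [0, π]) to the observed phase
differences, and taking the grid argmin. The sweep backend advances all
51 × 10 simulations as one vectorized batch from a single seeded
generator; the scalar simulator keeps a per-simulation generator with a
fixed draw order for bitwise reproducibility.

**Known property: the sweep is a conservative, strongly negative
estimator.** The mean pointwise distance between a stochastic simulation
and a single noisy realization is minimized by the *least-variance*
predictor: for an anti-phase-concentrated observation with circular spread
σ, same-K simulations score ≈ 1.13 σ (E|X − Y| for independent copies)
while maximally coupled, near-pinned simulations score ≈ 0.8 σ (E|X|).
The argmin therefore sits at or near the most negative grid value for
essentially any coupled observation — self-recovery of a known K_true is
not achievable with this objective, and the corresponding recovery test
in the suite documents the failure honestly. The same property makes
non-periodic estimates systematically more negative than classic fits,
the directional ordering the model comparison expects, and it is why the
classic regression (an unbiased estimator of the −K sin Φ term) is the
package's recommended point estimator on synthetic coupled data.

## Synthetic data: what it emulates and what it does not

* **Control bouts** — each individual is an independent alternating
  renewal process (state p held for Exp(μ_p), then switch), discretized at
  25 Hz with values in {0, 1}. Defaults are the standard pair parameters:
  μ_F = 5.06/4.04 s, μ_V = 3.17/3.10 s, bout durations Exp(53.32 s)
  floored at 10 s (so control sets survive the inclusion filter), 100
  bouts per pair, 25 starting from each joint initial state (VV, VF, FV,
  FF). An optional corruption step inserts engaged 0.5 segments to
  exercise the out-of-sight path.
* **Coupled bouts** — the non-periodic simulator at a known K_true, with
  each oscillator's half-circle membership mapped to a {0, 1} state
  series; the generator's internal phases are returned for end-to-end
  validation of the phase-extraction chain (circular means agree within
  0.3 rad on 60 s bouts).
* **Not emulated** — observer coding noise, camera dropouts, session
  truncation rules, pair-specific parameter heterogeneity, and any
  behavior beyond the two-state alternation. Passing tests show the
  pipeline's internal consistency under the model's own assumptions, not
  that real animals satisfy those assumptions.

## Group-level statistics

Per-pair summaries feed two-sided Wilcoxon signed-rank tests (fraction of
bouts with K < K_c, actual vs control; per-bout MAE, classic vs
non-periodic), a Friedman test across {control K, classic K, non-periodic
K} with a post-hoc Nemenyi test (mean-rank differences against the
studentized-range distribution, the PMCMR convention; fully tied blocks
report statistic 0, p 1), and Spearman correlations of pair members'
oscillation periods. The comparison of K-on-Ω regression lines between
groups uses a permutation test: group labels are shuffled (default 10⁴
permutations) and the absolute OLS slope difference recomputed — this
answers "are the two lines unequal" without the bandwidth choices of a
smoothing-based analysis of covariance, and is a deliberate design
substitution. p-values are reported unadjusted; test families are
labelled in the report.

The control-null K-on-Ω slope deserves a caveat: per-bout (K, Ω)
estimates are heavy-tailed (short bouts where one individual completes
barely one oscillation produce high-leverage points), so the OLS slope of
a 700-bout set scatters far more between replicate sets (sd ≈ 0.2) than
its nominal standard error suggests. The suite's null check therefore
uses a heteroscedasticity-robust (HC3) standard error.

## Problem sizes and determinism

Default experiment sizes: 700 control bouts for the null regression, 40
coupled bouts for the model-comparison tests, 50 sweep-recovery trials
per coupling level, 10⁴ permutations for slope tests, 1000 bootstrap
replicates for ratio nulls. Every generator and experiment takes an
explicit seed; identical seeds give bitwise-identical outputs (scalar
simulators) or identical results (vectorized sweep, permutation and
bootstrap machinery).
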