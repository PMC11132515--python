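# pairsync

Coupled-oscillator analysis of paired vigilance/feeding behavior.

When two animals feed side by side and cannot feed and scan for predators
at the same time, they often fall into turn-taking: one is vigilant while
the other feeds. `pairsync` treats each individual as an oscillator cycling
between the two behaviors and quantifies this *anti-phase synchrony* with
the two-oscillator Kuramoto model. It is aimed at behavioral ecologists and
computational ethologists who have framewise behavioral codings (or want to
simulate them) and need per-bout estimates of coupling strength, the
threshold for synchrony, and the time needed to reach it.

## The model

Each individual carries a phase θᵢ; the pair obeys

    dθ₁/dt = ω₁ + (K/2)·sin(θ₂ − θ₁)
    dθ₂/dt = ω₂ + (K/2)·sin(θ₁ − θ₂)

so the phase difference Φ = θ₂ − θ₁ follows **dΦ/dt = Ω − K·sin Φ** with
Ω = ω₂ − ω₁. Negative coupling K drives the pair toward Φ = π (opposite
behaviors — turn-taking); positive K toward Φ = 0. Real equilibria exist
only for |K/Ω| ≥ 1 (saddle-node bifurcations at K/Ω = ±1), so anti-phase
locking is attainable exactly when K is below the critical coupling
**K_c = −|Ω|**. The package provides:

* **Phase extraction** — framewise state series (vigilance = 1, feeding = 0,
  transition = 0.5, sampled at 25 Hz) are lowpass filtered at 2.78 Hz (the
  fastest plausible head-oscillation rate, from a 1000 °/s maximal head
  speed) and passed through the Hilbert transform; the analytic-signal
  angle is the instantaneous phase.
* **Fitting** — Euler-discretizing the Φ equation gives a linear regression
  of per-frame phase-difference increments on sin Φ; K = −slope,
  Ω = intercept. The closed-form time to anti-phase synchrony is evaluated
  and cross-checked against direct ODE integration.
* **A non-periodic Kuramoto model** — real animals are not periodic: state
  durations are roughly exponential. The non-periodic variant resamples
  each oscillator's natural frequency (2π/(τ_V + τ_F), τ ~ Exp(μ)) at every
  behavioral transition; its coupling is inferred by a parameter sweep
  (K ∈ [−5, 0] in 0.1 steps, 10 seeds per value, mean angular distance to
  the observed phase differences).
* **Control simulations** — independent alternating-renewal (Poisson
  switching) bouts quantify how much apparent coupling arises by chance.
* **Duration analysis** — exponential fits to state durations, pair-ratio
  statistics with bootstrap nulls, oscillation periods (μ_V + μ_F), and
  the group-level non-parametric tests.

## Worked example

Fit the classic model to a noiseless simulated bout (natural frequencies
0.1215 and 0.1823 cycles/s, coupling −1.2, 60 s):

```python
import numpy as np
import pairsync as ps

p = ps.KuramotoParams(omega1_cycles=0.1215, omega2_cycles=0.1823,
                      K=-1.2, duration_s=60.0, theta0=(0.0, np.pi / 2))
_, _, phi = ps.simulate_classic(p)
fit = ps.fit_classic(phi)
print(f"K = {fit.K:+.3f}  Omega = {fit.Omega:+.3f}  Kc = {fit.Kc:+.3f}")
print(f"antiphase attainable: {fit.antiphase_attainable}  "
      f"T = {fit.T_s:.2f} s ({fit.T_source})  MAE = {fit.mae_rad:.2e} rad")
```

prints

```
K = -1.200  Omega = +0.382  Kc = -0.382
antiphase attainable: True  T = 4.13 s (closed_form)  MAE = 1.71e-14 rad
```

The regression inverts the Euler update exactly (machine-precision MAE),
K < K_c confirms the anti-phase regime, and the pair would come within
0.01 rad of the stable anti-phase equilibrium in 4.13 s. K and Ω are
reported as per-second phase increments (the regression's "Hz"
convention); divide by 2π (`fit.K_cycles`, `fit.Omega_cycles`) for
cycles/s.

The command line drives the same machinery end to end on synthetic data:

```sh
pairsync --seed 0 --out-dir demo_out demo
```

```
pair_id  control_K_mean  classic_K_mean  npk_K_mean  frac_actual  frac_control
  pair1       -0.169          -0.112          -4.4        0.75        0.286
  pair2       -0.002          -0.404          -4.9        1.00        0.188
fraction K<Kc actual: 0.857, control: 0.233
```

Coupled synthetic pairs cross the critical-coupling threshold far more
often (0.86) than uncoupled controls (0.23), and the non-periodic sweep
estimates are more negative than the classic fits — see
`docs/methods.md` for why the sweep is a conservative, strongly negative
estimator. Subcommands `encode`, `simulate-control`, `simulate-coupled`,
`fit`, `sweep` and `report` expose the individual pipeline stages.

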