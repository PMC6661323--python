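# connectodelay

Delay-coupled oscillator brain network models on a connectome: simulation,
phase extraction, phase-locking statistics, and analytic phase predictions.

## What this is for

The white-matter tracts of the brain impose both a coupling strength
(streamline count) and a transmission delay (tract length over ~5 m/s) on
every pair of cortical regions.  For oscillatory regional activity, these
delays organise the *phases*: whether two regions lock in-phase or
anti-phase depends on the product of the entrainment frequency Ω and the
delay, and how far an individual region lags the population depends on its
connectivity strength.  `connectodelay` is for computational neuroscientists
who want to simulate and analyse this mechanism end to end:

* build or load a connectome (weights, tract lengths, hemisphere labels);
* place a self-sustained oscillator on each region — chaotic (Rössler),
  nonlinearly damped (van der Pol) or non-isochronous (Landau–Stuart) — and
  integrate the stochastic delay-coupled network (Euler–Maruyama with a
  ring-buffer delay history, numba-accelerated, bit-reproducible by seed);
* extract proper phases (quadrant-correct protophase, then the
  protophase-to-phase transformation θ = ⟨φ̇⟩ ∫ dφ/φ̇), hemispheric order
  parameters r·e^{iΨ}, the entrainment frequency Ω, and a
  synchronized/drifting classification;
* quantify pairwise coherence with windowed complex phase-locking values
  cPLV = ⟨e^{i(θ_i-θ_j)}⟩ (5 periods of Ω per window, 25% overlap) and
  per-link permutation-surrogate significance;
* compare the simulated phase arrangement against the analytic
  (Kuramoto-derived) prediction
  ⟨θ_i⟩ = arcsin((ω0−Ω)/(K_i r cos ΩΔτ)) − Ωτ̃, the per-node locking
  condition |ω0−Ω| ≤ K_i r cos ΩΔτ, and the anti-phase criterion
  cos(Ω τ_ext) < 0.

A seeded synthetic connectome generator (two hemispheres, heavy-tailed
weights, degree heterogeneity, bimodal delays with weighted means
6.5 ms / 19.6 ms) makes every stage testable without any data download.

## Worked example

```python
from connectodelay import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(
    model="ls",            # Landau–Stuart oscillators
    frequency_hz=20.0,     # principal oscillation frequency
    global_coupling=0.02,  # s^-1
    noise_intensity=0.25,  # s^-1
    seed=1, connectome_seed=1,   # 68-node synthetic connectome
))
s = report.summary
print(s["regime"], round(s["omega_hz"], 3),
      round(s["internal_lag_mean_rad"], 3),
      round(s["external_lag_mean_rad"], 3))
```

prints

```
anti_phase 19.967 -0.073 2.906
```

meaning: at 20 Hz the network settled into the anti-phase regime (the
measured Ω times the inter-hemispheric delay falls in the left complex
half-plane); the entrainment frequency 19.97 Hz is slightly depressed below
the nominal 20 Hz; significantly coherent intra-hemispheric links have a
circular-mean lag of −0.073 rad (zero-lag locking within hemispheres), while
inter-hemispheric links lock at 2.906 rad ≈ π (the hemispheres in
anti-phase).  Re-running the same config at `frequency_hz=5.0` gives
`in_phase 4.92 0.015 -0.202`: at 5 Hz both link classes are zero-centred.
`report.node_table` and `report.link_table` are pandas DataFrames with
per-node strengths, synchronization flags, mean relative phases, amplitudes
and peak frequencies, and per-link PLV/lag/significance.

The same pipeline is scriptable from a shell:

```bash
connectodelay synth --n-per-hemisphere 34 --seed 1 --out conn/
connectodelay run -c config.yml --out results/
connectodelay sweep -c grid.yml --out sweep/
```

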