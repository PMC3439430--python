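# glycosync

Synchronisation analysis of glycolytic oscillations in yeast cell populations,
at single-cell resolution.

Starved yeast cells given glucose show NADH autofluorescence oscillations with
periods of roughly 24–70 s. In dense populations the cells synchronise and the
summed (collective) signal oscillates; below a critical cell density
ρ_c ≈ 0.3 % w/v the individual cells keep oscillating but lose phase and
frequency coherence, so the collective signal goes quiescent — a Kuramoto
transition rather than a cessation of single-cell rhythms. `glycosync`
implements the full analysis used to establish this, together with a synthetic
population generator so every stage can be verified without laboratory data.

The package is for quantitative biologists and biophysicists who have (or want
to simulate) per-cell fluorescence time series or photon-counting frame
stacks, and want population synchrony statistics out the other end.

## What it computes

For per-cell signals s_i(t) on a uniform 2 s grid:

- **Extraction** (for frame stacks): F_i = P_i/|A_i|, the mean photon count
  over the pixel area A_i occupied by cell i, plus the collective photon sum.
- **Preprocessing**: walking-average baseline subtraction (window = one
  oscillation period), brick-wall Fourier bandpass keeping 0.014–0.05 Hz,
  optional 3-point adjacent-average smoothing, amplitude normalisation
  against the loudest cell.
- **Periods**: per-cell dominant FFT period T_i, an oscillation classifier
  (dominant-peak power fraction against a white-noise Monte-Carlo null), the
  dispersion σ_T = [(1/N) Σ_i (T_i − T̄)²]^{1/2}, and a Gaussian fit to the
  period histogram. σ_T ≤ 2 s (the sampling interval) marks frequency
  coherence.
- **Phases and synchrony**: instantaneous phases φ_i(t) = atan2(H[s_i], s_i)
  from the Hilbert transform H, the Shinomoto–Kuramoto order parameter
  K(t) = |(1/N) Σ_i e^{iφ_i(t)}|, and its time average K̄ with spread σ_K.
  K̄ → 1 for coherent populations and → 0.886/√N for random phases.
- **Transition detection**: density sweeps of simulated populations and a
  logistic fit of K̄ versus log₁₀ρ whose midpoint estimates the critical
  density ρ_c.

The simulator integrates a mean-field Kuramoto model
dφ_i = [ω_i + (g/N) Σ_j sin(φ_j − φ_i)] dt + √(2D) dW_i with Gaussian natural
periods clipped to 24–70 s, an amplitude envelope (onset ≈ 350 s, decay after
glucose exhaustion ≈ 1800 s), Poisson photon emission, and a linear
density → coupling law calibrated so the deterministic threshold sits at
0.3 % w/v. It can also render 512×512 photon-count TIFF stacks
(0.33 µm/pixel, 169 µm circular field of view) for testing the imaging path.

## Worked example

```python
import numpy as np
from glycosync import PopulationConfig, simulate_population, analyze_traces

# a dense (0.7 % w/v) and a sparse, uncoupled population
dense = PopulationConfig(n_cells=50, density_pct=0.7, seed=1)
sparse = PopulationConfig(n_cells=30, coupling_scale=0.0, period_sd_s=8.0, seed=1)

for name, cfg in [("dense", dense), ("sparse", sparse)]:
    traces, truth = simulate_population(cfg)
    result = analyze_traces(traces, interval_s=(410, 1800))
    print(f"{name}: K_bar={result.sync_summary.k_mean:.3f} "
          f"sigma_K={result.sync_summary.k_std:.3f} "
          f"sigma_T={result.period_stats.sigma_t_s:.2f} s "
          f"oscillating={result.period_stats.n_oscillating}/{cfg.n_cells}")
```

prints

```
dense: K_bar=0.935 sigma_K=0.009 sigma_T=0.00 s oscillating=50/50
sparse: K_bar=0.159 sigma_K=0.096 sigma_T=7.52 s oscillating=30/30
```

The dense population phase-locks (K̄ ≈ 0.94, all cells on one FFT bin so
σ_T ≈ 0); the uncoupled one sits at the 30-cell random-phase floor
(0.886/√30 ≈ 0.16) with periods spread over several seconds. A full density
sweep with critical-density fit:

```python
from glycosync import run_density_sweep, estimate_critical_density

sweep = run_density_sweep(PopulationConfig(seed=1),
                          np.logspace(-3, np.log10(0.8), 8), replicates=10)
fit = estimate_critical_density(sweep)
print(fit.summary())
```

```
Critical-density logistic fit
---------------------------------
rho_c                 0.309 % w/v
95% CI             [0.309, 0.309] % w/v
incoherent plateau    0.257
coherent plateau      0.953
logistic width        0.001 decades
sigma_T > 2 s below      0.308 % w/v
```

Both coherence measures place the transition at ≈0.3 % w/v, the calibrated
ground truth. The same pipeline is available from the shell:

```bash
glycosync simulate --n-cells 50 --seed 1 --out run/
glycosync analyze --traces run/traces.csv --interval 410 1800 --out run/analysis/
glycosync sweep --densities 0.001,0.01,0.1,0.3,0.8 --replicates 5 --seed 1 --out run/sweep/
```

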