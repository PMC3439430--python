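# Methods

## The model

`glycosync` treats each yeast cell as a self-sustained phase oscillator. The
population obeys the stochastic mean-field Kuramoto equations

    dφ_i = [ ω_i + (g/N) Σ_j sin(φ_j − φ_i) ] dt + √(2D) dW_i ,

with natural frequencies ω_i = 2π/T_i, natural periods T_i drawn from a
Gaussian and clipped to the physiologically supported band 24–70 s, and D a
phase-diffusion coefficient for intrinsic metabolic noise. The choice of a
phase model (rather than mechanistic glycolysis kinetics) reflects what the
analysis is about: the density-dependent loss of phase coherence is a
Kuramoto transition, and the phase model is the minimal generative process
exhibiting it. Amplitude dynamics are deliberately *not* emergent: observed
fluorescence is

    F_i(t) = baseline + A_i(t) · (1 + sin φ_i(t)) / 2     [photons/s]

with an imposed per-cell envelope A_i(t) — a logistic ramp around the
oscillation onset and an exponential decay after glucose exhaustion — and
photon counting is Poisson per 2 s sample. The simulator therefore reproduces
the *shape* of real recordings (transient onset ≈ 350 s after glucose
addition, amplitude decay after ≈ 1800 s, 60–140 photons/s oscillation
amplitudes on a ~100 photons/s background, shot noise) without claiming a
mechanistic amplitude model.

### Density → coupling calibration

Cell-to-cell coupling is assumed mediated by the extracellular (mean-field)
concentration of a messenger molecule, so coupling strength is taken linear
in cell density:

    g(ρ) = g_c · (ρ / 0.3 %) · coupling_scale ,

where g_c = 2 σ_ω √(2/π) is the classical mean-field critical coupling for
Gaussian frequency spread σ_ω (obtained from the period spread by the delta
method, σ_ω ≈ 2π σ_T / T̄²). With the default `coupling_scale = 1` the
deterministic threshold thus sits exactly at ρ = 0.3 % w/v. This bakes the
empirically known critical density into the generator as recoverable ground
truth — the point of the synthetic module is that the analysis pipeline
should find it again. The 1 % w/v ≡ 1.5×10⁸ cells/ml conversion is used for
reporting only.

### Integration and determinism

Explicit Euler–Maruyama with an internal step of dt/10 (0.2 s at the default
2 s sampling), subsampled to the output grid. At ω ≈ 0.16 rad/s this resolves
the fastest supported oscillation (24 s period) with ~120 internal steps per
cycle; the free-rotation case reproduces the closed-form phase ramp to
≤ 1e−8 rad, which the test suite asserts. All randomness derives from a
single config seed split into four independent streams (periods/initial
phases, dynamical noise, envelope draws, photon emission), so identical
configs give bit-identical traces, and consuming one stream more or less
never silently shifts another.

## Simulator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| dt_s | 2 s | photon flux integration interval of the detector |
| duration_s | 2000 s | one batch experiment from glucose addition to past exhaustion |
| period_mean_s / period_sd_s | 40 / 8 s | desynchronised populations span the 24–70 s band (≈ ±2 sd) |
| onset_mean_s, onset_ramp_s | 350 s, 60 s | induction delay after glucose addition |
| exhaustion_s, decay_tau_s | 1800 s, 150 s | amplitude decay at glucose exhaustion |
| amp_range_photons | 60–140 | per-cell oscillation amplitudes at high density |
| baseline_photons | 100 | non-oscillatory background per cell |
| phase_noise_intensity | 0.002 rad²/s | phase sd ≈ 0.4 rad over one 40 s cycle: visibly rhythmic single cells |

What the generator does **not** emulate: mechanistic amplitude–density
covariation (amplitude, onset statistics and coupling are independent knobs),
spatially local coupling (the mean field is global, so adjacency carries no
frequency information — the adjacent-cell consistency test exploits this),
cell movement, detector artefacts (PSF blur, dead time, bleaching), or
touching/overlapping cells. Passing tests therefore demonstrate that the
*analysis* is correct and that the *transition phenomenology* is recovered
under a faithful noise model — not that real cells follow mean-field Kuramoto
dynamics in detail.

## Analysis pipeline choices

- **Baseline**: centred walking average with a one-period window, truncated
  (shrinking) at the edges so length is preserved. When the period is not
  supplied, a two-pass scheme is used: a first-pass FFT of the raw,
  mean-removed trace gives a provisional per-cell period for the window, and
  final periods are re-estimated after filtering.
- **Bandpass**: a literal brick-wall spectral gate — DFT coefficients with
  frequency outside [0.014, 0.05] Hz (inclusive) are zeroed. Bin-centred
  in-band tones pass bit-faithfully; DC and out-of-band tones vanish to
  rounding; the filter is exactly idempotent. The price is Gibbs ringing at
  sharp transients, accepted for reproducibility over a tapered design.
- **Period readout**: dominant in-band FFT bin; resolution 1/(N·dt)
  (≈ 0.5 mHz for a 2000 s trace) is reported with each estimate. No
  interpolation between bins: the coherence criterion (σ_T vs the 2 s
  sampling interval) is defined at this resolution, and phase-locked
  populations collapse onto a single bin, giving σ_T ≈ 0.
- **Oscillation classifier**: the in-band dominant-peak power fraction is
  compared against the 95th percentile of the same statistic on white-noise
  traces of matched length (400 Monte-Carlo draws, fixed internal seed,
  cached). Self-calibrating across trace lengths; ties count as oscillating.
- **σ_T normalisation**: population form (1/N). The statistic is
  descriptive; the sample form is available via `ddof=1`.
- **Gaussian histogram fit**: bin width equals the sampling interval;
  degenerate histograms (< 3 occupied bins, as in fully locked populations)
  yield NaN rather than a fabricated width.
- **Phases**: φ = atan2(H[s], s) with the filtered signal as real part,
  wrapped to (−π, π]. Identically-zero traces get an undefined phase (NaN,
  warned) and are excluded per sample from K(t) with the usable-cell count
  recorded.
- **Order parameter**: by default computed over cells flagged oscillating
  (falling back to all cells when fewer than two qualify), with the first and
  last half median period masked against Hilbert endpoint artefacts. K is
  clipped into [0, 1] only to absorb ~1e−16 phasor-sum rounding.
- **Averaging interval**: K̄ and σ_K default to the full usable series; the
  sweep and the worked examples use the post-onset window (onset + ramp to
  exhaustion, 410–1800 s at default settings), since the pre-onset transient
  would bias K̄ downward.
- **Amplitude normalisation**: per-cell amplitude = maximum of the Hilbert
  envelope of the filtered trace (peak-to-peak was the alternative; the
  envelope is less sensitive to single noisy samples), normalised by the
  loudest cell.

## Density sweeps and the critical density

Each sweep row simulates an independent population (seeds split
deterministically from the master seed via `SeedSequence`), runs the full
pipeline, and records (ρ, K̄, σ_K, σ_T, Gaussian σ, n_oscillating, collective
oscillation flag). The per-replicate cell count follows plating density,
n = clip(round(330·ρ), 10, 100): ≈ cells inside the 169 µm field of view at
these densities, floored so the random-phase level 0.886/√N stays a
meaningful baseline, and capped for tractability. Note the consequence,
visible in real measurements too: at very low density the *expected* K̄
rises simply because N is small.

ρ_c is estimated by least squares as the midpoint of a four-parameter
logistic in log₁₀ρ (lower/upper plateau, midpoint, width), the density where
K̄ crosses half-way between the fitted plateaus, with a 95 % interval from
the covariance of the midpoint. The estimate is invariant to row order and
duplication. A sweep whose K̄ span never exceeds 0.2 is reported as "no
transition" instead of a number. Two companion readouts are reported
descriptively, not fitted: the σ_T changepoint (first density, descending,
with median σ_T > 2 s) and the density below which the summed collective
signal stops passing the oscillation classifier — the latter sits well below
ρ_c because collective quiescence requires complete decoherence, not just
the loss of full synchrony.

Default sweep sizes (8 log-spaced densities 0.001–0.8 %, 10 replicates,
≤ 100 cells, 2000 s at 2 s sampling) run in well under a minute on one CPU;
they are the package's reference problem size and are what the acceptance
script uses.

## Imaging path

Rendering distributes each cell's integer photon count per frame
multinomially (or deterministically evenly, for exactness tests) over a disk
of pixels at a non-overlapping random position inside the circular field of
view (512×512 px, 0.33 µm/px, ⌀169 µm), so photons are conserved exactly per
cell and per frame. Segmentation — unspecified in real workflows, where cells
were marked by hand — is an Otsu threshold on the time-summed image plus
connected components and a minimum-area filter, adequate for the rendered
fixtures only. Extraction averages photons over ROI pixels (units: photons
per pixel per sampling interval; divide by dt for photons/s) and returns the
collective per-frame photon sum alongside.

## Known limitations

- The logistic-midpoint estimator locates the steepest observable rise of
  K̄, which for a shallow (square-root-like) order-parameter onset can sit
  slightly above the deterministic threshold; with the default calibration
  and grid the bias is within one density grid point (≈ 0.31 vs 0.30 % w/v).
- Brick-wall filtering rings at sharp amplitude transients; the masked edges
  and post-onset averaging window mitigate but do not remove this.
- The segmentation utility does not split touching cells.
- No time-resolved frequency tracking (windowed/wavelet) — per-cell periods
  are whole-trace summaries.
- Surrogate-data significance testing of K̄ is out of scope.
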