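# toneadapt

Spike-train analysis of adaptation in pure-tone sequences: stimulation-protocol
construction, Poisson likelihood-ratio responsiveness testing, PSTH
onset-latency estimation, frequency-response areas and best frequencies,
stimulus-specific-adaptation (SSA) indices, and a narrow-frequency-channel
adaptation model with per-unit fitting and a leave-the-deviants-out
sensitivity analysis. A synthetic adapting-neuron simulator generates spike
trains with the statistical structure the analysis assumes, so every stage is
testable without recorded data.

## Overview

| module | contents |
| --- | --- |
| `toneadapt.stimuli` | the nine stimulation protocols (oddball ×2, rare ×2, equal, diverse broad/narrow, FRA, BBN) as reproducible event logs |
| `toneadapt.simulate` | ground-truth units (Gaussian log-frequency tuning, resource-depletion adaptation with exponential recovery, boxcar evoked response, optional deviance boost) and inhomogeneous-Poisson spike simulation |
| `toneadapt.responsiveness` | activity filter (≥30 spikes in [−100, +100) ms) and the likelihood-ratio test of evoked activity against a baseline-rate null, 2LL ~ χ²(10) |
| `toneadapt.latency` | PSTH binning, 5-ms square smoothing, and the onset estimator (first prominent supra-threshold peak → preceding minimum → quadratic fit → 25% crossing → +1.5 ms shift) |
| `toneadapt.tuning` | FRA matrices (mean counts in [0, 100) ms) and best frequency from the three loudest levels |
| `toneadapt.ssa` | 40-ms response tables, CSI/SI indices, the steady-state adaptation model `(1−δ)/(1−(1−ū)δ)` with Gaussian-in-log-frequency depletion kernel, per-unit `(σ, δ)` least-squares fitting, leave-the-deviants-out prediction error |
| `toneadapt.io`, `toneadapt.config`, `toneadapt.pipeline`, `toneadapt.cli` | delimited-text interchange, YAML config collecting every analysis constant, end-to-end orchestration, CLI |

## CLI

```bash
# full pipeline on the configured simulated populations
toneadapt run-all --seed 0 --out out/

# individual pieces
toneadapt protocols --name diverse_narrow --f1 8000 --seed 1 --out out/
toneadapt simulate --config cfg.yaml --out out/
toneadapt ssa --config cfg.yaml --out out/
```

`RunConfig` (YAML) holds every analysis constant — activity threshold
(30 spikes), onset-peak threshold (7 SD), prominence (5% SD), quadratic
crossing (25%), smoothing correction (1.5 ms), SSA window (40 ms), rare-count
minimum (5 spikes), significance levels (0.01, Bonferroni 0.005) — all
overridable.

## Notes on conventions

- Natural logarithms throughout the frequency kernel; channel width σ is in
  natural-log frequency units.
- A 12-frequency ladder at ratio 1.44 spans a factor ≈55.2 against an allowed
  range of 64×, so only discrete bands of test frequencies admit a
  diverse-broad design inside 1–64 kHz; `stimuli.feasible_broad_f1` snaps an
  arbitrary frequency to the nearest feasible one, and the population
  simulator uses it when centering test frequencies on a unit's best
  frequency.
- The +1.5 ms onset correction is applied as a delay (centered smoothing
  advances the apparent rise; the correction must move the estimate later).
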