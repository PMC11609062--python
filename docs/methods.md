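# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `emgsynergy`.  It is the companion to the API docstrings:
those say *what* each function computes; this note says *why* it is
computed that way and what the synthetic benchmarks do and do not show.

## Preprocessing

Raw multi-channel EMG sampled at 1,111 Hz is converted to event-locked
cycles in four steps.

1. **Event detection.** The metronome/click channel is rectified and its
   envelope taken as a zero-phase low-pass (default 30 Hz) of the
   rectified signal; local maxima with a minimum spacing of half the
   nominal beat period (0.375 s at 80 bpm) are the reference timings.
   When the instrument is struck once per bar, the epoching events are
   every 4th click (`select_downbeats`).
2. **Filtering.** Each EMG channel is demeaned, full-wave rectified, and
   low-pass filtered with a 4th-order Butterworth at 20 Hz.  Filtering
   is zero-phase (forward–backward `sosfiltfilt`): the feature stage
   reports activation peak *timings*, and a causal filter would bias
   every peak late by a signal-dependent lag.  The effective attenuation
   order doubles; the documented cutoff refers to the designed filter.
3. **Epoching.** ±0.75 s windows around each event are resampled to 151
   points (10 ms grid) by linear interpolation; small negative values
   from filter ringing are clipped to zero (the factorization requires
   nonnegativity).  Events without a full window are dropped and
   counted.
4. **Normalization.** Cycles are flattened to a 10 × (151·n) matrix.
   Each muscle row has its minimum subtracted and is divided by
   (max − min), then by the standard deviation σ of the range-normalized
   row, giving unit sample variance so every muscle is weighted equally
   in the factorization.  The phrase "divide by the maximum" is
   ambiguous in common usage; dividing by (max − min), so rows span
   [0, 1], is the default, with the literal divide-by-max variant behind
   `divisor="max"`.  Likewise σ is computed on the range-normalized row
   by default (`sigma_on="raw"` for the raw row).  Both (min, max) and σ
   are stored so the scaling can be reverted exactly.

## Factorization

`nmf.extract` implements Lee–Seung multiplicative updates for the
squared Frobenius objective.  Numerical specifics:

- A small ε (10⁻¹²) is added to denominators only; zeros in the factors
  are therefore preserved exactly across iterations, which the
  shared/specific model relies on for its structural-zero blocks.
- Convergence is declared when the squared error changes by less than
  `tol · ‖M‖²_F` between checks (every 5 iterations).
- Best of `n_restarts` seeded random initializations (default 5);
  an explicit `init=(W0, C0)` can replace the first restart.
- A weight column collapsing to zero is re-seeded (degenerate-synergy
  guard) rather than silently returning a smaller model.
- Reported models have unit-norm weight columns with the norms absorbed
  into the coefficients; `rescale_weights` reverts the per-muscle
  unit-variance scaling (rows × σ) and re-normalizes.

Coefficients for a *fixed* W (test folds, feature refits) are obtained
by exact nonnegative least squares per time sample rather than by
C-only multiplicative updates: the per-column optimum is unique,
deterministic, and independent of iteration budgets.

**VAF.** The default is the uncentered coefficient of determination,
`100 × (1 − SSE/ΣM²)`.  The uncentered-correlation reading
(`method="corr"`) is also implemented; the two agree at high fit quality
but the SSE form is the one under which the reported hand example
([1,2] vs [1,1] → 80.0) and the selection thresholds are defined.

## Selecting the number of synergies

Cycles are split at the cycle level into 80% training / 20% test (16/4
for a 20-cycle dataset), synergies are extracted from the normalized
training cycles, test coefficients are refit by NNLS, and the test VAF
recorded for N = 1..10; 20 repetitions are averaged.  Normalization
statistics come from the training cycles only (`stats_from="pooled"`
reproduces the literal normalize-then-split order; the difference is
negligible at these sizes but the default avoids leakage).  For a large
reference dataset the same split cycle runs inside a bootstrap over
random 20-cycle subsamples (default 1,000), and the 2.5th/97.5th
percentiles give a 95% CI per N.

The plateau rule (`choose_n`) fits an ordinary least-squares line to the
VAF curve's suffix [N..n_max] on the fractional (0–1) scale and selects
the smallest N whose fit MSE falls below 10⁻⁵.  On the percent scale a
10⁻⁵ threshold would never be met; on the fractional scale the observed
near-plateau MSE values (~10⁻⁶–10⁻⁵) bracket the threshold exactly as
intended.  Suffixes with fewer than three points are skipped — one or
two points fit a line exactly, which would make the residual test
vacuous and silently select n_max − 1 on curves without any plateau.
If no suffix qualifies, n_max is returned with `plateau_found=False`.

Inside these heavily repeated loops the factorization runs with 2
restarts, 500 iterations and `tol=10⁻⁵` (`CV_NMF_PARAMS`); the
averaging over 20 repetitions absorbs the extra optimizer noise, and
one-off extractions keep the deeper defaults.

## Bootstrap confidence intervals and constrained clustering

Synergies are re-extracted from 1,000 random 20-cycle subsamples (each
normalized on its own subsample, σ-reverted afterwards).  The resulting
weight vectors are clustered by k-means under cosine distance with a
cannot-link constraint: two synergies from the same replicate may never
share a cluster.  The assignment step solves, per replicate, the optimal
one-to-one matching of its k synergies to the k centroids (Hungarian
algorithm) — the only assignment rule that satisfies the constraint by
construction; greedy constrained assignment can deadlock.  Centroids are
normalized means; iteration stops when assignments stabilize, and the
total within-cluster distance is non-increasing because both steps are
exact minimizers.  Initial centroids are one randomly chosen replicate's
synergies.  95% CIs are percentile bounds across replicates, for weights
and for cycle-averaged 151-point activation profiles.

## Shared and condition-specific synergies

The two conditions' cycles are pooled and normalized **jointly** (one
per-muscle scaling for the pooled matrix).  This is load-bearing: with
per-condition normalization the same underlying synergy has *different*
spatial directions in the two conditions' normalized spaces (each
muscle is rescaled by its own condition's range and σ), so genuinely
shared structure is penalized and per-condition VAF references are not
comparable with the pooled model's.  In the pooled space a synergy
common to both conditions has a single direction, and a per-condition
model fitted in its own normalized space can be transported into the
pooled space *exactly* (both normalizations are per-muscle affine maps
of the same raw data, so each weight row is multiplied by the ratio of
scale factors).

`condition_references` uses that mapping: each condition is fitted in
its own space — where module recovery is empirically most reliable —
with a deep search (10 restarts), mapped into pooled space, and
evaluated on its own pooled columns.  The resulting VAFs are the
acceptance references, and they are exact feasible points of the
no-sharing pooled model.

`select_split` starts at the no-sharing total N_A + N_B and reduces the
total one synergy at a time.  At each total, candidate partitions
(n_shared, n_specific_A, n_specific_B) are enumerated most-shared-first
under the constraint that neither condition receives more synergies than
its own analysis selected (relaxed only if no partition qualifies); each
candidate is fitted with structural zeros and accepted if both
condition-wise VAFs reach the references minus a 0.1 percentage-point
optimizer slack.  The search stops at the first total where no candidate
is acceptable and returns the accepted model with the minimal total.
Every candidate is warm-started from the mapped reference models (the
n_sh most cosine-similar cross-condition pairs seed the shared block,
the least-similar leftovers the specific blocks); without the warm
start, restart-to-restart variation (~0.5–1.5 pp) is as large as the
VAF signal separating correct from incorrect partitions, and the
selection becomes noise-driven.  The 0.1 pp slack is an order of
magnitude below the observed per-condition VAF cost (~0.5–1.3 pp) of
removing a genuinely needed synergy.

## Features

Temporal profiles are cycle-averages of the coefficient rows (the
coefficient matrix holds consecutive 151-point cycles).  Peaks are grid
argmaxima — times on the 10 ms grid, negative before the metronome
sound, ties broken toward the earlier time; an all-zero profile is
flagged rather than given a fake peak.  Spatial modules of two
conditions are paired by the assignment maximizing total cosine
similarity, and the per-pair cosine r is reported; r is invariant to
positive rescaling, so it is unaffected by the σ-reversion convention.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: 97
asymptomatic and 20 symptomatic cycles of 10-muscle EMG at 1,111 Hz, one
analyzed pedal strike per 3 s bar of an 80 bpm metronome.  Ground truth
is six synergies per condition — five shared plus one specific — each a
unit-norm weight vector with a Gaussian activation bump (default width
60 ms, the 10 ms grid of the 151-point axis).  Shared peak times and
amplitudes follow the asymptomatic condition's reported profiles
(−320 ms/0.37, −220 ms/0.20, −60 ms/0.26, +30 ms/0.59, +50 ms/0.50);
the symptomatic condition shifts the dorsiflexor module 100 ms earlier
at 2.9× amplitude (0.20 → 0.58).  The asymptomatic-specific synergy is
toe-extensor-dominant (EDB, −180 ms, 0.11); the symptomatic-specific
one is BF/VM-dominant (+150 ms, 0.45, between the printed late-cycle
stabilizer peaks of 0.50/0.59).  Weight vectors follow the reported
one-dominant-muscle-group-per-synergy structure with small
cross-memberships.

Per-cycle variability: amplitudes are scaled by exp(N(0, σ)) with
σ = 0.6 and peak times jittered by N(0, 10 ms), independently per
synergy and cycle.  The amplitude variability is deliberately strong
(±60–100%, plausible for beat-to-beat variation in a task where
symptoms themselves come and go): independent amplitude modulation is
what renders temporally adjacent synergies identifiable at all — with
near-constant amplitudes, two bumps 20–100 ms apart keep a fixed mixing
ratio in every cycle and any factorization can replace them with a
single merged module at almost no cost, so no data-driven rule could
recover the planted synergy number.

Noise is i.i.d. Gaussian per sample, scaled per channel (σ_m
proportional to the channel's RMS — measurement and physiological noise
scale with signal amplitude; a global noise floor would turn weak
channels into pure noise after the per-muscle variance equalization) and
truncated at zero.  The SNR parameter describes the **emitted** data:
the noise scale is solved by bisection so that the realized
signal-to-distortion power ratio after truncation equals `snr`
(truncation discards roughly half the drawn noise power; scaling before
truncation would make the data about twice as clean as requested).  At
the default snr = 10 the resulting reconstruction VAFs at the true
synergy number (~96–97.5%) and plateau-rule MSE values (~2·10⁻⁶–2·10⁻⁵)
sit in the ranges a real recording of this kind produces.

`simulate_session` additionally emits a continuous raw recording: a
zero-mean broadband carrier amplitude-modulated by each muscle's
envelope, a synchronized click channel (clicks every 0.75 s, one
analyzed cycle per `beats_per_cycle` clicks, windows guaranteed inside
the recording), and a sensor-noise floor two orders of magnitude below
signal power.  The default carrier has random sign and unit magnitude,
so full-wave rectification recovers the modulation envelope exactly and
the session → preprocess → cycles round trip isolates the pipeline's
own fidelity; `carrier="gauss"` gives Gaussian interference EMG, whose
rectified envelope estimate carries ~15% intrinsic fluctuation.

Cycle-level and session-level generation draw from condition-keyed seed
streams, so the session's underlying cycles equal `simulate_cycles`
output for the same spec, and everything is bit-reproducible from the
integer seed.

### What the synthetic benchmarks do not show

The generator produces smooth unimodal activations, exact low-rank
structure plus unstructured noise, and stationary statistics.  Real EMG
has structured residuals (crosstalk, motion artifacts, tremor),
non-Gaussian heavy-tailed noise, synergy waveforms that are neither
Gaussian nor time-invariant, and possible drift across trials.  Passing
the recovery benchmarks therefore demonstrates that the implementation
is correct and that the procedure can resolve the planted structure
under the stated variability — not that six synergies, or a 5+1+1
split, would be recovered from any particular real recording.

## Problem sizes

Default benchmark sizes were chosen so the full test suite runs in a few
minutes on one CPU: synergy-number recovery uses 10 datasets of 20
cycles (20 CV repetitions each), shared/specific recovery 5 datasets of
117 cycles, bootstrap/cluster checks use tens of replicates rather than
1,000.  The library defaults (1,000 bootstraps, 10 candidate N values,
5 restarts) match the analysis as described and are what `run_pipeline`
uses.

## Known limitations

- Artifact detection is out of scope; artifact cycles must be flagged
  manually (`TrialAnnotation`).
- The plateau rule's 10⁻⁵ threshold is sensitive to the overall noise
  scale of the data; on much cleaner or noisier recordings the suffix
  MSE values shift together and the rule may need its threshold
  revisited (exposed as `mse_threshold`).
- `select_split` explores partitions greedily per total (first
  acceptable, most-shared-first); it does not certify global optimality
  over all partitions, mirroring the sequential reduce-by-one procedure
  it implements.
- Only two conditions are supported in the shared/specific model.
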