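# emgsynergy

Muscle-synergy analysis of event-locked cyclic EMG, built for comparing
movement cycles recorded **with** and **without** dystonic symptoms in a
drummer playing a bass-drum pedal in time with an 80 bpm metronome.  The
package covers the full analysis chain — preprocessing, non-negative
matrix factorization (NMF), cross-validated selection of the synergy
number, bootstrap confidence intervals with cannot-link constrained
k-means, shared vs condition-specific synergy decomposition, and
temporal/spatial module features — together with a seeded synthetic-EMG
generator with known ground truth, so every stage is testable by
parameter recovery.

It is intended for motor-control researchers who want a tested, scripted
version of this analysis for their own cyclic-EMG recordings, or a
simulation bench for studying how the method behaves.

## The model

Each time sample of the preprocessed 10-muscle EMG matrix `M` is modeled
as a nonnegative linear combination of a few muscle synergies,

    M = Σᵢ Wᵢ Cᵢ + ε,   Wᵢ ≥ 0, Cᵢ ≥ 0,

where each column of `W` is a *spatial module* (a unit-norm muscle
weight vector) and the matching row of `C` is its *temporal module*
(activation coefficients across the ±0.75 s movement cycle, 151 points).
Factorization uses Lee–Seung multiplicative updates for the squared
Frobenius error, best of several seeded restarts.  Reconstruction
quality is the variance accounted for,

    VAF = 100 × (1 − Σ(M − Ŵ Ĉ)² / Σ M²),

computed without mean subtraction (nonnegative signals have a meaningful
zero).  The number of synergies is the smallest N from which the
cross-validated VAF curve is linear: a least-squares line is fitted to
the curve's suffix [N..10] (fractional VAF scale) and N is selected once
the fit's mean squared error drops below 10⁻⁵.

For two conditions, the pooled matrix is factorized with structural
zeros: shared synergies may activate anywhere, while each
condition-specific synergy's coefficients are exactly zero on the other
condition's columns (multiplicative updates preserve zeros).  Starting
from the no-sharing solution, the total synergy count is reduced one at
a time while each condition's VAF still reaches the VAF of its own
separate analysis.

## Worked example

```python
import emgsynergy as es
from emgsynergy import selection, shared

sim = es.simulate_cycles(es.default_spec(seed=1))   # 97 + 20 cycles, SNR 10

# step 1: how many synergies does the symptomatic data need?
curve = selection.cross_validate(sim.cycles_b, seed=101)
selection.choose_n(curve)
print("selected N =", curve.n_selected)

# step 2: how many synergies are shared between the conditions?
pooled = shared.pool(sim.cycles_a, sim.cycles_b)
ref_a, ref_b = shared.condition_references(
    sim.cycles_a, sim.cycles_b, pooled, 6, 6, seed=1)
model = shared.select_split(
    pooled, 6, 6, ref_a.vaf_pct, ref_b.vaf_pct, seed=1,
    ref_sets=(ref_a, ref_b))
print(f"shared = {model.n_sh}, specific = {model.n_a}/{model.n_b}")
print(f"VAF: pooled {model.vaf_pooled:.2f}%, "
      f"without {model.vaf_a:.2f}%, with {model.vaf_b:.2f}%")
```

Output:

```
selected N = 6
shared = 5, specific = 1/1
VAF: pooled 97.79%, without 97.68%, with 98.00%
```

The generator plants six synergies per condition, five of them shared;
the cross-validated plateau rule recovers N = 6 and the pooled
decomposition recovers the 5 + 1 + 1 split, with the symptomatic
condition's dorsiflexor module shifted 100 ms earlier at 2.9× amplitude
(recoverable via `emgsynergy.features`).

A command-line interface mirrors the library (`emgsynergy simulate`,
`preprocess`, `select-n`, `bootstrap-ci`, `shared-specific`, `features`,
`run-all`); `run-all` executes the whole two-step analysis from a YAML
config and writes CSV/JSON artifacts plus a run manifest.

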