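"""Synergy-number selection: cross-validated VAF curves and the linear
plateau rule.

For each candidate number of synergies N (1..10 by default) the cycles
are repeatedly split into an 80% training / 20% test set; spatial modules
are extracted from the training set and test activation coefficients
refit by nonnegative least squares, giving a test VAF per N.  The
selected N is the smallest one from which the remaining VAF curve is
linear: an ordinary least-squares line is fitted to the suffix [N, n_max]
of the curve (on the fractional 0-1 VAF scale) and N is accepted once the
fit's mean squared error drops below 1e-5.

For a large reference dataset the same split cycle is wrapped in a
bootstrap over random 20-cycle subsamples, yielding 95% percentile
confidence bands for the VAF at each N.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nmf
from .exceptions import ParameterError
from .preprocess import apply_normalization, normalize
from .types import CycleTensor

#: NMF settings used inside the (heavily repeated) selection loops; fewer
#: restarts and a looser tolerance than a one-off extraction, which the
#: averaging over repetitions compensates for.
CV_NMF_PARAMS = dict(n_restarts=2, max_iter=500, tol=1e-5)


@dataclass
class VafCurve:
    """VAF as a function of the candidate synergy number."""

    n_grid: np.ndarray
    vaf_mean: np.ndarray  # percent, per N
    vaf_reps: np.ndarray = None  # (n_reps, len(n_grid)) raw per-repetition VAF
    ci_low: np.ndarray = None  # 2.5th percentile, percent
    ci_high: np.ndarray = None  # 97.5th percentile, percent
    train_vaf_mean: np.ndarray = None
    mse_per_n: np.ndarray = None  # suffix line-fit MSE, fractional VAF scale
    n_selected: int = None
    plateau_found: bool = True
    warnings: list = field(default_factory=list)


def _split_vaf(
    train: CycleTensor,
    test: CycleTensor,
    n_max: int,
    seed,
    nmf_params: dict,
    stats_from: str,
    divisor: str,
):
    """Test (and train) VAF for N = 1..n_max on one train/test split."""
    if stats_from == "train":
        train_norm = normalize(train, divisor=divisor)
        M_train = train_norm.matrix
        M_test = apply_normalization(test, train_norm)
    elif stats_from == "pooled":
        # literal order: normalize everything together, then split columns
        both = CycleTensor(
            np.concatenate([train.data, test.data], axis=2),
            muscle_labels=train.muscle_labels,
        )
        M = normalize(both, divisor=divisor).matrix
        cut = train.n_cycles * train.data.shape[1]
        M_train, M_test = M[:, :cut], M[:, cut:]
    else:
        raise ParameterError("stats_from must be 'train' or 'pooled'")
    test_vaf = np.empty(n_max)
    train_vaf = np.empty(n_max)
    rng = np.random.default_rng(seed)
    for i, n_syn in enumerate(range(1, n_max + 1)):
        S = nmf.extract(M_train, n_syn, seed=rng.integers(2**31), **nmf_params)
        C_test = nmf.fit_coefficients(M_test, S.W)
        test_vaf[i] = nmf.vaf(M_test, S.W @ C_test)
        train_vaf[i] = S.vaf_pct
    return test_vaf, train_vaf


def cross_validate(
    cycles: CycleTensor,
    n_reps: int = 20,
    train_frac: float = 0.8,
    n_max: int = 10,
    seed=None,
    nmf_params: dict = None,
    stats_from: str = "train",
    divisor: str = "range",
) -> VafCurve:
    """Cross-validated VAF curve over candidate synergy numbers 1..n_max.

    Each repetition draws a random cycle-level split (80/20 by default,
    e.g. 16 train / 4 test cycles out of 20), extracts synergies on the
    normalized training cycles and scores the reconstruction of the test
    cycles.  Normalization statistics come from the training cycles only
    unless ``stats_from="pooled"``.
    """
    if cycles.n_cycles < 5:
        raise ParameterError("cross-validation needs at least 5 cycles")
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must lie strictly between 0 and 1")
    n_train = int(round(train_frac * cycles.n_cycles))
    if n_train < 1 or n_train >= cycles.n_cycles:
        raise ParameterError("split leaves an empty train or test set")
    nmf_params = dict(CV_NMF_PARAMS if nmf_params is None else nmf_params)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_reps, n_max))
    train_reps = np.empty((n_reps, n_max))
    for r in range(n_reps):
        perm = rng.permutation(cycles.n_cycles)
        reps[r], train_reps[r] = _split_vaf(
            cycles.subset(perm[:n_train]),
            cycles.subset(perm[n_train:]),
            n_max,
            rng.integers(2**31),
            nmf_params,
            stats_from,
            divisor,
        )
    return VafCurve(
        n_grid=np.arange(1, n_max + 1),
        vaf_mean=reps.mean(axis=0),
        vaf_reps=reps,
        train_vaf_mean=train_reps.mean(axis=0),
    )


def bootstrap_reference(
    cycles: CycleTensor,
    subsample: int = 20,
    n_boot: int = 1000,
    train_frac: float = 0.8,
    n_max: int = 10,
    seed=None,
    nmf_params: dict = None,
    stats_from: str = "train",
    divisor: str = "range",
) -> VafCurve:
    """Bootstrap VAF curve with 95% CI for a large reference dataset.

    Each bootstrap draws ``subsample`` cycles at random, runs a single
    train/test split cycle exactly as in :func:`cross_validate`, and
    records the test VAF per N; the confidence bounds are the 2.5th and
    97.5th percentiles (order statistics) over bootstraps.
    """
    if subsample > cycles.n_cycles:
        raise ParameterError("subsample exceeds the available cycles")
    n_train = int(round(train_frac * subsample))
    if n_train < 1 or n_train >= subsample:
        raise ParameterError("split leaves an empty train or test set")
    nmf_params = dict(CV_NMF_PARAMS if nmf_params is None else nmf_params)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, n_max))
    for b in range(n_boot):
        chosen = rng.choice(cycles.n_cycles, size=subsample, replace=False)
        perm = rng.permutation(subsample)
        sub = cycles.subset(chosen)
        reps[b], _ = _split_vaf(
            sub.subset(perm[:n_train]),
            sub.subset(perm[n_train:]),
            n_max,
            rng.integers(2**31),
            nmf_params,
            stats_from,
            divisor,
        )
    return VafCurve(
        n_grid=np.arange(1, n_max + 1),
        vaf_mean=reps.mean(axis=0),
        vaf_reps=reps,
        ci_low=np.percentile(reps, 2.5, axis=0),
        ci_high=np.percentile(reps, 97.5, axis=0),
    )


def within_ci(curve: VafCurve, reference: VafCurve) -> np.ndarray:
    """Per-N flags: does ``curve``'s mean VAF lie inside ``reference``'s CI?"""
    if reference.ci_low is None:
        raise ParameterError("reference curve carries no confidence interval")
    return (curve.vaf_mean >= reference.ci_low) & (curve.vaf_mean <= reference.ci_high)


def choose_n(
    curve: VafCurve, mse_threshold: float = 1e-5, scale: str = "fraction"
) -> VafCurve:
    """Select the synergy number where the VAF curve linearly plateaus.

    For each candidate N in ascending order a least-squares line is
    fitted to the VAF points from N to n_max inclusive; the smallest N
    whose fit MSE falls below ``mse_threshold`` is selected.  The MSE is
    computed on the fractional VAF scale (0-1) by default
    (``scale="percent"`` uses the raw percent values).  Candidates whose
    suffix holds fewer than three points are skipped (one or two points
    always fit a line exactly, making the residual test vacuous); if no
    candidate qualifies, n_max is returned with ``plateau_found=False``.
    """
    if len(curve.n_grid) < 3:
        raise ParameterError("plateau selection needs at least 3 candidate N values")
    vals = curve.vaf_mean / 100.0 if scale == "fraction" else curve.vaf_mean
    n_grid = curve.n_grid
    mse = np.full(len(n_grid), np.nan)
    selected, found = None, False
    for i in range(len(n_grid)):
        xs, ys = n_grid[i:], vals[i:]
        if len(xs) < 3:
            continue
        coef = np.polyfit(xs, ys, 1)
        resid = ys - np.polyval(coef, xs)
        mse[i] = float(np.mean(resid**2))
        if selected is None and mse[i] < mse_threshold:
            selected, found = int(n_grid[i]), True
    if selected is None:
        selected = int(n_grid[-1])
        curve.warnings.append(
            f"no plateau with suffix-fit MSE below {mse_threshold:g}; returning n_max"
        )
    curve.mse_per_n = mse
    curve.n_selected = selected
    curve.plateau_found = found
    return curve
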