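"""Non-negative matrix factorization primitives for synergy extraction.

The model is M ≈ W C with W, C ≥ 0: W holds one spatial module (muscle
weight vector) per column, C the matching temporal activation coefficients
per row.  Extraction uses Lee–Seung multiplicative updates for the squared
Frobenius objective, best of several seeded random restarts.  Weight
columns are reported as unit Euclidean vectors with the norms absorbed
into C, so spatial and temporal modules are comparable across fits.

Reconstruction quality is quantified as variance accounted for (VAF),
computed on uncentered data: VAF = 100 x (1 - SSE / sum(M^2)).  The
literal uncentered-correlation reading is available via ``method="corr"``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .exceptions import ParameterError

_EPS = 1e-12


@dataclass
class SynergySet:
    """A fitted synergy decomposition.

    Attributes
    ----------
    W : ndarray, shape (n_muscles, N)
        Spatial modules; columns are unit Euclidean vectors.
    C : ndarray, shape (N, T)
        Temporal activation coefficients.
    vaf_pct : float
        Reconstruction VAF on the fitted matrix, percent.
    residual : float
        Frobenius norm of M - W C on the fitted matrix.
    """

    W: np.ndarray
    C: np.ndarray
    vaf_pct: float = np.nan
    residual: float = np.nan

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.W.ndim != 2 or self.C.ndim != 2 or self.W.shape[1] != self.C.shape[0]:
            raise ParameterError("W (m x N) and C (N x T) have incompatible shapes")

    @property
    def N(self) -> int:
        return self.W.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.C


def vaf(M, M_hat, method: str = "sse") -> float:
    """Variance accounted for, in percent.

    ``method="sse"`` (default): 100 * (1 - sum((M-M_hat)^2) / sum(M^2)),
    the uncentered coefficient-of-determination convention used throughout
    this package.  ``method="corr"``: 100 times the uncentered Pearson
    correlation between the flattened matrices.
    """
    M = np.asarray(M, dtype=float)
    M_hat = np.asarray(M_hat, dtype=float)
    if M.shape != M_hat.shape:
        raise ParameterError("M and M_hat must have equal shapes")
    ss_m = float(np.sum(M * M))
    if ss_m <= 0:
        raise ParameterError("VAF undefined for an all-zero reference matrix")
    if method == "sse":
        sse = float(np.sum((M - M_hat) ** 2))
        return 100.0 * (1.0 - sse / ss_m)
    if method == "corr":
        ss_h = float(np.sum(M_hat * M_hat))
        if ss_h == 0.0:
            return 0.0
        return 100.0 * float(np.sum(M * M_hat)) / np.sqrt(ss_m * ss_h)
    raise ParameterError(f"unknown VAF method {method!r}")


def _normalize_columns(W: np.ndarray, C: np.ndarray):
    """Move column norms of W into the rows of C (unit-vector convention)."""
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return W / safe, C * norms[:, None]


def _mu_iterate(M, W, C, max_iter, tol, rng, check_every=5):
    """Run multiplicative updates in place; returns (W, C, sq_err).

    Entries of C that start at exactly zero stay zero, which is what the
    shared/specific decomposition relies on for its structural-zero blocks.
    A weight column that collapses to zero is re-seeded from the rng
    (degenerate-synergy guard) unless the factorization already converged.
    """
    norm_m = float(np.sum(M * M))
    prev = None
    err = np.inf
    for it in range(max_iter):
        C *= (W.T @ M) / (W.T @ W @ C + _EPS)
        W *= (M @ C.T) / (W @ (C @ C.T) + _EPS)
        if (it + 1) % check_every == 0 or it == max_iter - 1:
            err = float(np.sum((M - W @ C) ** 2))
            if prev is not None and abs(prev - err) <= tol * norm_m:
                dead = np.linalg.norm(W, axis=0) < 1e-10
                if dead.any():
                    W[:, dead] = rng.random((M.shape[0], int(dead.sum()))) + _EPS
                    prev = None
                    continue
                break
            prev = err
    return W, C, err


def extract(
    M,
    N: int,
    seed=None,
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    c_support=None,
    vaf_method: str = "sse",
    init=None,
) -> SynergySet:
    """Extract N synergies from a nonnegative matrix M (muscles x time).

    Best of ``n_restarts`` random nonnegative initializations, each run to
    convergence (relative squared-error change below ``tol``, scaled by
    ||M||_F^2) or ``max_iter`` iterations.

    Parameters
    ----------
    c_support : ndarray of bool, shape (N, T), optional
        Mask of C entries allowed to be nonzero.  Entries outside the
        support are initialized to zero and remain exactly zero under the
        multiplicative updates (used by the shared/specific model).
    init : (W0, C0), optional
        Explicit nonnegative starting point used for the first restart
        (e.g. a warm start from a previously fitted model); the remaining
        restarts stay random.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ParameterError("M must be a 2-D matrix")
    if np.any(M < 0):
        raise ParameterError("M must be nonnegative")
    m, T = M.shape
    # a plain factorization is capped at one synergy per muscle; a structured
    # (masked-support) one may exceed it since no single column block sees all
    n_cap = m if c_support is None else 2 * m
    if not 1 <= N <= n_cap:
        raise ParameterError(f"N must be in [1, {n_cap}], got {N}")
    if c_support is not None:
        c_support = np.asarray(c_support, dtype=bool)
        if c_support.shape != (N, T):
            raise ParameterError("c_support must have shape (N, T)")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(M.mean(), _EPS) / N)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0 and init is not None:
            W0 = np.asarray(init[0], dtype=float).copy() + _EPS
            C0 = np.asarray(init[1], dtype=float).copy() + _EPS
            if W0.shape != (m, N) or C0.shape != (N, T):
                raise ParameterError("init factors have wrong shapes")
        else:
            W0 = scale * rng.random((m, N)) + _EPS
            C0 = scale * rng.random((N, T)) + _EPS
        if c_support is not None:
            C0 = np.where(c_support, C0, 0.0)
        W, C, err = _mu_iterate(M, W0, C0, max_iter, tol, rng)
        if best is None or err < best[2]:
            best = (W, C, err)
    W, C, err = best
    W, C = _normalize_columns(W, C)
    return SynergySet(
        W, C, vaf_pct=vaf(M, W @ C, method=vaf_method), residual=float(np.sqrt(err))
    )


def fit_coefficients(M, W_fixed) -> np.ndarray:
    """Fit activation coefficients for a fixed spatial-module matrix.

    Each column of C solves the nonnegative least-squares problem
    min ||m - W c||_2, c >= 0 for the matching column m of M; the optimum
    is exact and deterministic (no multiplicative updates involved).
    """
    M = np.asarray(M, dtype=float)
    W = np.asarray(W_fixed, dtype=float)
    if M.ndim != 2 or W.ndim != 2 or M.shape[0] != W.shape[0]:
        raise ParameterError("M (m x T) and W (m x N) have incompatible shapes")
    if np.any(W < 0):
        raise ParameterError("W must be nonnegative")
    if np.any(np.linalg.norm(W, axis=0) == 0):
        raise ParameterError("W contains an all-zero column")
    C = np.empty((W.shape[1], M.shape[1]))
    for j in range(M.shape[1]):
        C[:, j], _ = _scipy_nnls(W, M[:, j])
    return C


def rescale_weights(S: SynergySet, sigma) -> SynergySet:
    """Revert a per-muscle unit-variance scaling on the spatial modules.

    Multiplies row i of W by sigma_i, then re-normalizes columns to unit
    vectors with the norms absorbed into C, so W C is preserved up to the
    per-row sigma rescaling.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (S.W.shape[0],):
        raise ParameterError("sigma must have one entry per muscle")
    if np.any(sigma <= 0):
        raise ParameterError("sigma must be strictly positive")
    W, C = _normalize_columns(S.W * sigma[:, None], S.C.copy())
    return SynergySet(W, C, vaf_pct=S.vaf_pct, residual=S.residual)
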