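"""Shared vs condition-specific synergy decomposition on pooled data.

The two conditions' cycles are pooled into one normalized matrix and
factorized with a structured NMF: shared synergies may be active on any
column, while each condition-specific synergy's activation coefficients
are structurally zero on the other condition's columns.  The
multiplicative updates preserve exact zeros, so the structural blocks
stay zero through any number of iterations.

The split (n_shared, n_specific_A, n_specific_B) is selected by starting
from the no-sharing solution (total = N_A + N_B) and reducing the total
one synergy at a time, accepting a candidate while each condition's VAF
still meets its per-condition reference; among candidates at a total the
one with the most sharing is preferred.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nmf
from .exceptions import ParameterError
from .preprocess import normalize
from .types import CONDITION_A, CONDITION_B, CycleTensor, NormalizedEmgMatrix


@dataclass
class PooledData:
    """Pooled, jointly normalized two-condition matrix with a column mask."""

    matrix: np.ndarray  # (n_muscles, T_A + T_B)
    is_b: np.ndarray  # bool per column: True on condition-B columns
    stats: NormalizedEmgMatrix
    muscle_labels: tuple

    @property
    def block_a(self) -> np.ndarray:
        return self.matrix[:, ~self.is_b]

    @property
    def block_b(self) -> np.ndarray:
        return self.matrix[:, self.is_b]


def pool(cycles_a: CycleTensor, cycles_b: CycleTensor, divisor: str = "range") -> PooledData:
    """Concatenate two conditions column-wise and normalize the pooled data.

    Normalization statistics (per-muscle min/max and sigma) are computed
    on the pooled matrix: a single per-muscle scaling for both conditions,
    so a synergy common to both conditions has one spatial direction in
    the pooled space.  Per-condition reference fits for the shared /
    specific selection must be computed in this same space (see
    :func:`condition_references`) to be comparable.
    """
    if tuple(cycles_a.muscle_labels) != tuple(cycles_b.muscle_labels):
        raise ParameterError("muscle labels differ between the pooled conditions")
    n_t = cycles_a.data.shape[1]
    pooled = CycleTensor(
        np.concatenate([cycles_a.data, cycles_b.data], axis=2),
        muscle_labels=cycles_a.muscle_labels,
    )
    stats = normalize(pooled, divisor=divisor)
    is_b = np.zeros(stats.matrix.shape[1], dtype=bool)
    is_b[cycles_a.n_cycles * n_t :] = True
    return PooledData(stats.matrix, is_b, stats, cycles_a.muscle_labels)


#: NMF settings for the one-off per-condition reference extractions; these
#: anchor the shared/specific acceptance rule, so they get a deeper search
#: than the many candidate fits.
REFERENCE_NMF_PARAMS = dict(n_restarts=10, max_iter=1000, tol=1e-6)


def condition_references(
    cycles_a: CycleTensor,
    cycles_b: CycleTensor,
    pooled: PooledData,
    n_a: int,
    n_b: int,
    seed=None,
    nmf_params: dict = None,
    divisor: str = "range",
):
    """Per-condition reference models, expressed in the pooled space.

    Each condition is fitted in its own normalized space (the same
    procedure its separate analysis uses), then mapped into the pooled
    space: both normalizations are per-muscle affine maps of the same raw
    data, so scaling each weight row by the ratio of the two per-muscle
    scale factors transports the model exactly.  The returned sets carry
    the reference VAFs for :func:`select_split` — evaluated on the pooled
    condition blocks, where they are feasible points of the no-sharing
    model — and seed its warm starts.  Returns (S_a, S_b).
    """
    nmf_params = dict(REFERENCE_NMF_PARAMS if nmf_params is None else nmf_params)
    rng = np.random.default_rng(seed)
    denom_p = (
        (pooled.stats.vmax - pooled.stats.vmin)
        if pooled.stats.divisor == "range"
        else pooled.stats.vmax
    )
    out = []
    for cycles, n_syn, block in (
        (cycles_a, n_a, pooled.block_a),
        (cycles_b, n_b, pooled.block_b),
    ):
        stats = normalize(cycles, divisor=divisor)
        S = nmf.extract(stats.matrix, n_syn, seed=rng.integers(2**31), **nmf_params)
        denom_c = (
            (stats.vmax - stats.vmin) if stats.divisor == "range" else stats.vmax
        )
        scale = (stats.sigma * denom_c) / (pooled.stats.sigma * denom_p)
        W_p = S.W * scale[:, None]
        norms = np.linalg.norm(W_p, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        W_p, C_p = W_p / safe, S.C * norms[:, None]
        vaf_block = nmf.vaf(block, W_p @ C_p)
        out.append(nmf.SynergySet(W_p, C_p, vaf_pct=vaf_block))
    return tuple(out)


@dataclass
class SharedSpecificModel:
    """Structured factorization of the pooled matrix."""

    n_sh: int
    n_a: int
    n_b: int
    W_shared: np.ndarray
    W_spec_a: np.ndarray
    W_spec_b: np.ndarray
    C: np.ndarray  # full (n_sh+n_a+n_b, T) coefficients, structural zeros intact
    is_b: np.ndarray
    vaf_pooled: float
    vaf_a: float
    vaf_b: float
    warnings: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_sh + self.n_a + self.n_b

    @property
    def W(self) -> np.ndarray:
        return np.concatenate([self.W_shared, self.W_spec_a, self.W_spec_b], axis=1)


#: NMF settings for the pooled structured fits; the selection loop fits
#: many candidate partitions, so these favor throughput over the last
#: decimal of the objective.
SPLIT_NMF_PARAMS = dict(n_restarts=3, max_iter=500, tol=1e-5)


def extract_split(
    pooled: PooledData,
    n_sh: int,
    n_a: int,
    n_b: int,
    seed=None,
    nmf_params: dict = None,
    init=None,
) -> SharedSpecificModel:
    """Fit the structured NMF with a fixed (shared, specific-A, specific-B)
    partition.  Rows of C are ordered shared first, then condition-A
    specific, then condition-B specific."""
    if min(n_sh, n_a, n_b) < 0:
        raise ParameterError("synergy counts must be nonnegative")
    if n_sh + n_a < 1 or n_sh + n_b < 1:
        raise ParameterError("each condition needs at least one available synergy")
    nmf_params = dict(SPLIT_NMF_PARAMS if nmf_params is None else nmf_params)
    N = n_sh + n_a + n_b
    T = pooled.matrix.shape[1]
    support = np.ones((N, T), dtype=bool)
    support[n_sh : n_sh + n_a, pooled.is_b] = False
    support[n_sh + n_a :, ~pooled.is_b] = False
    S = nmf.extract(
        pooled.matrix, N, seed=seed, c_support=support, init=init, **nmf_params
    )
    recon = S.W @ S.C
    cols_a, cols_b = ~pooled.is_b, pooled.is_b
    return SharedSpecificModel(
        n_sh=n_sh,
        n_a=n_a,
        n_b=n_b,
        W_shared=S.W[:, :n_sh],
        W_spec_a=S.W[:, n_sh : n_sh + n_a],
        W_spec_b=S.W[:, n_sh + n_a :],
        C=S.C,
        is_b=pooled.is_b,
        vaf_pooled=S.vaf_pct,
        vaf_a=nmf.vaf(pooled.matrix[:, cols_a], recon[:, cols_a]),
        vaf_b=nmf.vaf(pooled.matrix[:, cols_b], recon[:, cols_b]),
    )


def _warm_init(pooled: PooledData, S_a, S_b, n_sh: int, n_a: int, n_b: int, rng):
    """Build a structured starting point from per-condition reference fits.

    The two reference module sets are matched by cosine similarity; the
    ``n_sh`` most similar pairs seed the shared modules (normalized mean
    weights, each condition's own activation rows), the least-shared
    leftovers seed the specific blocks, and any remaining columns are
    random.  Starting every candidate partition this close to a good
    solution makes the partition comparison reflect model capacity rather
    than optimizer luck.
    """
    from scipy.optimize import linear_sum_assignment

    W_a, C_a = S_a.W, S_a.C
    W_b, C_b = S_b.W, S_b.C
    sim = W_a.T @ W_b / np.outer(
        np.linalg.norm(W_a, axis=0), np.linalg.norm(W_b, axis=0)
    )
    rows, cols = linear_sum_assignment(-sim)
    order = np.argsort(-sim[rows, cols])  # most similar pairs first
    pairs = [(rows[i], cols[i]) for i in order]

    m, T = pooled.matrix.shape
    cols_a, cols_b = ~pooled.is_b, pooled.is_b
    scale = np.sqrt(max(pooled.matrix.mean(), 1e-12))
    W0 = np.empty((m, 0))
    C0 = np.empty((0, T))

    def rand_col():
        return scale * rng.random((m, 1)), scale * rng.random((1, T))

    shared_pairs = pairs[:n_sh]
    for i in range(n_sh):
        if i < len(shared_pairs):
            ia, ib = shared_pairs[i]
            w = W_a[:, ia] + W_b[:, ib]
            w = w / np.linalg.norm(w)
            c = np.empty(T)
            c[cols_a], c[cols_b] = C_a[ia], C_b[ib]
        else:
            (w, c) = rand_col()
            w, c = w.ravel(), c.ravel()
        W0 = np.column_stack([W0, w])
        C0 = np.vstack([C0, c])

    # least-shared modules first for the specific blocks
    spare_a = [ia for ia, _ in reversed(pairs[n_sh:])] + [
        i for i in range(S_a.N) if i not in {p[0] for p in pairs}
    ]
    spare_b = [ib for _, ib in reversed(pairs[n_sh:])] + [
        i for i in range(S_b.N) if i not in {p[1] for p in pairs}
    ]
    for count, spare, W_ref, C_ref, mask in (
        (n_a, spare_a, W_a, C_a, cols_a),
        (n_b, spare_b, W_b, C_b, cols_b),
    ):
        for i in range(count):
            if i < len(spare):
                w = W_ref[:, spare[i]]
                c = np.zeros(T)
                c[mask] = C_ref[spare[i]]
            else:
                w, c = rand_col()
                w, c = w.ravel(), c.ravel()
            W0 = np.column_stack([W0, w])
            C0 = np.vstack([C0, c])
    return W0, C0


def _candidate_partitions(total: int, n_a_ref: int, n_b_ref: int):
    """Partitions (n_sh, n_a, n_b) of ``total``, most-shared first.

    Constrains n_sh + n_a <= N_A and n_sh + n_b <= N_B (no condition gets
    more synergies than its own analysis needed); if no partition
    satisfies the constraints at this total they are relaxed.
    """
    all_parts = [
        (s, a, total - s - a)
        for s in range(total, -1, -1)
        for a in range(total - s + 1)
        if s + a >= 1 and s + (total - s - a) >= 1
    ]
    constrained = [
        p for p in all_parts if p[0] + p[1] <= n_a_ref and p[0] + p[2] <= n_b_ref
    ]
    parts = constrained if constrained else all_parts
    # most sharing first; among equals prefer balanced specific counts
    return sorted(parts, key=lambda p: (-p[0], abs(p[1] - p[2]), -p[1]))


def select_split(
    pooled: PooledData,
    n_a_ref: int,
    n_b_ref: int,
    vaf_ref_a: float,
    vaf_ref_b: float,
    seed=None,
    nmf_params: dict = None,
    ref_sets=None,
    slack_pct: float = 0.1,
) -> SharedSpecificModel:
    """Select the shared/specific split against per-condition reference VAFs.

    Starting from the no-sharing total N_A + N_B, the total synergy count
    is reduced one at a time.  At each total, candidate partitions are
    fitted most-shared-first and the first one whose condition-wise VAFs
    both meet the references (minus ``slack_pct`` percentage points of
    optimizer tolerance) is accepted; the search stops at the first total
    where no candidate is acceptable, returning the accepted model with
    the minimal total (maximal sharing as tie-break).  If even the
    initial total fails, the all-specific model is returned with a
    warning flag.

    Parameters
    ----------
    ref_sets : (SynergySet, SynergySet), optional
        The per-condition reference fits (in each condition's normalized
        space).  When given, every candidate partition is warm-started
        from them, which removes most restart-to-restart noise from the
        partition comparison.
    """
    if n_a_ref < 1 or n_b_ref < 1:
        raise ParameterError("per-condition synergy counts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    fallback = None
    for total in range(n_a_ref + n_b_ref, 0, -1):
        accepted = None
        for n_sh, n_a, n_b in _candidate_partitions(total, n_a_ref, n_b_ref):
            init = (
                _warm_init(pooled, ref_sets[0], ref_sets[1], n_sh, n_a, n_b, rng)
                if ref_sets is not None
                else None
            )
            model = extract_split(
                pooled, n_sh, n_a, n_b, seed=rng.integers(2**31),
                nmf_params=nmf_params, init=init,
            )
            if fallback is None:
                fallback = model
            if model.vaf_a >= vaf_ref_a - slack_pct and model.vaf_b >= vaf_ref_b - slack_pct:
                accepted = model
                break
        if accepted is None:
            break
        best = accepted
    if best is None:
        best = fallback
        best.warnings.append(
            "no partition met both reference VAFs; returning the all-specific model"
        )
    return best
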