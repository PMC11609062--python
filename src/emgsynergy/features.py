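"""Summary features of fitted synergies: temporal-profile peaks, peak-time
ordering, and cosine matching of spatial modules across conditions."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import ParameterError
from .nmf import SynergySet
from .types import N_POINTS, TIME_AXIS_MS


def temporal_profile(C: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Cycle-averaged activation profiles.

    ``C`` (N x T) must hold consecutive ``n_points``-sample cycles along
    its columns; rows are reshaped to (cycles x n_points) and averaged
    across cycles, returning an (N x n_points) array.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] % n_points:
        raise ParameterError(
            f"column count {C.shape[1]} is not a multiple of {n_points}"
        )
    n_cycles = C.shape[1] // n_points
    return C.reshape(C.shape[0], n_cycles, n_points).mean(axis=1)


@dataclass
class PeakFeatures:
    """Peak of one temporal module: time (ms relative to the event,
    negative = before the metronome sound) and amplitude (a.u.)."""

    peak_time_ms: float
    peak_amplitude: float
    defined: bool = True


def peak_features(profile: np.ndarray) -> PeakFeatures:
    """Argmax peak of a 151-point profile; ties break toward earlier time.

    An all-zero profile has no meaningful peak and is flagged undefined.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    if profile.size != N_POINTS:
        raise ParameterError(f"profile must have {N_POINTS} points")
    if not profile.any():
        return PeakFeatures(np.nan, 0.0, defined=False)
    idx = int(np.argmax(profile))  # argmax returns the first (earliest) maximum
    return PeakFeatures(float(TIME_AXIS_MS[idx]), float(profile[idx]))


def sort_by_peak(profiles: np.ndarray) -> np.ndarray:
    """Synergy order sorted by peak time (stable; ties keep synergy index)."""
    times = [peak_features(p).peak_time_ms for p in profiles]
    times = [np.inf if np.isnan(t) else t for t in times]
    return np.argsort(times, kind="stable")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """r = (a.b) / (|a||b|); invariant to positive rescaling."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ParameterError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def match_and_similarity(W_A: np.ndarray, W_B: np.ndarray):
    """Optimal one-to-one pairing of spatial modules across two sets.

    Solves the assignment problem maximizing total cosine similarity;
    returns (pairs, r) where ``pairs[i] = (col_in_A, col_in_B)`` and
    ``r[i]`` is the pair's cosine similarity.
    """
    W_A = np.asarray(W_A, dtype=float)
    W_B = np.asarray(W_B, dtype=float)
    if W_A.shape != W_B.shape:
        raise ParameterError("synergy sets must have equal shapes to be matched")
    k = W_A.shape[1]
    sim = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = cosine_similarity(W_A[:, i], W_B[:, j])
    rows, cols = linear_sum_assignment(-sim)
    return list(zip(rows.tolist(), cols.tolist())), sim[rows, cols]


def feature_table(S: SynergySet, condition: str):
    """Per-synergy feature rows: (condition, synergy, peak time, amplitude).

    Returned as a list of dicts ready for a DataFrame / CSV writer.
    """
    profiles = temporal_profile(S.C)
    rows = []
    for i, prof in enumerate(profiles):
        pk = peak_features(prof)
        rows.append(
            dict(
                condition=condition,
                synergy=i,
                peak_time_ms=pk.peak_time_ms,
                peak_amplitude=pk.peak_amplitude,
                defined=pk.defined,
            )
        )
    return rows
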