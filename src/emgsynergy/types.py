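"""Core data containers shared by every stage of the analysis.

The containers are deliberately thin: plain dataclasses wrapping numpy
arrays, with validation at construction so downstream code can assume the
documented invariants (nonnegativity, fixed 151-point time axis, unit-norm
weight columns, ...).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

#: Canonical muscle order (right lower limb, proximal to distal):
#: rectus femoris, vastus lateralis, vastus medialis, biceps femoris,
#: tibialis anterior, extensor digitorum longus, soleus, gastrocnemius,
#: peroneus longus, extensor digitorum brevis.  Readers map by label, never
#: by file-column position.
MUSCLES = ("RF", "VL", "VM", "BF", "TA", "EDL", "SOL", "GAS", "PL", "EDB")

#: Number of resampled time points per event-locked cycle.
N_POINTS = 151

#: Event-locked window half-width in seconds (one beat at 80 bpm).
HALF_WINDOW_S = 0.75

#: Time axis of a resampled cycle in milliseconds relative to the event
#: (151 points, 10 ms spacing, symmetric about 0).
TIME_AXIS_MS = np.linspace(-HALF_WINDOW_S * 1000, HALF_WINDOW_S * 1000, N_POINTS)

#: Condition labels used throughout: A = without dystonia symptoms,
#: B = with dystonia symptoms.
CONDITION_A = "without_dystonia"
CONDITION_B = "with_dystonia"


@dataclass
class EmgRecording:
    """Continuous multi-muscle EMG signal.

    Attributes
    ----------
    signals : ndarray, shape (n_muscles, n_samples)
        Raw or filtered signal per muscle, arbitrary units.
    fs_hz : float
        Sampling rate in Hz.
    muscle_labels : tuple of str
        Ordered channel labels; defaults to the canonical 10-muscle order.
    """

    signals: np.ndarray
    fs_hz: float = 1111.0
    muscle_labels: tuple = MUSCLES

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ParameterError("signals must be a 2-D (muscles x samples) array")
        if self.signals.shape[0] != len(self.muscle_labels):
            raise ParameterError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.muscle_labels)} muscle labels"
            )
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be positive")

    @property
    def n_muscles(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class EventTimes:
    """Strictly increasing event (reference) times in seconds."""

    times_s: np.ndarray

    def __post_init__(self):
        self.times_s = np.atleast_1d(np.asarray(self.times_s, dtype=float))
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ParameterError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class CycleTensor:
    """Event-locked, resampled EMG cycles.

    Attributes
    ----------
    data : ndarray, shape (n_muscles, 151, n_cycles)
        Nonnegative resampled cycles.
    condition : ndarray of str, shape (n_cycles,)
        Per-cycle condition label.
    muscle_labels : tuple of str
    time_axis_ms : ndarray, shape (151,)
    """

    data: np.ndarray
    condition: np.ndarray = None
    muscle_labels: tuple = MUSCLES
    time_axis_ms: np.ndarray = field(default_factory=lambda: TIME_AXIS_MS.copy())

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("cycle data must be 3-D (muscles x time x cycles)")
        if self.data.shape[1] != N_POINTS:
            raise ParameterError(f"cycles must have exactly {N_POINTS} time points")
        if np.any(self.data < 0):
            raise ParameterError("cycle data must be nonnegative")
        if self.condition is None:
            self.condition = np.array([""] * self.n_cycles, dtype=object)
        else:
            self.condition = np.asarray(self.condition, dtype=object)
            if self.condition.shape != (self.n_cycles,):
                raise ParameterError("condition labels must be one per cycle")

    @property
    def n_muscles(self) -> int:
        return self.data.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.data.shape[2]

    def flatten(self) -> np.ndarray:
        """Return the (n_muscles, 151 * n_cycles) matrix with cycles laid out
        consecutively along time (cycle 0's 151 points, then cycle 1's, ...)."""
        return self.data.transpose(0, 2, 1).reshape(self.n_muscles, -1)

    def subset(self, idx) -> "CycleTensor":
        idx = np.asarray(idx)
        return CycleTensor(
            self.data[:, :, idx],
            condition=self.condition[idx],
            muscle_labels=self.muscle_labels,
            time_axis_ms=self.time_axis_ms,
        )


@dataclass
class NormalizedEmgMatrix:
    """Per-muscle range-normalized, unit-variance EMG matrix.

    Holds the statistics needed to undo the scaling: per-muscle (min, max)
    of the range step and the standard deviation sigma of the
    range-normalized vector used for unit-variance scaling.
    """

    matrix: np.ndarray
    sigma: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    divisor: str = "range"
    muscle_labels: tuple = MUSCLES

    @property
    def n_muscles(self) -> int:
        return self.matrix.shape[0]
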