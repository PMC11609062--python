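"""Raw EMG + click signal -> normalized cycle matrix.

Stages: metronome peak detection on the click envelope, per-channel
demeaning / full-wave rectification / zero-phase 4th-order Butterworth
low-pass at 20 Hz, event-locked ±0.75 s epoching resampled to 151 points,
and per-muscle range + unit-variance normalization.  Cycle bookkeeping
(symptom / artifact tallies per trial) lives here as well.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import (
    EpochingError,
    EventDetectionError,
    NormalizationError,
    ParameterError,
)
from .types import (
    HALF_WINDOW_S,
    N_POINTS,
    CycleTensor,
    EmgRecording,
    EventTimes,
    NormalizedEmgMatrix,
)


def lowpass(x: np.ndarray, fs_hz: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis."""
    if cutoff_hz <= 0 or cutoff_hz >= fs_hz / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs_hz / 2} Hz)"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def detect_events(
    click_signal: np.ndarray,
    fs_hz: float,
    nominal_period_s: float = 0.75,
    envelope_cutoff_hz: float = 30.0,
    min_height_frac: float = 0.3,
) -> EventTimes:
    """Detect metronome reference timings from a click/metronome channel.

    The signal is rectified, its envelope taken as the zero-phase low-pass
    of the rectified signal, and local maxima picked with a minimum
    inter-peak distance of half the nominal beat period.  Peaks below
    ``min_height_frac`` of the envelope maximum are ignored.
    """
    x = np.asarray(click_signal, dtype=float).ravel()
    if x.size == 0:
        raise ParameterError("click signal is empty")
    env = lowpass(np.abs(x), fs_hz, envelope_cutoff_hz)
    if env.max() <= 0:
        raise EventDetectionError("no events found: click envelope is identically zero")
    distance = max(1, int(round(0.5 * nominal_period_s * fs_hz)))
    peaks, _ = sps.find_peaks(env, distance=distance, height=min_height_frac * env.max())
    if peaks.size == 0:
        raise EventDetectionError("no events found in click signal")
    return EventTimes(peaks / fs_hz)


def select_downbeats(events: EventTimes, every: int = 4, offset: int = 0) -> EventTimes:
    """Keep every ``every``-th detected click starting at ``offset``.

    With a metronome clicking each beat but one analyzed pedal strike per
    bar, the epoching events are the bar downbeats, i.e. every 4th click.
    """
    if every < 1:
        raise ParameterError("every must be >= 1")
    return EventTimes(events.times_s[offset::every])


def filter_emg(rec: EmgRecording, cutoff_hz: float = 20.0, order: int = 4) -> EmgRecording:
    """Demean, full-wave rectify, and low-pass filter each channel.

    Filtering is zero-phase (forward-backward), chosen to preserve the
    activation peak timings the feature stage reports; the effective
    attenuation order is therefore doubled.  The output may contain small
    negative values from filter ringing; epoching clips them at zero.
    """
    if rec.fs_hz <= 2 * cutoff_hz:
        raise ParameterError("sampling rate must exceed twice the cutoff")
    x = rec.signals - rec.signals.mean(axis=1, keepdims=True)
    filtered = lowpass(np.abs(x), rec.fs_hz, cutoff_hz, order=order)
    return EmgRecording(filtered, fs_hz=rec.fs_hz, muscle_labels=rec.muscle_labels)


@dataclass
class EpochResult:
    cycles: CycleTensor
    n_dropped: int  # events too close to a recording edge


def epoch_cycles(
    rec: EmgRecording,
    events: EventTimes,
    half_window_s: float = HALF_WINDOW_S,
    n_points: int = N_POINTS,
    condition_labels=None,
) -> EpochResult:
    """Extract ±``half_window_s`` windows around each event, resampled to
    ``n_points`` by linear interpolation; negatives are clipped to zero.

    Events without a full window on both sides are dropped (counted in
    ``n_dropped``); per-event condition labels, if given, are carried
    through for the surviving events.
    """
    t_samples = np.arange(rec.n_samples) / rec.fs_hz
    grid_rel = np.linspace(-half_window_s, half_window_s, n_points)
    kept, labels = [], []
    n_dropped = 0
    for i, ev in enumerate(events.times_s):
        if ev - half_window_s < 0 or ev + half_window_s > t_samples[-1]:
            n_dropped += 1
            continue
        grid = ev + grid_rel
        cycle = np.empty((rec.n_muscles, n_points))
        for m in range(rec.n_muscles):
            cycle[m] = np.interp(grid, t_samples, rec.signals[m])
        kept.append(np.clip(cycle, 0.0, None))
        if condition_labels is not None:
            labels.append(condition_labels[i])
    if not kept:
        raise EpochingError("no event has a full epoch window inside the recording")
    data = np.stack(kept, axis=2)
    condition = np.asarray(labels, dtype=object) if condition_labels is not None else None
    return EpochResult(
        CycleTensor(data, condition=condition, muscle_labels=rec.muscle_labels),
        n_dropped,
    )


def normalize(
    cycles: CycleTensor, divisor: str = "range", sigma_on: str = "normalized"
) -> NormalizedEmgMatrix:
    """Per-muscle range normalization followed by unit-variance scaling.

    Cycles are flattened along time (muscles x 151*n_cycles).  Each muscle
    row has its minimum subtracted and is divided by (max - min)
    (``divisor="range"``, so rows span [0, 1]) or by the original maximum
    (``divisor="max"``, the literal alternative).  Each row is then
    divided by its standard deviation sigma — computed on the
    range-normalized row by default (``sigma_on="raw"`` uses the raw row)
    — so every non-constant row has unit sample variance.  The (min, max)
    and sigma are stored for later unscaling.
    """
    if divisor not in ("range", "max"):
        raise ParameterError("divisor must be 'range' or 'max'")
    X = cycles.flatten()
    vmin = X.min(axis=1)
    vmax = X.max(axis=1)
    flat = vmax - vmin <= 0
    if flat.any():
        bad = [cycles.muscle_labels[i] for i in np.flatnonzero(flat)]
        raise NormalizationError(f"constant muscle channel(s): {', '.join(bad)}")
    denom = (vmax - vmin) if divisor == "range" else vmax
    if np.any(denom <= 0):
        bad = [cycles.muscle_labels[i] for i in np.flatnonzero(denom <= 0)]
        raise NormalizationError(f"nonpositive normalization divisor for: {', '.join(bad)}")
    ranged = (X - vmin[:, None]) / denom[:, None]
    sigma = (ranged if sigma_on == "normalized" else X).std(axis=1)
    if np.any(sigma <= 0):
        bad = [cycles.muscle_labels[i] for i in np.flatnonzero(sigma <= 0)]
        raise NormalizationError(f"zero-variance muscle channel(s): {', '.join(bad)}")
    return NormalizedEmgMatrix(
        matrix=np.clip(ranged / sigma[:, None], 0.0, None),
        sigma=sigma,
        vmin=vmin,
        vmax=vmax,
        divisor=divisor,
        muscle_labels=cycles.muscle_labels,
    )


def apply_normalization(cycles: CycleTensor, stats: NormalizedEmgMatrix) -> np.ndarray:
    """Normalize a cycle tensor with statistics from another dataset.

    Used for cross-validation test folds so the test data is scaled with
    training statistics only.  Negative values after min subtraction are
    clipped to zero to keep the matrix factorizable.
    """
    X = cycles.flatten()
    denom = (
        (stats.vmax - stats.vmin) if stats.divisor == "range" else stats.vmax
    )
    ranged = (X - stats.vmin[:, None]) / denom[:, None]
    return np.clip(ranged / stats.sigma[:, None], 0.0, None)


def denormalize(norm: NormalizedEmgMatrix) -> np.ndarray:
    """Invert :func:`normalize` using the stored statistics."""
    denom = (norm.vmax - norm.vmin) if norm.divisor == "range" else norm.vmax
    return norm.matrix * norm.sigma[:, None] * denom[:, None] + norm.vmin[:, None]


@dataclass
class TrialAnnotation:
    """Manual bookkeeping for one trial: which analyzed cycles carried
    symptoms and which are excluded as movement artifacts."""

    n_cycles: int
    symptom_cycles: list = field(default_factory=list)
    artifact_cycles: list = field(default_factory=list)

    def __post_init__(self):
        for idx in list(self.symptom_cycles) + list(self.artifact_cycles):
            if not 0 <= idx < self.n_cycles:
                raise ParameterError(f"cycle index {idx} outside trial of {self.n_cycles}")


def tally_cycles(trials) -> tuple:
    """Count analyzable cycles per condition across trials.

    Returns (n_with_symptoms, n_without).  Artifact-flagged cycles are
    excluded entirely; a cycle flagged both symptomatic and artifactual is
    excluded (artifact wins) and counted once.
    """
    n_with = n_without = 0
    for trial in trials:
        artifacts = set(trial.artifact_cycles)
        symptoms = set(trial.symptom_cycles)
        for c in range(trial.n_cycles):
            if c in artifacts:
                continue
            if c in symptoms:
                n_with += 1
            else:
                n_without += 1
    return n_with, n_without
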