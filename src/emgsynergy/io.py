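"""Readers and writers for every artifact the pipeline touches.

All on-disk formats are plain text: delimited numeric matrices for
signals and cycles (with JSON sidecars for metadata), CSV for factor
matrices and curves, JSON for summaries and the run manifest.  Floats are
written with 17 significant digits so write -> read round-trips are
lossless at double precision.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusteredSynergies
from .exceptions import FormatError
from .nmf import SynergySet
from .selection import VafCurve
from .shared import SharedSpecificModel
from .types import MUSCLES, CycleTensor, EmgRecording, EventTimes

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------- recordings
def read_emg(path, fs_hz: float = 1111.0) -> EmgRecording:
    """Read a delimited EMG matrix: rows = samples, columns = muscles,
    header = muscle labels.  Columns are reordered into the canonical
    muscle order by label, never by position."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse EMG file {path}: {exc}") from exc
    labels = [str(c).strip() for c in df.columns]
    missing = [m for m in MUSCLES if m not in labels]
    if missing:
        raise FormatError(f"EMG header is missing canonical labels: {', '.join(missing)}")
    df.columns = labels
    sub = df[list(MUSCLES)]
    bad = sub.columns[sub.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
    if len(bad):
        for col in bad:
            row = int(pd.to_numeric(sub[col], errors="coerce").isna().idxmax())
            raise FormatError(f"non-numeric value in column {col!r}, row {row}")
    return EmgRecording(sub.to_numpy(dtype=float).T, fs_hz=fs_hz)


def write_emg(path, rec: EmgRecording) -> None:
    pd.DataFrame(rec.signals.T, columns=list(rec.muscle_labels)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_events(path) -> EventTimes:
    """One event time (seconds) per line."""
    return EventTimes(np.loadtxt(path, ndmin=1))


def write_events(path, events: EventTimes) -> None:
    np.savetxt(path, events.times_s, fmt=_FLOAT_FMT)


def read_labels(path) -> np.ndarray:
    """Per-cycle condition labels, one per line."""
    return np.array(Path(path).read_text().split(), dtype=object)


# -------------------------------------------------------------------- cycles
def write_cycles(prefix, cycles: CycleTensor) -> None:
    """Write a cycle tensor as a flattened delimited matrix plus sidecar
    metadata (muscle order, per-cycle condition labels)."""
    prefix = Path(prefix)
    pd.DataFrame(cycles.flatten(), index=list(cycles.muscle_labels)).to_csv(
        prefix.with_suffix(".csv"), float_format=_FLOAT_FMT
    )
    meta = dict(
        muscle_labels=list(cycles.muscle_labels),
        n_cycles=cycles.n_cycles,
        n_points=int(cycles.data.shape[1]),
        condition=list(map(str, cycles.condition)),
    )
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_cycles(prefix) -> CycleTensor:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    flat = pd.read_csv(prefix.with_suffix(".csv"), index_col=0).to_numpy(dtype=float)
    n_points, n_cycles = meta["n_points"], meta["n_cycles"]
    data = flat.reshape(flat.shape[0], n_cycles, n_points).transpose(0, 2, 1)
    return CycleTensor(
        data,
        condition=np.array(meta["condition"], dtype=object),
        muscle_labels=tuple(meta["muscle_labels"]),
    )


# ----------------------------------------------------------------- synergies
def write_synergies(prefix, S: SynergySet, muscle_labels=MUSCLES) -> None:
    """W as muscles x synergies CSV, C as synergies x time CSV."""
    prefix = Path(prefix)
    cols = [f"syn{i + 1}" for i in range(S.N)]
    pd.DataFrame(S.W, index=list(muscle_labels), columns=cols).to_csv(
        prefix.parent / (prefix.name + "_W.csv"), float_format=_FLOAT_FMT
    )
    pd.DataFrame(S.C, index=cols).to_csv(
        prefix.parent / (prefix.name + "_C.csv"), float_format=_FLOAT_FMT
    )


def read_synergies(prefix) -> SynergySet:
    prefix = Path(prefix)
    W = pd.read_csv(prefix.parent / (prefix.name + "_W.csv"), index_col=0)
    C = pd.read_csv(prefix.parent / (prefix.name + "_C.csv"), index_col=0)
    return SynergySet(W.to_numpy(dtype=float), C.to_numpy(dtype=float))


# -------------------------------------------------------------------- curves
def write_vaf_curve(prefix, curve: VafCurve) -> None:
    prefix = Path(prefix)
    df = pd.DataFrame(
        dict(
            n=curve.n_grid,
            vaf_mean=curve.vaf_mean,
            ci_low=curve.ci_low if curve.ci_low is not None else np.nan,
            ci_high=curve.ci_high if curve.ci_high is not None else np.nan,
            mse=curve.mse_per_n if curve.mse_per_n is not None else np.nan,
        )
    )
    df.to_csv(prefix.with_suffix(".csv"), index=False, float_format=_FLOAT_FMT)
    summary = dict(
        n_selected=curve.n_selected,
        plateau_found=curve.plateau_found,
        warnings=list(curve.warnings),
    )
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2))


# ------------------------------------------------------------------ clusters
def write_clusters(prefix, clustered: ClusteredSynergies, muscle_labels=MUSCLES) -> None:
    """Per-cluster weight and activation means with 95% CI bounds."""
    prefix = Path(prefix)
    cols = [f"cluster{j + 1}" for j in range(clustered.k)]
    for name, arr, idx in (
        ("W_mean", clustered.centroid_W, list(muscle_labels)),
        ("W_ci_low", clustered.ci_W_low, list(muscle_labels)),
        ("W_ci_high", clustered.ci_W_high, list(muscle_labels)),
        ("C_mean", clustered.centroid_C, None),
        ("C_ci_low", clustered.ci_C_low, None),
        ("C_ci_high", clustered.ci_C_high, None),
    ):
        pd.DataFrame(arr, index=idx, columns=cols).to_csv(
            prefix.parent / (prefix.name + f"_{name}.csv"), float_format=_FLOAT_FMT
        )


# ------------------------------------------------------------ shared/specific
def write_shared_specific(prefix, model: SharedSpecificModel, muscle_labels=MUSCLES) -> None:
    prefix = Path(prefix)
    for name, W in (
        ("W_shared", model.W_shared),
        ("W_specific_A", model.W_spec_a),
        ("W_specific_B", model.W_spec_b),
    ):
        if W.shape[1]:
            pd.DataFrame(W, index=list(muscle_labels)).to_csv(
                prefix.parent / (prefix.name + f"_{name}.csv"), float_format=_FLOAT_FMT
            )
    report = dict(
        n_shared=model.n_sh,
        n_specific_A=model.n_a,
        n_specific_B=model.n_b,
        vaf_pooled_pct=model.vaf_pooled,
        vaf_A_pct=model.vaf_a,
        vaf_B_pct=model.vaf_b,
        warnings=list(model.warnings),
    )
    (prefix.parent / (prefix.name + "_report.json")).write_text(json.dumps(report, indent=2))


def write_feature_table(path, rows) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
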