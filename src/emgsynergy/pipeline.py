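"""End-to-end orchestration of the two-step synergy analysis.

Step one extracts synergies per condition and determines the synergy
number from the cross-validated VAF curves (direct repeated CV for the
small symptomatic dataset, bootstrap over 20-cycle subsamples for the
large asymptomatic one).  Step two pools both conditions and decomposes
them into shared and condition-specific synergies.  Bootstrap CIs of the
asymptomatic modules and a per-synergy feature table round out the run.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__, cluster, features, io, nmf, selection, shared
from .config import PipelineConfig
from .exceptions import SynergyError
from .preprocess import (
    detect_events,
    epoch_cycles,
    filter_emg,
    normalize,
    select_downbeats,
)
from .types import CONDITION_A, CONDITION_B, CycleTensor, EmgRecording, EventTimes

log = logging.getLogger("emgsynergy")


@dataclass
class PipelineResult:
    cycles_a: CycleTensor
    cycles_b: CycleTensor
    curve_a: selection.VafCurve
    curve_b: selection.VafCurve
    synergies_a: nmf.SynergySet
    synergies_b: nmf.SynergySet
    clustered: cluster.ClusteredSynergies
    shared_model: shared.SharedSpecificModel
    feature_rows: list
    manifest: dict


def _stage(name):
    """Decorator labeling stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SynergyError as exc:
                raise SynergyError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def preprocess_stage(cfg: PipelineConfig, rec: EmgRecording, click, labels,
                     events: EventTimes = None):
    """Raw signals -> per-condition cycle tensors, with bookkeeping."""
    if events is None:
        events = detect_events(click, rec.fs_hz, nominal_period_s=0.75)
        log.info("detected %d metronome events", len(events))
    analyzed = select_downbeats(events, every=cfg.epoch_every, offset=cfg.epoch_offset)
    filtered = filter_emg(rec, cutoff_hz=cfg.cutoff_hz, order=cfg.filter_order)
    res = epoch_cycles(
        filtered,
        analyzed,
        half_window_s=cfg.half_window_s,
        n_points=cfg.n_points,
        condition_labels=labels,
    )
    log.info(
        "epoched %d cycles (%d dropped at recording edges)",
        res.cycles.n_cycles,
        res.n_dropped,
    )
    cond = res.cycles.condition
    cycles_a = res.cycles.subset(np.flatnonzero(cond == CONDITION_A))
    cycles_b = res.cycles.subset(np.flatnonzero(cond == CONDITION_B))
    log.info(
        "cycle tally: %d %s / %d %s",
        cycles_b.n_cycles, CONDITION_B, cycles_a.n_cycles, CONDITION_A,
    )
    return cycles_a, cycles_b, res.n_dropped


def run_pipeline(
    cfg: PipelineConfig,
    rec: EmgRecording = None,
    click=None,
    labels=None,
    events: EventTimes = None,
) -> PipelineResult:
    """Execute the full analysis; inputs are read from the configured paths
    unless supplied directly.  All artifacts are written under
    ``cfg.output_dir`` together with a JSON run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list = []

    if rec is None:
        rec = _stage("read")(io.read_emg)(cfg.emg_path, fs_hz=cfg.fs_hz)
    if events is None and click is None and cfg.events_path:
        events = io.read_events(cfg.events_path)
    if click is None and cfg.click_path:
        click = np.loadtxt(cfg.click_path)
    if labels is None and cfg.labels_path:
        labels = io.read_labels(cfg.labels_path)

    cycles_a, cycles_b, n_dropped = _stage("preprocess")(preprocess_stage)(
        cfg, rec, click, labels, events
    )
    io.write_cycles(out / "cycles_without_dystonia", cycles_a)
    io.write_cycles(out / "cycles_with_dystonia", cycles_b)

    # --- step 1: per-condition synergy number -----------------------------
    seed = np.random.SeedSequence(cfg.seed)
    s_cv_b, s_boot_a, s_clust, s_extract, s_shared = (
        s.generate_state(1)[0] % 2**31 for s in seed.spawn(5)
    )
    curve_b = _stage("select-n")(selection.cross_validate)(
        cycles_b,
        n_reps=cfg.n_reps,
        train_frac=cfg.train_frac,
        n_max=cfg.n_max,
        seed=s_cv_b,
        divisor=cfg.divisor,
    )
    selection.choose_n(curve_b, mse_threshold=cfg.mse_threshold, scale=cfg.mse_scale)
    curve_a = _stage("select-n")(selection.bootstrap_reference)(
        cycles_a,
        subsample=min(cfg.subsample, cycles_a.n_cycles),
        n_boot=cfg.n_boot,
        train_frac=cfg.train_frac,
        n_max=cfg.n_max,
        seed=s_boot_a,
        divisor=cfg.divisor,
    )
    selection.choose_n(curve_a, mse_threshold=cfg.mse_threshold, scale=cfg.mse_scale)
    log.info(
        "selected %d synergies (%s), %d (%s)",
        curve_a.n_selected, CONDITION_A, curve_b.n_selected, CONDITION_B,
    )
    warnings.extend(curve_a.warnings + curve_b.warnings)
    io.write_vaf_curve(out / "vaf_without_dystonia", curve_a)
    io.write_vaf_curve(out / "vaf_with_dystonia", curve_b)

    # --- full-data extraction per condition (features + references) -------
    rng = np.random.default_rng(s_extract)
    per_condition = {}
    for name, cycles, n_sel in (
        (CONDITION_A, cycles_a, curve_a.n_selected),
        (CONDITION_B, cycles_b, curve_b.n_selected),
    ):
        norm = _stage("extract")(normalize)(cycles, divisor=cfg.divisor)
        S = _stage("extract")(nmf.extract)(
            norm.matrix, n_sel, seed=rng.integers(2**31),
            vaf_method=cfg.vaf_method, **cfg.nmf_params(),
        )
        per_condition[name] = (nmf.rescale_weights(S, norm.sigma), S.vaf_pct)
        io.write_synergies(out / f"synergies_{name}", per_condition[name][0])
    synergies_a, vaf_ref_a = per_condition[CONDITION_A]
    synergies_b, vaf_ref_b = per_condition[CONDITION_B]

    # --- bootstrap CIs for the asymptomatic modules ------------------------
    clustered = None
    if cfg.run_bootstrap_ci:
        reps = _stage("bootstrap-ci")(cluster.replicate_extract)(
            cycles_a,
            N=curve_a.n_selected,
            n_boot=cfg.cluster_n_boot,
            subsample=min(cfg.subsample, cycles_a.n_cycles),
            seed=s_clust,
            divisor=cfg.divisor,
        )
        clustered = _stage("bootstrap-ci")(cluster.constrained_kmeans)(
            reps, k=curve_a.n_selected, seed=s_clust
        )
        io.write_clusters(out / "clusters_without_dystonia", clustered)

    # --- step 2: shared / specific decomposition ---------------------------
    shared_model = None
    if cfg.run_shared_specific:
        pooled = _stage("shared-specific")(shared.pool)(
            cycles_a, cycles_b, divisor=cfg.divisor
        )
        shared_model = _stage("shared-specific")(shared.select_split)(
            pooled,
            n_a_ref=curve_a.n_selected,
            n_b_ref=curve_b.n_selected,
            vaf_ref_a=vaf_ref_a,
            vaf_ref_b=vaf_ref_b,
            seed=s_shared,
        )
        warnings.extend(shared_model.warnings)
        log.info(
            "shared/specific split: %d shared + %d/%d specific",
            shared_model.n_sh, shared_model.n_a, shared_model.n_b,
        )
        io.write_shared_specific(out / "shared_specific", shared_model)

    # --- features -----------------------------------------------------------
    rows = features.feature_table(synergies_a, CONDITION_A) + features.feature_table(
        synergies_b, CONDITION_B
    )
    if synergies_a.N == synergies_b.N:
        pairs, rvals = features.match_and_similarity(synergies_a.W, synergies_b.W)
        for (ia, ib), r in zip(pairs, rvals):
            rows[ia]["matched_synergy"] = ib
            rows[ia]["cosine_r"] = float(r)
            rows[synergies_a.N + ib]["matched_synergy"] = ia
            rows[synergies_a.N + ib]["cosine_r"] = float(r)
    io.write_feature_table(out / "features.csv", rows)

    manifest = dict(
        package_version=__version__,
        numpy_version=np.__version__,
        config={k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        stage_seeds=dict(
            cv_with=int(s_cv_b), bootstrap_without=int(s_boot_a),
            cluster=int(s_clust), extract=int(s_extract), shared=int(s_shared),
        ),
        n_cycles=dict(
            without_dystonia=cycles_a.n_cycles, with_dystonia=cycles_b.n_cycles,
            dropped_events=n_dropped,
        ),
        n_selected=dict(
            without_dystonia=curve_a.n_selected, with_dystonia=curve_b.n_selected,
        ),
        shared_specific=(
            None
            if shared_model is None
            else dict(n_shared=shared_model.n_sh, n_specific_A=shared_model.n_a,
                      n_specific_B=shared_model.n_b)
        ),
        warnings=warnings,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        cycles_a, cycles_b, curve_a, curve_b,
        synergies_a, synergies_b, clustered, shared_model, rows, manifest,
    )
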