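"""Pipeline configuration: one validated record for the whole analysis."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ParameterError


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; validated at construction.

    Paths may be None for stages fed programmatically.  The seed is
    mandatory: every stochastic stage derives its own stream from it.
    """

    # inputs
    emg_path: str = None
    click_path: str = None
    events_path: str = None
    labels_path: str = None
    output_dir: str = "results"
    # preprocessing
    fs_hz: float = 1111.0
    cutoff_hz: float = 20.0
    filter_order: int = 4
    half_window_s: float = 0.75
    n_points: int = 151
    epoch_every: int = 4
    epoch_offset: int = 0
    divisor: str = "range"
    # model selection
    n_reps: int = 20
    train_frac: float = 0.8
    n_max: int = 10
    n_boot: int = 1000
    subsample: int = 20
    mse_threshold: float = 1e-5
    mse_scale: str = "fraction"
    # extraction
    n_restarts: int = 5
    max_iter: int = 1000
    tol: float = 1e-6
    vaf_method: str = "sse"
    # stage toggles
    run_bootstrap_ci: bool = True
    run_shared_specific: bool = True
    cluster_n_boot: int = None  # defaults to n_boot
    # randomness
    seed: int = field(default=None)

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("seed is mandatory for any stochastic stage")
        if not 0 < self.train_frac < 1:
            raise ParameterError("train_frac must lie strictly between 0 and 1")
        if self.cutoff_hz <= 0 or self.cutoff_hz >= self.fs_hz / 2:
            raise ParameterError("cutoff_hz must lie in (0, Nyquist)")
        if self.n_points < 3 or self.half_window_s <= 0:
            raise ParameterError("invalid epoch window parameters")
        if self.n_max < 3:
            raise ParameterError("n_max must be >= 3 for plateau selection")
        if self.n_reps < 1 or self.n_boot < 1 or self.subsample < 5:
            raise ParameterError("invalid repetition/bootstrap counts")
        if self.mse_threshold <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ParameterError("invalid extraction/selection tolerances")
        if self.divisor not in ("range", "max"):
            raise ParameterError("divisor must be 'range' or 'max'")
        if self.mse_scale not in ("fraction", "percent"):
            raise ParameterError("mse_scale must be 'fraction' or 'percent'")
        if self.vaf_method not in ("sse", "corr"):
            raise ParameterError("vaf_method must be 'sse' or 'corr'")
        if self.epoch_every < 1:
            raise ParameterError("epoch_every must be >= 1")
        if self.cluster_n_boot is None:
            self.cluster_n_boot = self.n_boot

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def nmf_params(self) -> dict:
        return dict(n_restarts=self.n_restarts, max_iter=self.max_iter, tol=self.tol)
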