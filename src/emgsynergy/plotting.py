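"""Basic diagnostic plots (VAF curve, spatial/temporal modules)."""
from __future__ import annotations

import numpy as np

from .selection import VafCurve
from .types import MUSCLES, TIME_AXIS_MS


def plot_vaf_curve(curve: VafCurve, ax=None, label=None, color=None):
    """VAF vs synergy number with CI band where available."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.n_grid, curve.vaf_mean, "o-", label=label, color=color)
    if curve.ci_low is not None:
        ax.fill_between(curve.n_grid, curve.ci_low, curve.ci_high, alpha=0.2, color=color)
    if curve.n_selected is not None:
        ax.axvline(curve.n_selected, ls="--", lw=0.8, color=color or "k")
    ax.set_xlabel("number of synergies")
    ax.set_ylabel("VAF (%)")
    if label:
        ax.legend()
    return ax


def plot_synergies(W, profiles, muscle_labels=MUSCLES, axes=None):
    """Bar plot of each spatial module next to its temporal module."""
    import matplotlib.pyplot as plt

    W = np.asarray(W)
    k = W.shape[1]
    if axes is None:
        _, axes = plt.subplots(k, 2, figsize=(8, 1.6 * k), squeeze=False)
    for j in range(k):
        axes[j][0].bar(range(len(muscle_labels)), W[:, j])
        axes[j][0].set_xticks(range(len(muscle_labels)), muscle_labels, fontsize=6)
        axes[j][0].set_ylabel(f"W{j + 1}", fontsize=8)
        axes[j][1].plot(TIME_AXIS_MS, profiles[j])
        axes[j][1].axvline(0, ls=":", lw=0.8, color="k")
        if j == k - 1:
            axes[j][1].set_xlabel("time re event (ms)")
    return axes
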