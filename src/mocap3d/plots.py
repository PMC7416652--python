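"""Static diagnostic plots: velocity-vs-time traces and error boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_velocity(speeds: np.ndarray, keep: np.ndarray, path,
                  fitted: np.ndarray | None = None,
                  threshold: float | None = 2.5) -> None:
    """Per-step speed dots with masked spans marked by vertical bars."""
    t = np.arange(len(speeds))
    ok = np.isfinite(speeds)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(t[ok & keep], speeds[ok & keep], ".", ms=4, label="speed")
    for ti in t[ok & ~keep]:
        ax.axvline(ti, color="red", alpha=0.4, lw=1)
    if fitted is not None:
        ax.plot(np.arange(len(fitted)), fitted, "-", lw=1.5, label="best fit")
    if threshold is not None:
        ax.axhline(threshold, color="gray", ls="--", lw=1)
    ax.set_xlabel("timestep")
    ax.set_ylabel("speed (m/s)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_error_boxes(errors: pd.DataFrame, path, value="error_mm",
                     by="pair") -> None:
    """Boxplot panel of per-pair (or per-marker) error distributions."""
    groups = sorted(errors[by].unique())
    data = [errors.loc[errors[by] == g, value].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(groups), 3.5))
    ax.boxplot(data, tick_labels=[str(g) for g in groups])
    ax.set_xlabel(by)
    ax.set_ylabel(value)
    ax.axhline(0.0, color="gray", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
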