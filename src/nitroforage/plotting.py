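"""Optional matplotlib renderings of growth-curve panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import PatchResult, SplitRootSummary  # noqa: E402
from .simulate import Trajectory  # noqa: E402

__all__ = ["plot_trajectory", "plot_split_root_bars", "plot_patch"]


def plot_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Per-compartment root length versus time."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for x in range(traj.L.shape[1]):
        ax.plot(traj.times, traj.L[:, x], label=f"compartment {x}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cumulative root length (mm)")
    if traj.L.shape[1] <= 4:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_split_root_bars(summary: SplitRootSummary, path: str | Path) -> Path:
    """Final focal-half lengths for the four split-root conditions."""
    labels = ["LN/LN", "LN/HN", "HN/LN", "HN/HN"]
    values = [summary.ln_ln, summary.ln_hn, summary.hn_ln, summary.hn_hn]
    colors = ["navy", "firebrick", "forestgreen", "lightskyblue"]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.bar(labels, values, color=colors)
    ax.set_ylabel("final length (mm)")
    ax.set_title(summary.mutant)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_patch(on: PatchResult, off: PatchResult, path: str | Path) -> Path:
    """High-patch and summed low-compartment growth, CK gating on vs off."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(off.times, off.L_high, "k-", label="high patch, no CK gating")
    ax.plot(off.times, off.L_low_sum, "k--", label="low sum, no CK gating")
    ax.plot(on.times, on.L_high, "r-", label="high patch, CK gating")
    ax.plot(on.times, on.L_low_sum, "r--", label="low sum, CK gating")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cumulative root length (mm)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
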