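"""Optional figure generation (matplotlib; imported lazily by the CLI)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["plot_curling_profiles", "plot_grade_histograms", "plot_parameter_profiles"]

GRADE_LABELS = ["0", "I", "II", "III", "IV"]
GRADE_COLORS = ["#2a9d2a", "#9acd32", "#e6c229", "#e8832a", "#d62728"]


def plot_curling_profiles(profiles: dict, path) -> Path:
    """Tip trajectories over stylet extraction for several arrays."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, prof in profiles.items():
        traj = prof.tip_trajectory
        ax.plot(traj[:, 0], traj[:, 1], label=label)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title("curling profiles (tip trajectory over stylet extraction)")
    ax.legend()
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_grade_histograms(batch_frame, path) -> Path:
    """Grouped grade-share bars per strategy, arrays x cochleae panels."""
    import matplotlib.pyplot as plt

    strategies = sorted(batch_frame.strategy.unique())
    fig, axes = plt.subplots(1, len(strategies), figsize=(5 * len(strategies), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, strat in zip(axes, strategies):
        sub = batch_frame[batch_frame.strategy == strat]
        shares = sub[[f"grade_{g}" for g in GRADE_LABELS]].mean()
        ax.bar(GRADE_LABELS, shares, color=GRADE_COLORS)
        ax.set_title(strat)
        ax.set_xlabel("trauma-risk grade")
    axes[0].set_ylabel("share of insertion steps")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_parameter_profiles(plans: dict, path) -> Path:
    """dphi(s), dy(s) and dx(s) of optimized plans, normalized to s=0."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for label, plan in plans.items():
        s = plan.s_values
        poses = plan.poses
        axes[0].plot(s, poses[:, 2] - poses[0, 2], label=label)
        axes[1].plot(s, poses[:, 1] - poses[0, 1], label=label)
        axes[2].plot(s, poses[:, 0], label=label)
    if plans:
        s = next(iter(plans.values())).s_values
        axes[2].plot(s, s, "r:", label="1:1 coupling")
    for ax, ylab in zip(axes, ["dphi - dphi0 (deg)", "dy - dy0 (mm)", "dx (mm)"]):
        ax.set_xlabel("stylet extraction s (mm)")
        ax.set_ylabel(ylab)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
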