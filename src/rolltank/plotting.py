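"""Basic trajectory figures (matplotlib, non-interactive backend safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .dynamics import Trajectory  # noqa: E402

__all__ = ["plot_xy_path", "plot_trajectory_3d"]


def plot_xy_path(trajectories, geometry=None, ax=None, **kwargs):
    """Cross-sectional (x, y) paths, with the cylinder wall if given."""
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for tr in trajectories:
        ax.plot(tr.positions[:, 0], tr.positions[:, 1], **kwargs)
        ax.plot(tr.positions[0, 0], tr.positions[0, 1], "o", ms=4, color="red")
    if geometry is not None:
        circle = plt.Circle((0, 0), geometry.inner_radius, fill=False, color="k", lw=1)
        ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax


def plot_trajectory_3d(trajectories, geometry=None, ax=None, **kwargs):
    """3-D pathlines (z along the cylinder axis)."""
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    if ax is None:
        fig = plt.figure(figsize=(7, 5))
        ax = fig.add_subplot(projection="3d")
    for tr in trajectories:
        ax.plot(tr.positions[:, 2], tr.positions[:, 0], tr.positions[:, 1], **kwargs)
    ax.set_xlabel("z (m)")
    ax.set_ylabel("x (m)")
    ax.set_zlabel("y (m)")
    return ax
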