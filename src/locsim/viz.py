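"""Trajectory animation export (optional; never required by the physics)."""

from __future__ import annotations

import warnings

import numpy as np

from .engine import TrajectoryLog
from .errors import ConfigurationError

__all__ = ["export_animation"]


def export_animation(log: TrajectoryLog, path, geometry_meta: dict | None = None, fps: int = 20):
    """Render the logged particle positions (xy and xz views) to a video
    file (GIF via pillow, or any container matplotlib's writers support).

    Returns the path on success; on a missing rendering backend the export
    is skipped with a warning and ``None`` is returned.
    """
    if log.positions.shape[0] == 0:
        raise ConfigurationError("cannot animate an empty trajectory log")
    try:
        import matplotlib

        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt
        from matplotlib import animation
    except Exception as exc:  # pragma: no cover - environment dependent
        warnings.warn(f"animation export skipped: no rendering backend ({exc})")
        return None

    pos_um = log.positions * 1e6
    fig, (ax_xy, ax_xz) = plt.subplots(2, 1, figsize=(8, 6))
    for ax, comp, label in ((ax_xy, 1, "y"), (ax_xz, 2, "z")):
        ax.set_xlabel("x (um)")
        ax.set_ylabel(f"{label} (um)")
        ax.set_xlim(pos_um[..., 0].min() - 5, pos_um[..., 0].max() + 5)
        ax.set_ylim(pos_um[..., comp].min() - 5, pos_um[..., comp].max() + 5)
    if geometry_meta and "electrodes" in geometry_meta:
        for poly in geometry_meta["electrodes"].values():
            xy = np.asarray(poly) * 1e6
            ax_xy.fill(xy[:, 0], xy[:, 1], color="gold", alpha=0.5, zorder=0)
    sc_xy = ax_xy.scatter(pos_um[0, :, 0], pos_um[0, :, 1])
    sc_xz = ax_xz.scatter(pos_um[0, :, 0], pos_um[0, :, 2])
    title = ax_xy.set_title(f"t = {log.times[0]:.2f} s")

    def _frame(i):
        sc_xy.set_offsets(pos_um[i, :, :2])
        sc_xz.set_offsets(pos_um[i, :, ::2])
        title.set_text(f"t = {log.times[i]:.2f} s")
        return sc_xy, sc_xz, title

    anim = animation.FuncAnimation(fig, _frame, frames=len(log.times), blit=False)
    try:
        anim.save(path, writer=animation.PillowWriter(fps=fps))
    except Exception as exc:  # pragma: no cover - writer availability varies
        warnings.warn(f"animation export skipped: writer failed ({exc})")
        plt.close(fig)
        return None
    plt.close(fig)
    return path
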