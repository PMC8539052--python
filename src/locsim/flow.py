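"""Fluid velocity fields.

Flow models implement ``velocity(r, t) -> (n, 3)``.  The cell-sorter device
uses a piecewise-constant approximation: a left-to-right carrier flow that
acquires a transverse component in the two slanted outlet channels so the
average flow is tangential to the channel walls.  An optional box
moving-average smoothing turns the piecewise field into a continuous one.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import uniform_filter

from .errors import DomainError

__all__ = ["UniformFlow", "PiecewiseFlow", "sorter_flow", "SorterFlow", "smooth_flow", "SmoothedFlow"]


class UniformFlow:
    """Spatially uniform, steady flow."""

    def __init__(self, velocity):
        self.v = np.asarray(velocity, dtype=float).reshape(3)

    def velocity(self, r, t=0.0):
        r = np.asarray(r, dtype=float)
        return np.broadcast_to(self.v, r.shape).copy()


class PiecewiseFlow:
    """First-match list of ``(predicate(x, y, z) -> bool array, velocity)``
    regions with a default velocity; every point maps to exactly one region."""

    def __init__(self, regions, default):
        self.regions = [(pred, np.asarray(v, dtype=float).reshape(3)) for pred, v in regions]
        self.default = np.asarray(default, dtype=float).reshape(3)

    def velocity(self, r, t=0.0):
        r = np.atleast_2d(np.asarray(r, dtype=float))
        out = np.broadcast_to(self.default, r.shape).copy()
        unset = np.ones(r.shape[0], dtype=bool)
        for pred, v in self.regions:
            hit = unset & np.asarray(pred(r[:, 0], r[:, 1], r[:, 2]), dtype=bool)
            out[hit] = v
            unset &= ~hit
        return out


def SorterFlow(speed: float = 150e-6, v_y: float = 30e-6, x_split: float = 170e-6, y_split: float = 30e-6):
    """Piecewise sorter flow: ``(speed, +v_y, 0)`` for x > x_split, y > y_split;
    ``(speed, -v_y, 0)`` for x > x_split, y < -y_split; ``(speed, 0, 0)``
    otherwise (strict inequalities; the split lines fall to the default)."""
    return PiecewiseFlow(
        regions=[
            (lambda x, y, z: (x > x_split) & (y > y_split), (speed, v_y, 0.0)),
            (lambda x, y, z: (x > x_split) & (y < -y_split), (speed, -v_y, 0.0)),
        ],
        default=(speed, 0.0, 0.0),
    )


def sorter_flow(r):
    """Sorter flow velocity at ``r`` (SI), default device constants."""
    return SorterFlow().velocity(r)


class SmoothedFlow:
    """Box moving-average of a flow field, sampled on a regular grid and
    interpolated back; ``kernel_width = 0`` reproduces the base field."""

    def __init__(self, base, kernel_width: float, bounds, spacing: float):
        if kernel_width < 0:
            raise DomainError(f"kernel width must be >= 0, got {kernel_width}")
        self.base = base
        self.kernel_width = float(kernel_width)
        if kernel_width == 0:
            self._interp = None
            return
        axes = [np.arange(lo, hi + spacing / 2, spacing) for lo, hi in bounds]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        vals = base.velocity(pts).reshape(X.shape + (3,))
        size = max(1, int(round(kernel_width / spacing)))
        smoothed = np.stack(
            [uniform_filter(vals[..., k], size=size, mode="nearest") for k in range(3)], axis=-1
        )
        self._interp = RegularGridInterpolator(axes, smoothed, bounds_error=False, fill_value=None)
        self._bounds = bounds

    def velocity(self, r, t=0.0):
        if self._interp is None:
            return self.base.velocity(r, t)
        r = np.atleast_2d(np.asarray(r, dtype=float))
        lo = np.array([b[0] for b in self._bounds])
        hi = np.array([b[1] for b in self._bounds])
        return self._interp(np.clip(r, lo, hi))


def smooth_flow(flow, kernel_width: float, bounds=None, spacing: float = 5e-6):
    """Return a smoothed version of ``flow`` (see :class:`SmoothedFlow`).

    ``bounds`` is ``((x0, x1), (y0, y1), (z0, z1))`` in metres; required
    when ``kernel_width > 0``.
    """
    if kernel_width == 0:
        return flow
    if bounds is None:
        raise DomainError("smoothing needs explicit domain bounds")
    return SmoothedFlow(flow, kernel_width, bounds, spacing)
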