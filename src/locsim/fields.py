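"""Scalar |E|^2 field plumbing for the DEP force.

The electric field of a device is computed externally (any electrostatics
solver); this module only consumes the squared field magnitude ``|E|^2``:

* :class:`GridScalarField` — ``|E|^2`` sampled on a regular 2D/3D lattice,
  read from a plain-text file; the gradient is precomputed with
  second-order central differences and queried through multilinear
  interpolation.  Queries outside the grid are clamped to the edge (with a
  one-time warning), so fixtures should pad the domain past the particle
  injection region.
* :class:`AnalyticScalarField` — a user-supplied callable pair
  ``value(r)`` / ``gradient(r)`` with closed forms.
* :func:`sorter_surrogate_field` — a qualitative analytic stand-in for the
  cell-sorter device field: two smooth intensity ridges running along the
  electrode gaps, decaying exponentially with height.

Grid file format (text, ``# locsim-e2-grid v1`` header)::

    # locsim-e2-grid v1
    origin_um: x0 y0 z0
    spacing_um: dx dy dz
    shape: nx ny nz
    <nx*ny*nz values of |E|^2 in V^2/m^2, C-order (x slowest, z fastest)>
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigurationError, DomainError

__all__ = [
    "GridScalarField",
    "AnalyticScalarField",
    "read_e2_grid",
    "write_e2_grid",
    "sorter_surrogate_field",
]

_MAGIC = "# locsim-e2-grid v1"


class AnalyticScalarField:
    """Closed-form scalar field with its exact gradient.

    ``value(r)`` and ``gradient(r)`` accept ``(..., 3)`` arrays (SI metres)
    and return ``(...)`` / ``(..., 3)`` arrays.
    """

    def __init__(self, value, gradient):
        self._value = value
        self._gradient = gradient

    def value(self, r):
        return self._value(np.asarray(r, dtype=float))

    def gradient(self, r):
        return self._gradient(np.asarray(r, dtype=float))


class GridScalarField:
    """Regular-lattice scalar field with interpolated central-difference
    gradient and clamp-to-edge extrapolation."""

    def __init__(self, origin, spacing, values):
        self.origin = np.asarray(origin, dtype=float).reshape(3)
        self.spacing = np.asarray(spacing, dtype=float).reshape(3)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("grid values must be a 3D array (use nz=1 for planar fields)")
        if np.any(self.spacing <= 0):
            raise ConfigurationError(f"grid spacing must be positive, got {self.spacing}")
        if np.any(self.values < 0):
            raise ConfigurationError("|E|^2 must be non-negative everywhere")
        axes = [
            self.origin[k] + self.spacing[k] * np.arange(self.values.shape[k])
            for k in range(3)
        ]
        self._axes = axes
        self._interp = RegularGridInterpolator(axes, self.values, bounds_error=False, fill_value=None)
        grads = []
        for k in range(3):
            if self.values.shape[k] > 1:
                g = np.gradient(self.values, self.spacing[k], axis=k, edge_order=2)
            else:
                g = np.zeros_like(self.values)
            grads.append(RegularGridInterpolator(axes, g, bounds_error=False, fill_value=None))
        self._grad_interp = grads
        self._warned = False

    def _clamp(self, r):
        r = np.atleast_2d(np.asarray(r, dtype=float))
        lo = np.array([a[0] for a in self._axes])
        hi = np.array([a[-1] for a in self._axes])
        # degenerate (single-sample) axes are unconstrained
        flat = np.array([len(a) == 1 for a in self._axes])
        out = (r < lo) | (r > hi)
        out[:, flat] = False
        if np.any(out) and not self._warned:
            warnings.warn("field query outside grid domain; clamping to edge", stacklevel=3)
            self._warned = True
        return np.clip(r, lo, hi)

    def value(self, r):
        r = np.asarray(r, dtype=float)
        squeeze = r.ndim == 1
        out = self._interp(self._clamp(r))
        return out[0] if squeeze else out

    def gradient(self, r):
        r = np.asarray(r, dtype=float)
        squeeze = r.ndim == 1
        rc = self._clamp(r)
        out = np.stack([g(rc) for g in self._grad_interp], axis=-1)
        return out[0] if squeeze else out


def write_e2_grid(path, field: GridScalarField) -> None:
    """Write a :class:`GridScalarField` in the documented text format."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write("origin_um: " + " ".join(f"{v * 1e6:.9g}" for v in field.origin) + "\n")
        fh.write("spacing_um: " + " ".join(f"{v * 1e6:.9g}" for v in field.spacing) + "\n")
        fh.write("shape: " + " ".join(str(s) for s in field.values.shape) + "\n")
        np.savetxt(fh, field.values.reshape(-1, 1))


def read_e2_grid(path) -> GridScalarField:
    """Read the documented text grid format; validates header and size."""
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _MAGIC:
            raise ConfigurationError(f"not a locsim |E|^2 grid file (header {header!r})")
        meta = {}
        for _ in range(3):
            key, _, rest = fh.readline().partition(":")
            meta[key.strip()] = rest.split()
        try:
            origin = np.array([float(v) * 1e-6 for v in meta["origin_um"]])
            spacing = np.array([float(v) * 1e-6 for v in meta["spacing_um"]])
            shape = tuple(int(v) for v in meta["shape"])
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"malformed grid header: {exc}") from exc
        data = np.loadtxt(fh)
    if data.size != int(np.prod(shape)):
        raise ConfigurationError(
            f"grid payload has {data.size} values, header shape {shape} needs {int(np.prod(shape))}"
        )
    return GridScalarField(origin, spacing, data.reshape(shape))


def sorter_surrogate_field(
    *,
    e2_peak: float,
    ridge_half_gap_start: float = 31e-6,
    ridge_half_gap_end: float = 43e-6,
    x_start: float = -175e-6,
    x_end: float = 175e-6,
    sigma_y: float = 12e-6,
    z_decay: float = 25e-6,
    edge_width: float = 10e-6,
) -> AnalyticScalarField:
    """Analytic stand-in for the sorter |E|^2 distribution.

    Two Gaussian ridges (width ``sigma_y``) run along the electrode gap
    centrelines ``y = +-yc(x)``, where ``yc`` tapers linearly from
    ``ridge_half_gap_start`` to ``ridge_half_gap_end`` over the electrode
    length, mirroring the tapered middle electrode.  A logistic window
    confines the field to the electrode span in ``x`` and the intensity
    decays as ``exp(-z/z_decay)`` above the planar electrodes.  ``e2_peak``
    (V^2/m^2) is the ridge-top intensity at z = 0.

    The shape is qualitative by construction — it reproduces where the real
    field is strong (the gaps) and its sign structure, not its magnitudes.
    """
    if e2_peak < 0:
        raise DomainError("e2_peak must be non-negative")
    span = x_end - x_start
    slope = (ridge_half_gap_end - ridge_half_gap_start) / span

    def _parts(r):
        x, y, z = r[..., 0], r[..., 1], r[..., 2]
        s0 = 1.0 / (1.0 + np.exp(-(x - x_start) / edge_width))
        s1 = 1.0 / (1.0 + np.exp(-(x_end - x) / edge_width))
        wx = s0 * s1
        yc = ridge_half_gap_start + slope * (x - x_start)
        gm = np.exp(-((y - yc) ** 2) / (2.0 * sigma_y**2))
        gp = np.exp(-((y + yc) ** 2) / (2.0 * sigma_y**2))
        ez = np.exp(-np.maximum(z, 0.0) / z_decay)
        return x, y, z, s0, s1, wx, yc, gm, gp, ez

    def value(r):
        _, _, _, _, _, wx, _, gm, gp, ez = _parts(r)
        return e2_peak * wx * (gm + gp) * ez

    def gradient(r):
        x, y, z, s0, s1, wx, yc, gm, gp, ez = _parts(r)
        g_sum = gm + gp
        dwx = (s0 * (1 - s0) * s1 - s0 * s1 * (1 - s1)) / edge_width
        # chain rule through the tapering ridge centreline yc(x)
        dg_dx = slope * (gm * (y - yc) - gp * (y + yc)) / sigma_y**2
        dval_dx = e2_peak * ez * (dwx * g_sum + wx * dg_dx)
        dval_dy = e2_peak * ez * wx * (-(y - yc) * gm - (y + yc) * gp) / sigma_y**2
        dval_dz = np.where(z > 0, -e2_peak * wx * g_sum * ez / z_decay, 0.0)
        return np.stack([dval_dx, dval_dy, dval_dz], axis=-1)

    return AnalyticScalarField(value, gradient)
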