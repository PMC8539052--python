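"""Dielectric response of layered cells for dielectrophoresis.

A biological cell in an AC field is modelled as concentric spherical layers
(cytoplasm core, plasma membrane, cell wall), each with a complex relative
permittivity ``eps~ = eps_r - j*sigma/(2*pi*f*eps0)``.  The multi-shell
(single-shell applied recursively) homogenization replaces the innermost
sphere plus its surrounding shell by one equivalent sphere:

    gamma = R_shell / R_inner
    K     = (eps~_inner - eps~_shell) / (eps~_inner + 2*eps~_shell)
    eps~_eq = eps~_shell * (gamma^3 + 2*K) / (gamma^3 - K)

repeated outward until a single equivalent homogeneous sphere remains.  The
Clausius–Mossotti factor of that sphere in a medium ``eps~_m``,

    CM = (eps~_p - eps~_m) / (eps~_p + 2*eps~_m),

sets the sign and strength of the time-averaged DEP force: ``Re(CM) > 0``
pulls the particle toward field maxima (positive DEP), ``Re(CM) < 0``
pushes it away.

The bundled yeast parameterization (``data/yeast_cells.yaml``) is a
two-shell cell (cytoplasm + membrane + wall) whose layer values are
calibrated so the homogenized sphere reproduces the reference effective
properties of viable and non-viable yeast at 5 MHz (relative permittivities
199.94 / 18.82, conductivities 0.36 / 0.013 S/m).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .constants import EPS0
from .core import Medium
from .errors import DegenerateParameterError, DomainError

__all__ = [
    "ShellLayer",
    "ShellSpec",
    "complex_permittivity",
    "multishell_effective_permittivity",
    "effective_properties",
    "cm_factor",
    "medium_complex_permittivity",
    "load_yeast_cells",
]


def complex_permittivity(eps_r: float, sigma: float, f: float) -> complex:
    """Complex relative permittivity ``eps_r - j*sigma/(2*pi*f*eps0)``."""
    if f <= 0:
        raise DomainError(f"frequency must be positive, got {f}")
    return complex(eps_r, -sigma / (2.0 * np.pi * f * EPS0))


@dataclass(frozen=True)
class ShellLayer:
    """One concentric layer: outer radius (m), relative permittivity,
    conductivity (S/m)."""

    radius: float
    eps_r: float
    sigma: float


@dataclass(frozen=True)
class ShellSpec:
    """Ordered layers from the core outward; the outermost radius is the
    particle radius."""

    layers: tuple[ShellLayer, ...]

    def __post_init__(self):
        if not self.layers:
            raise DomainError("ShellSpec needs at least one layer")
        radii = [l.radius for l in self.layers]
        if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
            raise DomainError(f"layer radii must be positive and strictly increasing, got {radii}")

    @property
    def ro(self) -> float:
        """Outer (particle) radius, m."""
        return self.layers[-1].radius


def multishell_effective_permittivity(shells: ShellSpec, f: float) -> complex:
    """Equivalent complex relative permittivity of the layered sphere."""
    layers = shells.layers
    eq = complex_permittivity(layers[0].eps_r, layers[0].sigma, f)
    r_inner = layers[0].radius
    for layer in layers[1:]:
        sh = complex_permittivity(layer.eps_r, layer.sigma, f)
        gamma3 = (layer.radius / r_inner) ** 3
        K = (eq - sh) / (eq + 2.0 * sh)
        denom = gamma3 - K
        if abs(denom) < 1e-12 * max(1.0, abs(gamma3)):
            raise DegenerateParameterError("gamma^3 = K: shell homogenization is degenerate")
        eq = sh * (gamma3 + 2.0 * K) / denom
        r_inner = layer.radius
    return eq


def effective_properties(shells: ShellSpec, f: float) -> tuple[float, float]:
    """(effective relative permittivity, effective conductivity in S/m)."""
    eq = multishell_effective_permittivity(shells, f)
    return eq.real, -eq.imag * 2.0 * np.pi * f * EPS0


def medium_complex_permittivity(medium: Medium, f: float) -> complex:
    """Complex relative permittivity of the suspension medium."""
    return complex_permittivity(medium.eps_m, medium.sigma_m, f)


def cm_factor(eps_p: complex, eps_m: complex) -> complex:
    """Clausius–Mossotti factor ``(eps~_p - eps~_m)/(eps~_p + 2*eps~_m)``."""
    denom = eps_p + 2.0 * eps_m
    if abs(denom) < 1e-15 * max(1.0, abs(eps_p), abs(eps_m)):
        raise DegenerateParameterError("eps~_p + 2 eps~_m = 0: CM factor undefined")
    return (eps_p - eps_m) / denom


def _shells_from_dict(d: dict) -> ShellSpec:
    return ShellSpec(
        tuple(ShellLayer(l["radius_um"] * 1e-6, l["eps_r"], l["sigma_S_per_m"]) for l in d["layers"])
    )


def load_yeast_cells(path=None) -> dict:
    """Load the bundled (or a user-supplied) yeast cell parameterization.

    Returns ``{"viable": ShellSpec, "nonviable": ShellSpec,
    "medium": Medium-kwargs dict, "frequency_Hz": float}``.
    """
    if path is None:
        text = resources.files("locsim.data").joinpath("yeast_cells.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        "viable": _shells_from_dict(raw["viable"]),
        "nonviable": _shells_from_dict(raw["nonviable"]),
        "medium": raw["medium"],
        "frequency_Hz": float(raw["frequency_Hz"]),
    }
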