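"""Unit conversion at the configuration boundary.

All internal computation is in SI.  Configuration files use the unit
conventions of the microfluidics literature: lengths in micrometres,
velocities in micrometres per second, times in seconds, forces in
piconewtons, voltages in volts.  ``to_si``/``from_si`` convert scalars or
arrays between configuration units and SI.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

#: Multiplicative factor taking a quantity *in the tagged unit* to SI.
_FACTORS = {
    "um": 1e-6,
    "μm": 1e-6,
    "um/s": 1e-6,
    "μm/s": 1e-6,
    "um2/s": 1e-12,
    "μm2/s": 1e-12,
    "s": 1.0,
    "ms": 1e-3,
    "pN": 1e-12,
    "V": 1.0,
    "m": 1.0,
    "m/s": 1.0,
}


def _factor(unit: str) -> float:
    try:
        return _FACTORS[unit]
    except KeyError:
        raise ConfigurationError(f"unknown unit tag {unit!r}") from None


def to_si(value, unit: str):
    """Convert ``value`` tagged with ``unit`` to the corresponding SI unit."""
    return np.asarray(value, dtype=float) * _factor(unit) if np.ndim(value) else float(value) * _factor(unit)


def from_si(value, unit: str):
    """Inverse of :func:`to_si`."""
    return np.asarray(value, dtype=float) / _factor(unit) if np.ndim(value) else float(value) / _factor(unit)
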