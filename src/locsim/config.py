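"""Experiment configuration files.

Configurations are YAML (or JSON) documents with sections ``seed``,
``time``, ``medium``, ``particles``, ``forces``, ``flow``, ``geometry``,
``init_box_um`` and ``output``.  All lengths are in micrometres, times in
seconds, voltages in volts; key names carry their units.  Unknown keys are
rejected with the offending section in the message.
"""

from __future__ import annotations

import numpy as np
import yaml

from .constants import KB
from .core import Medium, ParticleState, mass_from_density
from .dielectrics import load_yeast_cells
from .engine import SimulationConfig
from .errors import ConfigurationError
from .fields import read_e2_grid, sorter_surrogate_field
from .flow import SorterFlow, UniformFlow, smooth_flow
from .forces import DEPForce, GaussianTrap, GravityBuoyancy, TimeGated
from .geometry import build_sorter_geometry, build_trap_geometry

__all__ = ["load_config", "build_simulation", "validate_config", "write_config"]

_UM = 1e-6

_SCHEMA = {
    "seed": None,
    "time": {"dt_s", "t_end_s"},
    "medium": {"eta_Pa_s", "T_K", "eps_m", "sigma_S_per_m", "rho_kg_per_m3"},
    "particles": {
        "radius_um",
        "density_kg_per_m3",
        "mass_kg",
        "position_um",
        "velocity_um_s",
        "re_cm",
        "cell",
        "count",
    },
    "forces": {
        "type",
        "ad_kBT_per_um3",
        "width_um",
        "center_um",
        "t_on_s",
        "t_off_s",
        "frequency_Hz",
        "field",
    },
    "field": {"type", "path", "e2_peak_V2_per_m2"},
    "flow": {"type", "velocity_um_s", "kernel_width_um"},
    "geometry": {"type", "full_height_walls"},
    "init_box_um": None,
    "output": {"log_every"},
}

_TOP_KEYS = {
    "seed",
    "time",
    "medium",
    "particles",
    "forces",
    "flow",
    "geometry",
    "init_box_um",
    "output",
}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in section {where!r}")


def validate_config(doc: dict) -> dict:
    """Structural validation; returns the document unchanged if valid."""
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration root must be a mapping")
    _check_keys(doc, _TOP_KEYS, "<root>")
    for sect in ("time", "medium", "particles"):
        if sect not in doc:
            raise ConfigurationError(f"missing required section {sect!r}")
    _check_keys(doc["time"], _SCHEMA["time"], "time")
    _check_keys(doc["medium"], _SCHEMA["medium"], "medium")
    if not isinstance(doc["particles"], list) or not doc["particles"]:
        raise ConfigurationError("'particles' must be a non-empty list")
    for k, p in enumerate(doc["particles"]):
        _check_keys(p, _SCHEMA["particles"], f"particles[{k}]")
        if "radius_um" not in p:
            raise ConfigurationError(f"particles[{k}] needs radius_um")
        if ("density_kg_per_m3" in p) == ("mass_kg" in p):
            raise ConfigurationError(
                f"particles[{k}] needs exactly one of density_kg_per_m3 or mass_kg"
            )
    for k, f in enumerate(doc.get("forces", []) or []):
        _check_keys(f, _SCHEMA["forces"], f"forces[{k}]")
        if f.get("type") not in {"gaussian_trap", "dep", "gravity"}:
            raise ConfigurationError(f"forces[{k}] has unknown type {f.get('type')!r}")
        if f.get("type") == "dep":
            _check_keys(f.get("field", {}), _SCHEMA["field"], f"forces[{k}].field")
    if "flow" in doc and doc["flow"] is not None:
        _check_keys(doc["flow"], _SCHEMA["flow"], "flow")
        if doc["flow"].get("type") not in {"none", "uniform", "sorter"}:
            raise ConfigurationError(f"flow has unknown type {doc['flow'].get('type')!r}")
    if "geometry" in doc and doc["geometry"] is not None:
        _check_keys(doc["geometry"], _SCHEMA["geometry"], "geometry")
        if doc["geometry"].get("type") not in {"none", "trap", "sorter"}:
            raise ConfigurationError(f"geometry has unknown type {doc['geometry'].get('type')!r}")
    if "output" in doc and doc["output"] is not None:
        _check_keys(doc["output"], _SCHEMA["output"], "output")
    return doc


def load_config(path) -> dict:
    """Read and validate a YAML/JSON configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return validate_config(doc)


def write_config(doc: dict, path) -> None:
    validate_config(doc)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _build_particles(doc: dict, yeast=None) -> list[ParticleState]:
    out = []
    pid = 0
    for p in doc["particles"]:
        count = int(p.get("count", 1))
        ro = p["radius_um"] * _UM
        for _ in range(count):
            mass = p["mass_kg"] if "mass_kg" in p else mass_from_density(ro, p["density_kg_per_m3"])
            dielectric = None
            if "re_cm" in p:
                dielectric = float(p["re_cm"])
            elif "cell" in p:
                if yeast is None:
                    yeast = load_yeast_cells()
                if p["cell"] not in ("viable", "nonviable"):
                    raise ConfigurationError(f"unknown cell type {p['cell']!r}")
                dielectric = yeast[p["cell"]]
            out.append(
                ParticleState(
                    id=pid,
                    ro=ro,
                    m=mass,
                    r=np.asarray(p.get("position_um", (0, 0, 0)), dtype=float) * _UM,
                    v=np.asarray(p.get("velocity_um_s", (0, 0, 0)), dtype=float) * _UM,
                    dielectric=dielectric,
                )
            )
            pid += 1
    return out


def build_simulation(doc: dict, *, seed: int | None = None) -> SimulationConfig:
    """Turn a validated configuration document into a runnable
    :class:`SimulationConfig` (SI units throughout)."""
    validate_config(doc)
    med = doc["medium"]
    medium = Medium(
        eta=med["eta_Pa_s"],
        T=med["T_K"],
        eps_m=med.get("eps_m", 80.0),
        sigma_m=med.get("sigma_S_per_m", 0.0),
        rho_f=med.get("rho_kg_per_m3"),
    )
    particles = _build_particles(doc)

    forces = []
    dep_frequency = None
    for f in doc.get("forces", []) or []:
        if f["type"] == "gaussian_trap":
            ad_si = f["ad_kBT_per_um3"] * KB * medium.T / _UM**3
            trap = GaussianTrap(
                ad=ad_si,
                w=f["width_um"] * _UM,
                center=np.asarray(f.get("center_um", (0, 0, 0)), dtype=float) * _UM,
            )
            if "t_on_s" in f or "t_off_s" in f:
                trap = TimeGated(trap, f.get("t_on_s", -np.inf), f.get("t_off_s", np.inf))
            forces.append(trap)
        elif f["type"] == "dep":
            dep_frequency = float(f["frequency_Hz"])
            fld = f.get("field", {"type": "surrogate"})
            if fld.get("type") == "grid":
                field = read_e2_grid(fld["path"])
            elif fld.get("type") == "surrogate":
                field = sorter_surrogate_field(
                    e2_peak=float(fld.get("e2_peak_V2_per_m2", 3.0e9))
                )
            else:
                raise ConfigurationError(f"unknown DEP field type {fld.get('type')!r}")
            forces.append(DEPForce(field, medium, dep_frequency))
        elif f["type"] == "gravity":
            forces.append(GravityBuoyancy(medium))

    flow = None
    fdoc = doc.get("flow")
    if fdoc and fdoc.get("type") == "uniform":
        flow = UniformFlow(np.asarray(fdoc["velocity_um_s"], dtype=float) * _UM)
    elif fdoc and fdoc.get("type") == "sorter":
        flow = SorterFlow()
        kw = fdoc.get("kernel_width_um", 0.0) * _UM
        if kw > 0:
            flow = smooth_flow(
                flow, kw, bounds=((-600e-6, 1500e-6), (-400e-6, 400e-6), (0.0, 100e-6))
            )

    walls = None
    gdoc = doc.get("geometry")
    if gdoc and gdoc.get("type") == "trap":
        walls = build_trap_geometry()
    elif gdoc and gdoc.get("type") == "sorter":
        walls, _ = build_sorter_geometry(
            full_height_walls=bool(gdoc.get("full_height_walls", True))
        )

    init_box = None
    if doc.get("init_box_um") is not None:
        init_box = tuple((lo * _UM, hi * _UM) for lo, hi in doc["init_box_um"])

    return SimulationConfig(
        dt=doc["time"]["dt_s"],
        t_end=doc["time"]["t_end_s"],
        seed=int(seed if seed is not None else doc.get("seed", 0)),
        particles=particles,
        medium=medium,
        forces=forces,
        flow=flow,
        walls=walls,
        init_box=init_box,
        log_every=(doc.get("output") or {}).get("log_every"),
        dep_frequency=dep_frequency,
    )
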