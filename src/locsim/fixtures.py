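"""Ready-made experiment configurations for the two reference devices.

``fixture_optical_trap`` — four polystyrene beads above a solid floor with
a time-gated Gaussian optical trap (beam ON for 1 s < t < 8 s), 12 s at
dt = 10 ms.

``fixture_dep_sorter`` — the tapered-electrode DEP cell sorter: 17 viable
plus 17 non-viable yeast cells (3 um radius) injected upstream, carried by
a 150 um/s piecewise flow through a 4 V, 5 MHz electrode array and sorted
into three outlet channels; 6 s at dt = 5 ms.  The |E|^2 distribution
comes either from an imported solver grid or from the bundled analytic
surrogate.
"""

from __future__ import annotations

from .dielectrics import load_yeast_cells

__all__ = ["fixture_optical_trap", "fixture_dep_sorter"]


def fixture_optical_trap(*, seed: int = 0) -> dict:
    """Configuration document for the optical-trap experiment."""
    return {
        "seed": seed,
        "time": {"dt_s": 0.01, "t_end_s": 12.0},
        "medium": {"eta_Pa_s": 8.9e-4, "T_K": 300.0, "rho_kg_per_m3": 1000.0},
        "particles": [
            {"radius_um": ro, "density_kg_per_m3": 1055.0} for ro in (1.5, 2.5, 2.0, 2.0)
        ],
        # injected within the capture range of the trap (well width 10 um)
        "init_box_um": [[-10.0, 10.0], [-10.0, 10.0], [3.0, 20.0]],
        "forces": [
            {
                "type": "gaussian_trap",
                "ad_kBT_per_um3": 120.0,
                "width_um": 10.0,
                "center_um": [0.0, 0.0, 0.0],
                "t_on_s": 1.0,
                "t_off_s": 8.0,
            }
        ],
        "geometry": {"type": "trap"},
        "flow": {"type": "none"},
    }


def fixture_dep_sorter(
    *,
    seed: int = 0,
    field_grid: str | None = None,
    e2_peak: float = 3.0e9,
    n_viable: int = 17,
    n_nonviable: int = 17,
    init_box_um=((-480.0, -200.0), (-280.0, 280.0), (6.0, 80.0)),
) -> dict:
    """Configuration document for the DEP cell-sorter experiment.

    With ``field_grid`` the |E|^2 values come from the documented text grid
    format (e.g. exported from an electrostatics solver for the 4 V, 5 MHz
    drive); otherwise the analytic surrogate with ridge-top intensity
    ``e2_peak`` (V^2/m^2) stands in.
    """
    yeast = load_yeast_cells()
    field = (
        {"type": "grid", "path": field_grid}
        if field_grid
        else {"type": "surrogate", "e2_peak_V2_per_m2": e2_peak}
    )
    return {
        "seed": seed,
        "time": {"dt_s": 0.005, "t_end_s": 6.0},
        "medium": {
            "eta_Pa_s": 8.9e-4,
            "T_K": 300.0,
            "eps_m": yeast["medium"]["eps_m"],
            "sigma_S_per_m": yeast["medium"]["sigma_S_per_m"],
            "rho_kg_per_m3": 1000.0,
        },
        "particles": [
            {"radius_um": 3.0, "density_kg_per_m3": 1100.0, "cell": "viable", "count": n_viable},
            {
                "radius_um": 3.0,
                "density_kg_per_m3": 1100.0,
                "cell": "nonviable",
                "count": n_nonviable,
            },
        ],
        "init_box_um": [list(b) for b in init_box_um],
        "forces": [{"type": "dep", "frequency_Hz": yeast["frequency_Hz"], "field": field}],
        "flow": {"type": "sorter", "kernel_width_um": 0.0},
        "geometry": {"type": "sorter"},
    }
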