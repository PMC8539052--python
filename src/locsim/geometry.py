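"""Wall geometry: planes, thin wall segments, and device builders.

Walls come in two flavours:

* :class:`PlaneWall` — an infinite plane given by a point and the inward
  (fluid-side) unit normal; the signed distance is positive on the fluid
  side.
* :class:`SegmentWall` — a thin vertical baffle: a 2D segment in the xy
  plane extruded from z = 0 up to ``height``.  It is two-sided (fluid on
  both sides); the returned normal points from the wall toward the query
  point, so a reflection always pushes the particle away from the wall.

Builders assemble the two devices simulated in the package: the optical
trap (a bare floor) and the tapered-electrode DEP cell sorter (floor,
funnel-shaped inlet walls, and slanted outlet-channel dividers, with the
electrode footprints recorded as metadata for visualization and the
analytic field surrogate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "PlaneWall",
    "SegmentWall",
    "WallSet",
    "build_trap_geometry",
    "build_sorter_geometry",
    "SORTER",
]

_FAR = np.inf


@dataclass(frozen=True)
class PlaneWall:
    """Infinite plane: signed distance = (r - point) . normal."""

    point: tuple
    normal: tuple
    name: str = "plane"

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise DomainError(f"wall normal must be unit length, got {n}")

    def signed_distance(self, r):
        r = np.asarray(r, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        p = np.asarray(self.point, dtype=float)
        return float(np.dot(r - p, n)), n


@dataclass(frozen=True)
class SegmentWall:
    """Thin vertical wall over a 2D segment, blocking for z below ``height``.

    With ``full_height=True`` (default) the wall blocks at every z, which
    keeps particles injected above the physical wall height from crossing
    wall footprints; set it to False to cap blocking at ``height``.
    """

    a: tuple
    b: tuple
    height: float
    name: str = "segment"
    full_height: bool = True

    def signed_distance(self, r):
        r = np.asarray(r, dtype=float)
        if not self.full_height and r[2] > self.height:
            return _FAR, np.array([0.0, 0.0, 1.0])
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        ab = b - a
        tt = np.clip(np.dot(r[:2] - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        closest = a + tt * ab
        d = r[:2] - closest
        dist = float(np.linalg.norm(d))
        if dist == 0.0:
            # on the wall line: push along the in-plane normal of the segment
            n2 = np.array([-ab[1], ab[0]]) / np.linalg.norm(ab)
        else:
            n2 = d / dist
        return dist, np.array([n2[0], n2[1], 0.0])


@dataclass
class WallSet:
    """Ordered collection of walls, iterable in wall-id order."""

    walls: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.walls)

    def __len__(self):
        return len(self.walls)

    def __getitem__(self, i):
        return self.walls[i]


def build_trap_geometry() -> WallSet:
    """Optical-trap geometry: a single solid floor at z = 0."""
    return WallSet([PlaneWall((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), name="floor")])


#: Device constants of the tapered-electrode sorter (SI metres).
SORTER = {
    "electrode_length": 350e-6,  # along x
    "electrode_gap": 16e-6,
    "outer_electrode_width": 20e-6,  # top and bottom electrodes, along y
    "middle_electrode_width": (46e-6, 70e-6),  # linear taper over the length
    "wall_height": 50e-6,
    "flow_speed": 150e-6,
    "outlet_y_split": 30e-6,
    "outlet_x_split": 170e-6,
    "outlet_slope": 30.0 / 150.0,  # tangent of the slanted outlet channels
}


def _electrode_polygons():
    """Electrode footprints (xy polygons, metres) for metadata/surrogate."""
    L = SORTER["electrode_length"]
    x0, x1 = -L / 2, L / 2
    w0, w1 = SORTER["middle_electrode_width"]
    gap = SORTER["electrode_gap"]
    wo = SORTER["outer_electrode_width"]
    middle = [(x0, -w0 / 2), (x1, -w1 / 2), (x1, w1 / 2), (x0, w0 / 2)]
    top = [
        (x0, w0 / 2 + gap),
        (x1, w1 / 2 + gap),
        (x1, w1 / 2 + gap + wo),
        (x0, w0 / 2 + gap + wo),
    ]
    bottom = [(x, -y) for x, y in top]
    return {"middle": middle, "top": top, "bottom": bottom}


def build_sorter_geometry(
    *,
    inlet_half_width: float = 290e-6,
    channel_half_width: float = 50e-6,
    funnel_x=(-200e-6, -20e-6),
    outlet_x_end: float = 1500e-6,
    full_height_walls: bool = True,
):
    """Sorter wall set plus electrode-layout metadata.

    One wide inlet chamber funnels into a straight channel over the
    electrode array; past ``x = 170 um`` the channel splits into a centre
    outlet (|y| < 30 um) and two slanted outlets whose dividers and outer
    walls rise with slope 30/150, tangential to the outlet flow.  All
    channel walls are ``wall_height`` (50 um) high.
    """
    h = SORTER["wall_height"]
    ys = SORTER["outlet_y_split"]
    xs = SORTER["outlet_x_split"]
    m = SORTER["outlet_slope"]
    y_out = channel_half_width + m * (outlet_x_end - xs)
    walls = [PlaneWall((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), name="floor")]
    for s, tag in ((1.0, "top"), (-1.0, "bottom")):
        walls += [
            # inlet chamber outer wall, then funnel into the channel
            SegmentWall((-1000e-6, s * inlet_half_width), (funnel_x[0], s * inlet_half_width),
                        h, name=f"inlet-{tag}", full_height=full_height_walls),
            SegmentWall((funnel_x[0], s * inlet_half_width), (funnel_x[1], s * channel_half_width),
                        h, name=f"funnel-{tag}", full_height=full_height_walls),
            # straight channel wall over the electrode region
            SegmentWall((funnel_x[1], s * channel_half_width), (xs, s * channel_half_width),
                        h, name=f"channel-{tag}", full_height=full_height_walls),
            # slanted outer wall of the side outlet channel
            SegmentWall((xs, s * channel_half_width), (outlet_x_end, s * y_out),
                        h, name=f"outlet-outer-{tag}", full_height=full_height_walls),
            # divider between the centre channel and the side channel
            SegmentWall((xs, s * ys), (outlet_x_end, s * (ys + m * (outlet_x_end - xs))),
                        h, name=f"outlet-divider-{tag}", full_height=full_height_walls),
        ]
    return WallSet(walls), {"electrodes": _electrode_polygons(), **SORTER}
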