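"""Parameterized 2D catheter-tip geometry and its rasterization.

The toy domain is a planar analog of a catheter inserted along a vein:
a rectangular vessel channel (x axial, y transverse) with the catheter
running along the top boundary.  The catheter lumen is the open band just
under the top wall; a solid wall of finite thickness separates it from the
vessel, closed at the distal end by an end cap.  Blood enters the lumen
through the tip opening (a gap in the wall adjacent to the cap) and through
zero, one or two side-holes cut further proximally.  Side-holes are either
``straight_cut`` (drilled, square edges) or ``angled_cut`` (skived, edges
chamfered so the opening widens toward the vessel side).

::

    y=W  ───────────────────────────────┐ (top boundary = outer lumen wall)
          lumen → → (outflow at x=0)  ██│ cap
    y_w1  ██████████──────██████──────██│
          wall      hole   tip opening  │
    y_w0
          vessel  → → → → (inlet 0.3 m/s at x=0, outlet p=0 at x=L)
    y=0  ───────────────────────────────┘

Rasterization produces a cell-centered fluid/solid mask on a uniform grid
together with labeled boundary cells and the face segments of every
opening, which the finite-volume solver and the flux metrics consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = ["SideHole", "TipGeometry2D", "RasterizedGeometry", "rasterize_geometry"]

HOLE_PROFILES = ("straight_cut", "angled_cut")
ARRANGEMENTS = ("single", "dual_linear")


@dataclass(frozen=True)
class SideHole:
    """One side-hole in the catheter wall.

    ``length`` is the opening length measured on the lumen (inner) surface;
    ``distance_to_tip`` is from the hole's distal edge to the distal end of
    the catheter (held constant across compared designs).  For
    ``angled_cut`` the wall edges are chamfered at ``chamfer_angle_deg``
    from the wall plane, so the outer opening is longer by
    ``2 * wall_thickness / tan(angle)``.
    """

    profile: str
    length: float
    distance_to_tip: float
    chamfer_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.profile not in HOLE_PROFILES:
            raise ValueError(f"profile must be one of {HOLE_PROFILES}, got {self.profile!r}")
        if self.length <= 0 or self.distance_to_tip <= 0:
            raise ValueError("hole length and distance_to_tip must be positive")
        if not 0.0 < self.chamfer_angle_deg <= 90.0:
            raise ValueError("chamfer angle must lie in (0, 90] degrees")

    def chamfer_run(self, wall_thickness: float) -> float:
        """Horizontal extent of the chamfer at the outer surface (m)."""
        if self.profile == "straight_cut":
            return 0.0
        return wall_thickness / math.tan(math.radians(self.chamfer_angle_deg))


@dataclass(frozen=True)
class TipGeometry2D:
    """Planar toy catheter-tip layout (all lengths in metres).

    Defaults give a desk-scale analog of a symmetric-tip hemodialysis
    catheter in the superior vena cava: a 20 mm wide vessel, a 3 mm slot
    lumen (the height of one semicircular lumen of the 5 mm-bore catheter),
    2 mm wall, 5 mm tip opening and the 16.5 mm hole-to-tip distance used
    when side-holes are present.
    """

    vessel_width: float = 0.020
    vessel_length: float = 0.050
    wall_thickness: float = 0.002
    lumen_height: float = 0.003
    insertion_length: float = 0.030
    tip_opening_length: float = 0.005
    side_holes: tuple[SideHole, ...] = ()
    arrangement: str = "single"

    def __post_init__(self) -> None:
        object.__setattr__(self, "side_holes", tuple(self.side_holes))
        for name in (
            "vessel_width", "vessel_length", "wall_thickness",
            "lumen_height", "insertion_length", "tip_opening_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"arrangement must be one of {ARRANGEMENTS}")
        if self.arrangement == "single" and len(self.side_holes) > 1:
            raise ValueError("'single' arrangement admits at most one side-hole")
        if self.arrangement == "dual_linear" and len(self.side_holes) != 2:
            raise ValueError("'dual_linear' arrangement requires exactly two side-holes")
        if self.lumen_height + self.wall_thickness >= self.vessel_width:
            raise ValueError("catheter body does not fit inside the vessel width")
        if self.insertion_length >= self.vessel_length:
            raise ValueError("insertion length must be shorter than the vessel")
        if self.wall_thickness + self.tip_opening_length >= self.insertion_length:
            raise ValueError("tip opening does not fit on the inserted length")
        spans = []
        for hole in self.side_holes:
            x_d, x_a = self.hole_inner_span(hole)
            run = hole.chamfer_run(self.wall_thickness)
            if x_d > self.insertion_length - self.wall_thickness - self.tip_opening_length:
                raise ValueError(
                    f"side-hole at distance {hole.distance_to_tip} overlaps the tip opening"
                )
            if x_a - run <= 0.0:
                raise ValueError("side-hole extends past the catheter base (x=0)")
            spans.append((x_a - run, x_d + run))
        spans.sort()
        for (a0, d0), (a1, d1) in zip(spans, spans[1:]):
            if d0 > a1:
                raise ValueError("side-hole openings overlap")

    # -- derived locations -------------------------------------------------

    @property
    def lumen_bottom(self) -> float:
        """y of the lumen's inner (lower) wall surface."""
        return self.vessel_width - self.lumen_height

    @property
    def wall_bottom(self) -> float:
        """y of the wall's outer surface facing the vessel."""
        return self.lumen_bottom - self.wall_thickness

    @property
    def tip_opening_span(self) -> tuple[float, float]:
        hi = self.insertion_length - self.wall_thickness
        return (hi - self.tip_opening_length, hi)

    def hole_inner_span(self, hole: SideHole) -> tuple[float, float]:
        """(distal edge x, proximal edge x) on the lumen surface — returned
        as (x_d, x_a) with x_a < x_d."""
        x_d = self.insertion_length - hole.distance_to_tip
        return x_d, x_d - hole.length

    def thinnest_fluid_feature(self) -> tuple[str, float]:
        feats = [("lumen_height", self.lumen_height),
                 ("tip_opening_length", self.tip_opening_length)]
        feats += [(f"side_hole[{k}].length", h.length) for k, h in enumerate(self.side_holes)]
        return min(feats, key=lambda kv: kv[1])


@dataclass
class RasterizedGeometry:
    """Cell-centered rasterization of a :class:`TipGeometry2D`.

    ``fluid`` has shape (nx, ny) with x index first; cell (i, j) spans
    ``[i*h, (i+1)*h] x [j*h, (j+1)*h]``.  ``inlet_cells``, ``lumen_outlet_cells``
    and ``vessel_outlet_cells`` hold j indices of boundary cells.  Opening
    segments are (j_face, i_indices) pairs addressing horizontal (v) faces
    on the lumen surface row where fluxes are integrated.
    """

    geometry: TipGeometry2D
    spacing: float
    fluid: np.ndarray
    inlet_cells: np.ndarray
    lumen_outlet_cells: np.ndarray
    vessel_outlet_cells: np.ndarray
    mouth_j_face: int
    hole_segments: list[np.ndarray]
    tip_opening_segment: np.ndarray
    achieved_hole_lengths: list[float] = dc_field(default_factory=list)
    achieved_tip_opening_length: float = 0.0

    @property
    def nx(self) -> int:
        return self.fluid.shape[0]

    @property
    def ny(self) -> int:
        return self.fluid.shape[1]


def rasterize_geometry(geom: TipGeometry2D, spacing: float) -> RasterizedGeometry:
    """Rasterize the geometry onto a uniform grid of cell size ``spacing``.

    Deterministic: a cell is solid iff its center lies inside catheter
    material.  Chamfered (``angled_cut``) edges come out stair-stepped with
    the requested slope to within one cell.  Every fluid opening (lumen
    height, tip opening, hole lengths) must be resolved by at least three
    cells and the wall by at least one, otherwise the geometry is rejected
    naming the offending feature.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    h = float(spacing)
    name, size = geom.thinnest_fluid_feature()
    if size / h < 3.0 - 1e-9:
        raise ValueError(
            f"under-resolved feature {name} ({size:g} m needs >= 3 cells, "
            f"got {size / h:.2f} at spacing {h:g})"
        )
    if geom.wall_thickness / h < 1.0 - 1e-9:
        raise ValueError(
            f"under-resolved feature wall_thickness ({geom.wall_thickness:g} m "
            f"needs >= 1 cell at spacing {h:g})"
        )
    nx = int(round(geom.vessel_length / h))
    ny = int(round(geom.vessel_width / h))
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h

    y_w0, y_w1 = geom.wall_bottom, geom.lumen_bottom
    wall_rows = (yc > y_w0) & (yc < y_w1)
    cap_rows = yc > y_w0
    tip_lo, tip_hi = geom.tip_opening_span

    solid = np.zeros((nx, ny), dtype=bool)
    # catheter bottom wall along the inserted length, minus the tip opening
    wall_cols = xc < tip_lo
    solid[np.ix_(wall_cols, wall_rows)] = True
    # distal end cap (full catheter height)
    cap_cols = (xc > tip_hi) & (xc < geom.insertion_length)
    solid[np.ix_(cap_cols, cap_rows)] = True

    # carve the side-holes (chamfer widens the opening toward the vessel)
    for hole in geom.side_holes:
        x_d, x_a = geom.hole_inner_span(hole)
        if hole.profile == "straight_cut":
            open_2d = (xc[:, None] > x_a) & (xc[:, None] < x_d)
        else:
            tan = math.tan(math.radians(hole.chamfer_angle_deg))
            reach = (y_w1 - yc[None, :]) / tan  # widening at depth below lumen surface
            open_2d = (xc[:, None] > x_a - reach) & (xc[:, None] < x_d + reach)
        carve = open_2d & wall_rows[None, :]
        solid &= ~carve

    fluid = ~solid

    j_all = np.arange(ny)
    inlet_cells = j_all[(yc < y_w0) & fluid[0]]
    lumen_outlet_cells = j_all[(yc > y_w1) & fluid[0]]
    vessel_outlet_cells = j_all[fluid[-1]]
    if inlet_cells.size == 0 or lumen_outlet_cells.size == 0:
        raise ValueError("rasterization produced no inlet or lumen-outlet cells")

    # flux-integration segments on the lumen-surface face row
    j_mouth = int(round(y_w1 / h))
    i_all = np.arange(nx)

    def open_faces(lo: float, hi: float) -> np.ndarray:
        cols = i_all[(xc > lo) & (xc < hi)]
        ok = fluid[cols, j_mouth - 1] & fluid[cols, j_mouth]
        return cols[ok]

    hole_segments = [open_faces(*geom.hole_inner_span(hole)[::-1]) for hole in geom.side_holes]
    tip_segment = open_faces(tip_lo, tip_hi)

    return RasterizedGeometry(
        geometry=geom,
        spacing=h,
        fluid=fluid,
        inlet_cells=inlet_cells,
        lumen_outlet_cells=lumen_outlet_cells,
        vessel_outlet_cells=vessel_outlet_cells,
        mouth_j_face=j_mouth,
        hole_segments=hole_segments,
        tip_opening_segment=tip_segment,
        achieved_hole_lengths=[seg.size * h for seg in hole_segments],
        achieved_tip_opening_length=tip_segment.size * h,
    )
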