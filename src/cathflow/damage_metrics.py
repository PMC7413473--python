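"""Design-scoring layer: platelet lysis index, shear statistics, tip-volume
metrics and opening flow rates.

The platelet lysis index (PLI) is the power-law blood-damage dose

    PLI = A · t^0.77 · τ^3.075,      A = 3.31e-6,

accumulated along a path line step by step: each recorded step contributes
``A dt^0.77 τ^3.075`` with its own duration and local scalar shear stress,
the per-line contributions are summed, and an ensemble score is the mean of
the per-line sums.  Because ``dt^0.77`` is sub-additive the per-line sum
depends on the recording step; the 0.5 μm default spatial step is therefore
part of the model definition, not a numerical knob.

Eulerian "tip volume" statistics mirror the per-design comparison columns:
maximum speed, volume-averaged scalar shear stress, and the percentage of
the region above a 10 Pa threshold (a commonly used platelet-activation
level), evaluated over a fixed rectangular region at the inflow lumen so
competing designs are compared over identical territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import StructuredField
from .geometry import TipGeometry2D
from .rheology import CarreauParameters, carreau_viscosity
from .solver import ML_MIN_PER_M3_S, SolveResult
from .tracking import PathLine

__all__ = [
    "PLIParameters",
    "TipVolumeSpec",
    "DamageReport",
    "step_pli",
    "pathline_pli",
    "ensemble_pli",
    "residence_time",
    "platelet_shear_stats",
    "tip_volume_stats",
    "hole_flow_rate",
    "hole_flow_rates",
    "shear_stress_nodes",
]


@dataclass(frozen=True)
class PLIParameters:
    """Constants of the power-law platelet lysis index."""

    prefactor: float = 3.31e-6
    time_exponent: float = 0.77
    stress_exponent: float = 3.075

    def __post_init__(self) -> None:
        if min(self.prefactor, self.time_exponent, self.stress_exponent) <= 0:
            raise ValueError("PLI parameters must be positive")


@dataclass(frozen=True)
class TipVolumeSpec:
    """Fixed comparison region at the inflow lumen (2D analog of a cuboid).

    The region extends ``axial_extent`` proximally from the distal catheter
    tip and spans ``transverse_extent`` upward from the lumen's inner
    surface; defaults cover the lumen over the side-hole and tip opening.
    ``bounds`` may override the placement explicitly as (x0, x1, y0, y1).
    """

    axial_extent: float = 0.024
    transverse_extent: float = 0.003
    threshold: float = 10.0
    bounds: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.axial_extent, self.transverse_extent) <= 0:
            raise ValueError("tip-volume extents must be positive")
        if self.threshold <= 0:
            raise ValueError("shear-stress threshold must be positive")

    def resolve_bounds(self, geometry: TipGeometry2D | None = None):
        if self.bounds is not None:
            return self.bounds
        if geometry is None:
            raise ValueError("explicit bounds or a geometry are required")
        x1 = geometry.insertion_length
        y0 = geometry.lumen_bottom
        return (x1 - self.axial_extent, x1, y0, y0 + self.transverse_extent)


@dataclass
class DamageReport:
    """Per-design metrics: Eulerian tip-volume columns plus the platelet
    (Lagrangian) columns.  Platelet entries are NaN for designs without
    side-holes (nothing to seed over)."""

    design: str
    max_speed: float
    avg_shear_stress: float
    pct_stress_above: float
    side_hole_flows_ml_min: list[float]
    tip_opening_flow_ml_min: float
    lumen_outflow_ml_min: float
    mean_residence_time: float = float("nan")
    pli: float = float("nan")
    platelet_avg_stress: float = float("nan")
    platelet_pct_above: float = float("nan")
    platelet_avg_shear_rate: float = float("nan")
    termination_counts: dict = dc_field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "design": self.design,
            "max_velocity_m_s": self.max_speed,
            "avg_shear_stress_pa": self.avg_shear_stress,
            "pct_shear_stress_above_threshold": self.pct_stress_above,
            "side_hole_flow_ml_min": sum(self.side_hole_flows_ml_min)
            if self.side_hole_flows_ml_min else float("nan"),
            "tip_opening_flow_ml_min": self.tip_opening_flow_ml_min,
            "lumen_outflow_ml_min": self.lumen_outflow_ml_min,
            "avg_residence_time_s": self.mean_residence_time,
            "pli": self.pli,
            "platelet_avg_shear_stress_pa": self.platelet_avg_stress,
            "platelet_pct_shear_stress_above_threshold": self.platelet_pct_above,
            "platelet_avg_shear_rate_s": self.platelet_avg_shear_rate,
        }


# ---------------------------------------------------------------------------
# PLI
# ---------------------------------------------------------------------------


def step_pli(params: PLIParameters, dt: float, tau: float) -> float:
    """PLI dose of one step: ``A · dt^a · τ^b`` (dimensionless)."""
    if dt < 0 or tau < 0:
        raise ValueError("step duration and stress must be non-negative")
    if dt == 0.0 or tau == 0.0:
        return 0.0
    return params.prefactor * dt**params.time_exponent * tau**params.stress_exponent


def pathline_pli(params: PLIParameters, line: PathLine) -> float:
    """Sum of per-step PLI doses along one path line."""
    if len(line) < 1:
        raise ValueError("path line has no records")
    dt = line.dt
    tau = line.tau
    live = dt > 0.0
    return float(
        params.prefactor
        * np.sum(dt[live] ** params.time_exponent * tau[live] ** params.stress_exponent)
    )


def ensemble_pli(
    params: PLIParameters, lines: list[PathLine], mode: str = "per_line"
) -> float:
    """Overall PLI magnitude of an ensemble of path lines.

    ``per_line`` (default): arithmetic mean over lines of the per-line sums
    — no velocity weighting.  ``per_step``: grand sum of step doses divided
    by the grand step count, the alternative reading of averaging over all
    steps.
    """
    if not lines:
        raise ValueError("empty ensemble")
    if mode == "per_line":
        return float(np.mean([pathline_pli(params, ln) for ln in lines]))
    if mode == "per_step":
        total = sum(pathline_pli(params, ln) for ln in lines)
        steps = sum(int(np.count_nonzero(ln.dt > 0.0)) for ln in lines)
        return total / max(steps, 1)
    raise ValueError(f"unknown ensemble mode {mode!r}")


def residence_time(line: PathLine) -> float:
    """Total tracked time: sum of step durations == last time − first time."""
    return line.residence_time


def platelet_shear_stats(
    lines: list[PathLine], threshold: float = 10.0, weighting: str = "time"
) -> tuple[float, float, float]:
    """(mean τ, % exposure with τ > threshold, mean γ̇) over all steps of
    all lines.

    ``time`` weighting (default) weights each step by its duration — the
    fraction of *exposure time* above threshold; ``step`` weights steps
    equally (near-uniform spatial steps make this a path-length weighting).
    """
    if not lines:
        raise ValueError("empty ensemble")
    tau = np.concatenate([ln.tau for ln in lines])
    gdot = np.concatenate([ln.gamma_dot for ln in lines])
    dt = np.concatenate([ln.dt for ln in lines])
    if weighting == "time":
        w = dt
    elif weighting == "step":
        w = (dt > 0.0).astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    wsum = w.sum()
    if wsum == 0.0:
        return 0.0, 0.0, 0.0
    mean_tau = float((w * tau).sum() / wsum)
    mean_gdot = float((w * gdot).sum() / wsum)
    pct = float(w[tau > threshold].sum() / wsum * 100.0)
    return mean_tau, pct, mean_gdot


# ---------------------------------------------------------------------------
# Eulerian tip-volume statistics
# ---------------------------------------------------------------------------


def shear_stress_nodes(field: StructuredField, rheo: CarreauParameters):
    """Node arrays (γ̇, τ) of a 2D field from its node-gradient tensors."""
    if field._gradients is None:
        field._gradients = field._node_gradients()
    g = field._gradients
    d = 0.5 * (g + np.swapaxes(g, -1, -2))
    gdot = np.sqrt(2.0 * np.sum(d * d, axis=(-1, -2)))
    mu = carreau_viscosity(rheo, gdot)
    return gdot, mu * gdot


def tip_volume_stats(
    field: StructuredField,
    spec: TipVolumeSpec,
    rheo: CarreauParameters,
    geometry: TipGeometry2D | None = None,
) -> tuple[float, float, float]:
    """(max speed, mean τ, % of region with τ > threshold) over the fluid
    part of the tip region.

    Node-sampled on the field grid: the mean is the discrete volume average
    over fluid nodes, the percentage the fluid-node fraction above
    threshold.  Raises if the region contains no fluid.
    """
    x0, x1, y0, y1 = spec.resolve_bounds(geometry)
    X, Y = np.meshgrid(field.x, field.y, indexing="ij")
    region = (
        (X >= x0 - 1e-12) & (X <= x1 + 1e-12)
        & (Y >= y0 - 1e-12) & (Y <= y1 + 1e-12)
        & field.mask[:, :, 0]
    )
    if not region.any():
        raise ValueError("tip-volume region contains no fluid nodes")
    speed = field.speed()[:, :, 0]
    _, tau = shear_stress_nodes(field, rheo)
    tau = tau[:, :, 0]
    max_speed = float(speed[region].max())
    mean_tau = float(tau[region].mean())
    pct = float(np.count_nonzero(tau[region] > spec.threshold) / region.sum() * 100.0)
    return max_speed, mean_tau, pct


def _region_cell_mask(field: StructuredField, bounds) -> np.ndarray:
    """Grid cells whose four corner nodes are fluid and lie inside bounds."""
    x0, x1, y0, y1 = bounds
    eps = 1e-12
    inx = (field.x >= x0 - eps) & (field.x <= x1 + eps)
    iny = (field.y >= y0 - eps) & (field.y <= y1 + eps)
    node_in = inx[:, None] & iny[None, :] & field.mask[:, :, 0]
    return node_in[:-1, :-1] & node_in[1:, :-1] & node_in[:-1, 1:] & node_in[1:, 1:]


def region_integral_average(field: StructuredField, values: np.ndarray, bounds) -> float:
    """Area-integral average of a node array over the fluid part of a
    rectangular region, by cell-wise trapezoid quadrature.

    Discretization-consistent across grid refinements of the same geometry:
    the quadrature error shrinks with the field's order instead of the O(h)
    drift a plain node-set mean shows as nodes crowd the walls.
    """
    cells = _region_cell_mask(field, bounds)
    if not cells.any():
        raise ValueError("region contains no fluid cells")
    dx = np.diff(field.x)[:, None]
    dy = np.diff(field.y)[None, :]
    corner_mean = 0.25 * (
        values[:-1, :-1] + values[1:, :-1] + values[:-1, 1:] + values[1:, 1:]
    )
    area = (dx * dy * cells).sum()
    return float((corner_mean * dx * dy * cells).sum() / area)


def probe_max_speed(field: StructuredField, bounds, probe_spacing: float = 2.5e-4) -> float:
    """Maximum interpolated speed over a fixed probe lattice spanning the
    region; the lattice is independent of the solution grid so refinement
    changes reflect the field, not the sampling set."""
    x0, x1, y0, y1 = bounds
    nx = max(int(round((x1 - x0) / probe_spacing)), 1) + 1
    ny = max(int(round((y1 - y0) / probe_spacing)), 1) + 1
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    speed = field.speed()[:, :, 0]
    from scipy.interpolate import RegularGridInterpolator

    rgi = RegularGridInterpolator((field.x, field.y), speed, bounds_error=False,
                                  fill_value=0.0)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    return float(rgi(np.stack([X.ravel(), Y.ravel()], axis=-1)).max())


def tip_convergence_metrics(
    field: StructuredField,
    spec: TipVolumeSpec,
    rheo: CarreauParameters,
    geometry: TipGeometry2D | None = None,
    probe_spacing: float = 2.5e-4,
) -> tuple[float, float]:
    """(max tip speed, average tip shear rate) — the two quantities the
    grid-convergence study monitors."""
    bounds = spec.resolve_bounds(geometry)
    gdot, _ = shear_stress_nodes(field, rheo)
    return (
        probe_max_speed(field, bounds, probe_spacing),
        region_integral_average(field, gdot[:, :, 0], bounds),
    )


# ---------------------------------------------------------------------------
# opening flow rates
# ---------------------------------------------------------------------------


def hole_flow_rate(result: SolveResult, face_columns: np.ndarray) -> float:
    """Signed flow through an opening segment on the lumen-surface face row,
    in 2D-equivalent mL/min; positive into the lumen.

    ``face_columns`` are the i indices of open faces (a closed segment —
    empty array — yields exactly zero).
    """
    cols = np.asarray(face_columns, dtype=int)
    if cols.size == 0:
        return 0.0
    j = result.raster.mouth_j_face
    h = result.raster.spacing
    q2d = float(np.sum(result.v[cols, j]) * h)  # +y is into the lumen
    depth = result.raster.geometry.lumen_height
    return q2d * depth * ML_MIN_PER_M3_S


def hole_flow_rates(result: SolveResult) -> list[float]:
    """Flow through each side-hole of a converged solve (mL/min, into the
    lumen positive), ordered as the geometry lists its holes."""
    return [hole_flow_rate(result, seg) for seg in result.raster.hole_segments]


def tip_opening_flow(result: SolveResult) -> float:
    """Flow through the tip opening (mL/min, into the lumen positive)."""
    return hole_flow_rate(result, result.raster.tip_opening_segment)
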