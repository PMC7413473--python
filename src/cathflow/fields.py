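"""Structured flow-field container, interpolation, gradients and VTK I/O.

A :class:`StructuredField` holds a steady velocity field on a node-centered
rectilinear grid together with a fluid/solid mask and an optional viscosity
field.  2D fields are stored with a singleton third dimension so a single
code path serves both dimensionalities.  Coordinates follow the package
convention: x is the axial (vessel/catheter) direction, y transverse, with
the origin at the vessel inlet lower corner.

The module also generates analytic laminar fixtures (uniform, Couette,
planar/tube Poiseuille, stagnation) whose closed-form velocities, gradients
and streamlines make every downstream stage testable without running a
solve, and reads/writes fields as VTK legacy ASCII so they can be inspected
in standard visualisation tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "StructuredField",
    "AnalyticFieldSpec",
    "make_analytic_field",
    "write_field",
    "read_field",
    "VTKParseError",
]

ANALYTIC_KINDS = (
    "uniform",
    "couette",
    "poiseuille_planar",
    "poiseuille_tube",
    "stagnation",
)


def _strictly_increasing(a: np.ndarray) -> bool:
    return a.size == 1 or bool(np.all(np.diff(a) > 0.0))


@dataclass
class StructuredField:
    """Steady velocity (and optional viscosity) field on a rectilinear grid.

    Attributes
    ----------
    x, y, z : ndarray
        Strictly increasing node coordinates (m); ``z`` is a singleton for
        2D fields.
    velocity : ndarray, shape (nx, ny, nz, 3)
        Node velocities (m/s).  Solid nodes carry zero velocity.
    mask : ndarray of bool, shape (nx, ny, nz)
        True on fluid nodes (wall-surface nodes count as fluid with zero
        velocity so interpolation is no-slip consistent).
    viscosity : ndarray or None, shape (nx, ny, nz)
        Optional node viscosities (Pa·s).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    velocity: np.ndarray
    mask: np.ndarray
    viscosity: np.ndarray | None = None
    _gradients: np.ndarray | None = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name, c in (("x", self.x), ("y", self.y), ("z", self.z)):
            if c.ndim != 1 or c.size == 0 or not _strictly_increasing(c):
                raise ValueError(f"{name} coordinates must be 1D strictly increasing")
        shape = (self.x.size, self.y.size, self.z.size)
        if self.velocity.shape != shape + (3,):
            raise ValueError(
                f"velocity shape {self.velocity.shape} != {shape + (3,)}"
            )
        if self.mask.shape != shape:
            raise ValueError(f"mask shape {self.mask.shape} != {shape}")
        if self.viscosity is not None:
            self.viscosity = np.asarray(self.viscosity, dtype=float)
            if self.viscosity.shape != shape:
                raise ValueError(f"viscosity shape {self.viscosity.shape} != {shape}")
        if np.any(self.velocity[~self.mask] != 0.0):
            raise ValueError("solid nodes must carry zero velocity")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity contains non-finite entries")

    # -- geometry helpers --------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.z.size)

    @property
    def is_2d(self) -> bool:
        return self.z.size == 1

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.x[0], self.y[0], self.z[0]])
        hi = np.array([self.x[-1], self.y[-1], self.z[-1]])
        return lo, hi

    def _position3(self, position) -> np.ndarray:
        p = np.asarray(position, dtype=float)
        if p.shape == (2,):
            p = np.array([p[0], p[1], self.z[0]])
        elif p.shape != (3,):
            raise ValueError(f"position must have 2 or 3 components, got {p.shape}")
        return p

    def contains(self, position) -> bool:
        """Whether the position lies inside the grid bounding box."""
        p = self._position3(position)
        lo, hi = self.bounds
        if self.is_2d:
            return bool(np.all(p[:2] >= lo[:2]) and np.all(p[:2] <= hi[:2]))
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def _locate(self, p: np.ndarray):
        """Cell index and trilinear weights along each axis."""
        idx, frac = [], []
        for c, v in ((self.x, p[0]), (self.y, p[1]), (self.z, p[2])):
            if c.size == 1:
                idx.append(0)
                frac.append(0.0)
                continue
            i = int(np.searchsorted(c, v, side="right")) - 1
            i = min(max(i, 0), c.size - 2)
            idx.append(i)
            frac.append((v - c[i]) / (c[i + 1] - c[i]))
        return idx, frac

    def _interp(self, data: np.ndarray, p: np.ndarray):
        (i, j, k), (fx, fy, fz) = self._locate(p)
        di = 1 if self.x.size > 1 else 0
        dj = 1 if self.y.size > 1 else 0
        dk = 1 if self.z.size > 1 else 0
        out = 0.0
        for a, wa in ((0, 1.0 - fx), (di, fx)):
            for b, wb in ((0, 1.0 - fy), (dj, fy)):
                for c, wc in ((0, 1.0 - fz), (dk, fz)):
                    out = out + wa * wb * wc * data[i + a, j + b, k + c]
        # singleton axes contribute (1-f) + f at the same node; halve nothing:
        # weights along a collapsed axis sum to 1 only when f == 0, which
        # _locate guarantees for size-1 axes.
        return out

    # -- sampling ----------------------------------------------------------

    def sample_velocity(self, position) -> np.ndarray | None:
        """Multilinear velocity interpolation at ``position`` (m).

        Returns ``None`` when the position falls outside the grid bounding
        box — an out-of-domain *signal*, not an error, because the particle
        tracker treats it as a legitimate path termination.  Exact at nodes;
        interpolation adjacent to solid nodes blends toward the zero wall
        velocity, consistent with no-slip.
        """
        if not self.contains(position):
            return None
        p = self._position3(position)
        return np.asarray(self._interp(self.velocity, p), dtype=float)

    def velocity_gradient_at(self, position) -> np.ndarray | None:
        """Velocity-gradient tensor ``G[i, j] = du_i/dx_j`` (1/s) at a point.

        Node gradients use central finite differences on the grid (one-sided
        at boundaries, second order for smooth fields) and are multilinearly
        interpolated to the requested position.  Returns ``None`` outside
        the domain.
        """
        if not self.contains(position):
            return None
        if self._gradients is None:
            self._gradients = self._node_gradients()
        p = self._position3(position)
        return np.asarray(self._interp(self._gradients, p), dtype=float)

    def _node_gradients(self) -> np.ndarray:
        g = np.zeros(self.shape + (3, 3))
        axes = ((0, self.x), (1, self.y), (2, self.z))
        for comp in range(3):
            u = self.velocity[..., comp]
            for ax, coord in axes:
                if coord.size > 2:
                    g[..., comp, ax] = np.gradient(u, coord, axis=ax, edge_order=2)
                elif coord.size == 2:
                    g[..., comp, ax] = np.gradient(u, coord, axis=ax)
        return g

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=-1)


@dataclass(frozen=True)
class AnalyticFieldSpec:
    """Closed-form laminar fixture description.

    ``speed`` is the characteristic speed (uniform speed, moving-wall speed
    for Couette, *mean* speed for Poiseuille profiles, strain-rate scale
    times length for stagnation flow); ``length`` the characteristic length
    (gap height, channel height, tube diameter); ``extents`` the (Lx, Ly)
    domain size in metres.
    """

    kind: str
    speed: float
    length: float
    extents: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ANALYTIC_KINDS:
            raise ValueError(
                f"unknown analytic field kind {self.kind!r}; expected one of {ANALYTIC_KINDS}"
            )
        if self.speed <= 0 or self.length <= 0:
            raise ValueError("characteristic speed and length must be positive")
        if len(self.extents) != 2 or min(self.extents) <= 0:
            raise ValueError("extents must be two positive lengths")


def analytic_velocity(spec: AnalyticFieldSpec, x: np.ndarray, y: np.ndarray):
    """Closed-form velocity components (u, v) of a fixture at points x, y."""
    u0, h = spec.speed, spec.length
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.kind == "uniform":
        return u0 * np.ones_like(y), np.zeros_like(y)
    if spec.kind == "couette":
        return u0 * y / h, np.zeros_like(y)
    if spec.kind == "poiseuille_planar":
        # mean speed u0 across gap h: u = 6 u0 (y/h)(1 - y/h), peak 1.5 u0
        eta = y / h
        return 6.0 * u0 * eta * (1.0 - eta), np.zeros_like(y)
    if spec.kind == "poiseuille_tube":
        # axial profile of a tube of diameter h on the diametral plane:
        # u = 2 u0 (1 - (r/R)^2), peak 2 u0 on the centerline y = R
        r_over = (y - 0.5 * h) / (0.5 * h)
        return 2.0 * u0 * (1.0 - r_over**2), np.zeros_like(y)
    if spec.kind == "stagnation":
        k = u0 / h
        return k * x, -k * y
    raise AssertionError(spec.kind)


def analytic_gradient(spec: AnalyticFieldSpec, x: float, y: float) -> np.ndarray:
    """Closed-form velocity gradient du_i/dx_j at a point (2D in 3x3)."""
    u0, h = spec.speed, spec.length
    g = np.zeros((3, 3))
    if spec.kind == "uniform":
        pass
    elif spec.kind == "couette":
        g[0, 1] = u0 / h
    elif spec.kind == "poiseuille_planar":
        g[0, 1] = 6.0 * u0 / h * (1.0 - 2.0 * y / h)
    elif spec.kind == "poiseuille_tube":
        # u = 2 u0 (1 - r^2/R^2), R = h/2  ->  du/dy = -16 u0 (y - h/2) / h^2
        g[0, 1] = -16.0 * u0 * (y - 0.5 * h) / h**2
    elif spec.kind == "stagnation":
        k = u0 / h
        g[0, 0] = k
        g[1, 1] = -k
    return g


def make_analytic_field(
    spec: AnalyticFieldSpec, resolution: tuple[int, int]
) -> StructuredField:
    """Evaluate a fixture's closed form exactly on an (nx, ny) node grid."""
    nx, ny = resolution
    if nx < 2 or ny < 2:
        raise ValueError("resolution must be at least 2x2 nodes")
    x = np.linspace(0.0, spec.extents[0], nx)
    y = np.linspace(0.0, spec.extents[1], ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    u, v = analytic_velocity(spec, xx, yy)
    vel = np.zeros((nx, ny, 1, 3))
    vel[..., 0, 0] = u
    vel[..., 0, 1] = v
    return StructuredField(
        x=x, y=y, z=np.array([0.0]), velocity=vel,
        mask=np.ones((nx, ny, 1), dtype=bool),
    )


# ---------------------------------------------------------------------------
# VTK legacy ASCII I/O
# ---------------------------------------------------------------------------


class VTKParseError(ValueError):
    """Malformed VTK legacy file; the message names the offending line."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def write_field(path, field: StructuredField) -> None:
    """Write a field as a VTK legacy ASCII rectilinear grid.

    Point data carries ``VECTORS velocity``, ``SCALARS mask`` and, when
    present, ``SCALARS viscosity``.  Values are printed with 17 significant
    digits so a read/write round trip reproduces the field to double
    precision.
    """
    nx, ny, nz = field.shape
    npts = nx * ny * nz

    def fmt(vals):
        return " ".join(f"{v:.17g}" for v in vals)

    lines = [
        "# vtk DataFile Version 3.0",
        "cathflow structured field",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"X_COORDINATES {nx} double",
        fmt(field.x),
        f"Y_COORDINATES {ny} double",
        fmt(field.y),
        f"Z_COORDINATES {nz} double",
        fmt(field.z),
        f"POINT_DATA {npts}",
        "VECTORS velocity double",
    ]
    # VTK point order: x varies fastest, then y, then z
    vel = np.transpose(field.velocity, (2, 1, 0, 3)).reshape(npts, 3)
    lines.extend(fmt(row) for row in vel)
    lines.append("SCALARS mask int 1")
    lines.append("LOOKUP_TABLE default")
    mask = np.transpose(field.mask, (2, 1, 0)).reshape(npts)
    lines.extend(str(int(m)) for m in mask)
    if field.viscosity is not None:
        lines.append("SCALARS viscosity double 1")
        lines.append("LOOKUP_TABLE default")
        visc = np.transpose(field.viscosity, (2, 1, 0)).reshape(npts)
        lines.extend(f"{v:.17g}" for v in visc)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class _Cursor:
    def __init__(self, path):
        with open(path) as fh:
            self.lines = fh.read().splitlines()
        self.i = 0

    def next_content(self) -> tuple[int, str]:
        while self.i < len(self.lines):
            line = self.lines[self.i].strip()
            self.i += 1
            if line:
                return self.i, line
        raise VTKParseError(len(self.lines), "unexpected end of file")

    def read_numbers(self, count: int, lineno_hint: int) -> np.ndarray:
        vals: list[float] = []
        last = lineno_hint
        while len(vals) < count:
            last, line = self.next_content()
            try:
                vals.extend(float(t) for t in line.split())
            except ValueError:
                raise VTKParseError(last, f"expected numeric data, got {line!r}") from None
        if len(vals) > count:
            raise VTKParseError(last, f"expected {count} values, got {len(vals)}")
        return np.array(vals)


def read_field(path) -> StructuredField:
    """Read a VTK legacy ASCII rectilinear or structured grid into a field.

    Requires a ``velocity`` point-data vector array; ``mask`` and
    ``viscosity`` are optional (mask defaults to all-fluid).  Raises
    :class:`VTKParseError` naming the offending line on malformed input.
    """
    cur = _Cursor(path)
    ln, line = cur.next_content()
    if not line.startswith("# vtk DataFile"):
        raise VTKParseError(ln, f"not a VTK legacy file header: {line!r}")
    cur.next_content()  # title
    ln, fmt_line = cur.next_content()
    if fmt_line.upper() != "ASCII":
        raise VTKParseError(ln, f"only ASCII format supported, got {fmt_line!r}")
    ln, ds = cur.next_content()
    parts = ds.split()
    if parts[0] != "DATASET" or parts[1] not in ("RECTILINEAR_GRID", "STRUCTURED_GRID"):
        raise VTKParseError(ln, f"unsupported dataset: {ds!r}")
    dataset = parts[1]
    ln, dim_line = cur.next_content()
    toks = dim_line.split()
    if toks[0] != "DIMENSIONS" or len(toks) != 4:
        raise VTKParseError(ln, f"expected DIMENSIONS, got {dim_line!r}")
    nx, ny, nz = (int(t) for t in toks[1:])
    npts = nx * ny * nz

    if dataset == "RECTILINEAR_GRID":
        coords = {}
        for name, n in (("X", nx), ("Y", ny), ("Z", nz)):
            ln, hdr = cur.next_content()
            if not hdr.startswith(f"{name}_COORDINATES"):
                raise VTKParseError(ln, f"expected {name}_COORDINATES, got {hdr!r}")
            declared = int(hdr.split()[1])
            if declared != n:
                raise VTKParseError(ln, f"{name}_COORDINATES count {declared} != dimension {n}")
            coords[name] = cur.read_numbers(n, ln)
        x, y, z = coords["X"], coords["Y"], coords["Z"]
    else:  # STRUCTURED_GRID: explicit points; must form a rectilinear lattice
        ln, hdr = cur.next_content()
        if not hdr.startswith("POINTS"):
            raise VTKParseError(ln, f"expected POINTS, got {hdr!r}")
        pts = cur.read_numbers(3 * npts, ln).reshape(npts, 3)
        lattice = pts.reshape(nz, ny, nx, 3)
        x = lattice[0, 0, :, 0]
        y = lattice[0, :, 0, 1]
        z = lattice[:, 0, 0, 2]
        recon = np.stack(np.meshgrid(z, y, x, indexing="ij"), axis=-1)[..., ::-1]
        if not np.allclose(recon.reshape(npts, 3), pts, atol=1e-12):
            raise VTKParseError(ln, "STRUCTURED_GRID points do not form a rectilinear lattice")

    ln, pd = cur.next_content()
    if not pd.startswith("POINT_DATA"):
        raise VTKParseError(ln, f"expected POINT_DATA, got {pd!r}")
    declared = int(pd.split()[1])
    if declared != npts:
        raise VTKParseError(ln, f"POINT_DATA count {declared} != {npts} grid points")

    velocity = None
    viscosity = None
    mask = None
    while True:
        try:
            ln, hdr = cur.next_content()
        except VTKParseError:
            break
        toks = hdr.split()
        if toks[0] == "VECTORS":
            data = cur.read_numbers(3 * npts, ln).reshape(npts, 3)
            if toks[1] == "velocity":
                velocity = data
        elif toks[0] == "SCALARS":
            ln2, lut = cur.next_content()
            if not lut.startswith("LOOKUP_TABLE"):
                raise VTKParseError(ln2, f"expected LOOKUP_TABLE after SCALARS, got {lut!r}")
            data = cur.read_numbers(npts, ln2)
            if toks[1] == "viscosity":
                viscosity = data
            elif toks[1] == "mask":
                mask = data
        else:
            raise VTKParseError(ln, f"unsupported point-data attribute: {hdr!r}")

    if velocity is None:
        raise VTKParseError(len(cur.lines), 'missing required VECTORS array "velocity"')

    def unflat(a, ncomp=None):
        if ncomp:
            return np.transpose(a.reshape(nz, ny, nx, ncomp), (2, 1, 0, 3))
        return np.transpose(a.reshape(nz, ny, nx), (2, 1, 0))

    return StructuredField(
        x=x, y=y, z=z,
        velocity=unflat(velocity, 3),
        mask=(unflat(mask) > 0.5) if mask is not None else np.ones((nx, ny, nz), bool),
        viscosity=unflat(viscosity) if viscosity is not None else None,
    )
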