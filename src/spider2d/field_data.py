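"""Gridded director/velocity field data: loading, validation, smoothing,
differentiation, masking and nondimensionalization.

Arrays live on a regular (t, y, x) grid, time slowest, x fastest.  Velocity
``u`` and director ``n`` carry a trailing component axis with component 0 = x,
component 1 = y.  The director is a *nematic* field: ``n`` and ``-n`` describe
the same physical state, so every routine that differentiates ``n`` performs a
local sign alignment first.

Index conventions (used consistently across the package, including the
synthetic generators): ``gradu[..., i, j]`` is the derivative along direction
``i`` of component ``j`` of the velocity; the strain rate is
``A = (gradu + gradu^T)/2``, the rotation rate ``Omega = (gradu - gradu^T)/2``
and the scalar vorticity is ``omega = -2 * Omega_xy``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "FieldGrid",
    "FieldSequence",
    "DerivedFields",
    "Mask",
    "MaskConfig",
    "NondimScales",
    "central_diff",
    "align_director",
    "director_diff",
    "mls_smooth",
    "derived_fields",
    "build_mask",
    "nondimensionalize",
    "extract_director",
    "load_fields",
    "save_fields",
]

# Array axis corresponding to each spatial/temporal direction: direction 0 is
# x (array axis 2), direction 1 is y (array axis 1), "t" is array axis 0.
_AXIS_OF_DIR = {0: 2, 1: 1, "t": 0, "x": 2, "y": 1}


@dataclass(frozen=True)
class FieldGrid:
    """Regular (x, y, t) grid metadata.

    ``dx``/``dy``/``dt`` are the (nondimensional or physical) steps; ``origin``
    is the coordinate of grid point (t=0, y=0, x=0).
    """

    nx: int
    ny: int
    nt: int
    dx: float
    dy: float
    dt: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nt) < 5:
            raise ValueError("grid needs at least 5 points per axis")
        if min(self.dx, self.dy, self.dt) <= 0:
            raise ValueError("grid spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape (nt, ny, nx)."""
        return (self.nt, self.ny, self.nx)

    @property
    def extents(self) -> tuple[float, float, float]:
        """Total extents (Lx, Ly, Lt)."""
        return (
            (self.nx - 1) * self.dx,
            (self.ny - 1) * self.dy,
            (self.nt - 1) * self.dt,
        )

    def spacing(self, direction) -> float:
        return {0: self.dx, 1: self.dy, "x": self.dx, "y": self.dy, "t": self.dt}[direction]

    def coords(self):
        """1D coordinate arrays (t, y, x)."""
        ot, oy, ox = self.origin[2], self.origin[1], self.origin[0]
        return (
            ot + self.dt * np.arange(self.nt),
            oy + self.dy * np.arange(self.ny),
            ox + self.dx * np.arange(self.nx),
        )


@dataclass
class FieldSequence:
    """Velocity, director and intensity proxy on a :class:`FieldGrid`.

    ``u`` and ``n`` have shape (nt, ny, nx, 2); ``phi`` has shape (nt, ny, nx)
    and defaults to 1 (fully reliable data).  ``S`` (the scalar order
    parameter) is fixed at 1.  ``periodic`` marks fields that are periodic in
    all three directions, which permits spectral differentiation.
    """

    grid: FieldGrid
    u: np.ndarray
    n: np.ndarray
    phi: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None  # boolean; False where n undefined
    periodic: bool = False
    S: float = 1.0

    def __post_init__(self) -> None:
        shape = self.grid.shape
        self.u = np.asarray(self.u, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.u.shape != shape + (2,) or self.n.shape != shape + (2,):
            raise ValueError(f"u and n must have shape {shape + (2,)}")
        if self.phi is None:
            self.phi = np.ones(shape)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != shape:
            raise ValueError(f"phi must have shape {shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("u must be finite everywhere")
        if self.phi.min() < -1e-9 or self.phi.max() > 1 + 1e-9:
            raise ValueError("phi must lie in [0, 1]")
        norms = np.linalg.norm(self.n, axis=-1)
        check = norms if self.valid is None else norms[self.valid]
        if check.size and np.abs(check - 1.0).max() > 1e-6:
            raise ValueError("director must be unit length at valid points")

    def copy(self) -> "FieldSequence":
        return FieldSequence(
            grid=self.grid,
            u=self.u.copy(),
            n=self.n.copy(),
            phi=self.phi.copy(),
            valid=None if self.valid is None else self.valid.copy(),
            periodic=self.periodic,
            S=self.S,
        )


@dataclass
class DerivedFields:
    """Kinematic tensors derived from a :class:`FieldSequence`."""

    Qbar: np.ndarray   # (..., 2, 2) symmetric traceless n n - I/2
    gradu: np.ndarray  # (..., i, j) = d_i u_j
    A: np.ndarray
    Abar: np.ndarray
    Omega: np.ndarray
    omega: np.ndarray  # scalar vorticity -2 Omega_xy
    div: np.ndarray
    Pperp: np.ndarray  # delta_ij - n_i n_j


@dataclass
class NondimScales:
    """Length/time rescaling bringing mean speed and vorticity to one."""

    length: float
    time: float


@dataclass
class MaskConfig:
    intensity_frac: float = 0.15     # threshold as a fraction of max(phi)
    grad_factor: float = 2.0         # threshold = factor * median ||grad n||
    passes: int = 10                 # box-smoothing passes
    box: int = 5                     # box kernel size per axis


@dataclass
class Mask:
    """Smooth data-reliability weight built from a Boolean exclusion field."""

    psi: np.ndarray
    psi0: np.ndarray
    intensity_threshold: float
    gradient_threshold: float
    passes: int


# ---------------------------------------------------------------------------
# differentiation


def central_diff(f: np.ndarray, direction, spacing: float) -> np.ndarray:
    """Second-order derivative of a sampled field along ``direction``.

    Interior points use the centered stencil, edges the one-sided
    second-order stencil.  ``direction`` is 0 (x), 1 (y) or "t".
    """

    axis = _AXIS_OF_DIR[direction]
    if axis >= f.ndim:
        raise ValueError(f"axis {axis} out of range for array of ndim {f.ndim}")
    if f.shape[axis] < 3:
        raise ValueError("need at least 3 points along the differentiated axis")
    return np.gradient(f, spacing, axis=axis, edge_order=2)


def spectral_diff(f: np.ndarray, direction, spacing: float) -> np.ndarray:
    """Fourier derivative along ``direction`` (periodic fields only)."""

    axis = _AXIS_OF_DIR[direction]
    npts = f.shape[axis]
    k = 2.0 * np.pi * np.fft.fftfreq(npts, d=spacing)
    shape = [1] * f.ndim
    shape[axis] = npts
    return np.real(np.fft.ifft(1j * k.reshape(shape) * np.fft.fft(f, axis=axis), axis=axis))


def _neighbor_sign(center: np.ndarray, neighbor: np.ndarray) -> np.ndarray:
    # flip neighbor so its dot product with the center director is >= 0;
    # exact-zero dot products are broken toward +.
    dot = np.sum(center * neighbor, axis=-1, keepdims=True)
    return np.where(dot < 0.0, -1.0, 1.0)


def director_diff(n: np.ndarray, direction, spacing: float) -> np.ndarray:
    """Derivative of the (sign-ambiguous) director along one direction.

    Each stencil neighbor is sign-flipped to agree with the center point
    before differencing, so the result is independent of the stored signs up
    to the center point's own sign (it transforms like ``n`` under gauge
    flips, i.e. it is "odd" in ``n``).
    """

    axis = _AXIS_OF_DIR[direction]
    if n.shape[axis] < 3:
        raise ValueError("need at least 3 points along the differentiated axis")
    n = np.moveaxis(n, axis, 0)
    out = np.empty_like(n)
    c, p, m = n[1:-1], n[2:], n[:-2]
    out[1:-1] = (_neighbor_sign(c, p) * p - _neighbor_sign(c, m) * m) / (2 * spacing)
    # one-sided second-order edges, signs taken relative to the edge point
    c0, n1, n2 = n[0], n[1], n[2]
    out[0] = (-3 * c0 + 4 * _neighbor_sign(c0, n1) * n1 - _neighbor_sign(c0, n2) * n2) / (
        2 * spacing
    )
    cN, m1, m2 = n[-1], n[-2], n[-3]
    out[-1] = (3 * cN - 4 * _neighbor_sign(cN, m1) * m1 + _neighbor_sign(cN, m2) * m2) / (
        2 * spacing
    )
    return np.moveaxis(out, 0, axis)


def align_director(n: np.ndarray) -> np.ndarray:
    """Return a smoothly gauged copy of ``n`` (sweep sign alignment).

    Signs are propagated along x on the first (t=0, y=0) line, then along y
    within the first frame, then along t for every (y, x) column.  The overall
    sign is fixed deterministically: the aligned director at grid point
    (0, 0, 0) has a non-negative x component (ties broken toward +y).  The
    result is therefore invariant under sign flips of any subset of the stored
    directors.  With topological defects present the gauge necessarily has
    seams; those regions must be excluded by the mask.
    """

    n = np.array(n, dtype=float)

    def _line_signs(line: np.ndarray) -> np.ndarray:
        # line: (m, ..., 2); cumulative sign products along axis 0
        dots = np.sum(line[:-1] * line[1:], axis=-1)
        s = np.where(dots < 0.0, -1.0, 1.0)
        return np.concatenate(
            [np.ones_like(s[:1]), np.cumprod(s, axis=0)], axis=0
        )

    n[0, 0] *= _line_signs(n[0, 0])[..., None]
    n[0] *= _line_signs(n[0])[..., None]
    n *= _line_signs(n)[..., None]
    ref = n[0, 0, 0]
    if ref[0] < 0.0 or (ref[0] == 0.0 and ref[1] < 0.0):
        n = -n
    return n


# ---------------------------------------------------------------------------
# moving least squares smoothing (3D Savitzky-Golay)


def _monomial_design(offsets: tuple[np.ndarray, np.ndarray, np.ndarray], degree: int):
    T, Y, X = np.meshgrid(*offsets, indexing="ij")
    cols = []
    for a in range(degree + 1):
        for b in range(degree + 1 - a):
            for c in range(degree + 1 - a - b):
                cols.append((T ** a * Y ** b * X ** c).ravel())
    return np.stack(cols, axis=1)


def _mls_kernel(offsets, degree: int) -> np.ndarray:
    """Weights of the local polynomial fit evaluated at offset zero."""

    A = _monomial_design(offsets, degree)
    # value at the origin = coefficient of the constant monomial (first col)
    AtA = A.T @ A
    w = np.linalg.solve(AtA, A.T)[0]
    return w.reshape(tuple(len(o) for o in offsets))


def _axis_classes(npts: int, hw: int):
    """(output indices, window offsets) pairs covering one axis."""

    classes = []
    for p in range(hw):  # left edge
        classes.append(([p], np.arange(-p, hw + 1)))
    classes.append((list(range(hw, npts - hw)), np.arange(-hw, hw + 1)))
    for p in range(npts - hw, npts):  # right edge
        classes.append(([p], np.arange(-hw, npts - p)))
    return classes


def mls_smooth(f: np.ndarray, window: int = 5, degree: int = 2) -> np.ndarray:
    """Moving-least-squares smoothing over a spatiotemporal window.

    Each point is replaced by the value at that point of a local total-degree
    ``degree`` polynomial least-squares fit over a ``window``-cubed
    neighborhood (windows are clipped at the boundaries).  Exactly reproduces
    polynomials of the fit degree.
    """

    if window % 2 == 0 or window < degree + 1:
        raise ValueError("window must be odd and at least degree + 1")
    if any(s < window for s in f.shape[:3]):
        raise ValueError("window larger than grid")
    hw = window // 2
    out = np.empty_like(np.asarray(f, dtype=float))
    f = np.asarray(f, dtype=float)
    from numpy.lib.stride_tricks import sliding_window_view

    classes = [_axis_classes(f.shape[d], hw) for d in range(3)]
    for it, offt in classes[0]:
        for iy, offy in classes[1]:
            for ix, offx in classes[2]:
                kern = _mls_kernel((offt, offy, offx), degree)
                block = f[
                    it[0] + offt[0] : it[-1] + offt[-1] + 1,
                    iy[0] + offy[0] : iy[-1] + offy[-1] + 1,
                    ix[0] + offx[0] : ix[-1] + offx[-1] + 1,
                ]
                windows = sliding_window_view(block, kern.shape, axis=(0, 1, 2))
                vals = np.einsum("tyx...abc,abc->tyx...", windows, kern)
                out[it[0] : it[-1] + 1, iy[0] : iy[-1] + 1, ix[0] : ix[-1] + 1] = vals
    return out


def smooth_sequence(fields: FieldSequence, window: int = 5, degree: int = 2) -> FieldSequence:
    """MLS-smooth u and n of a sequence (n via a smooth gauge, renormalized)."""

    out = fields.copy()
    for c in range(2):
        out.u[..., c] = mls_smooth(fields.u[..., c], window, degree)
    na = align_director(fields.n)
    for c in range(2):
        na[..., c] = mls_smooth(na[..., c], window, degree)
    norms = np.linalg.norm(na, axis=-1, keepdims=True)
    out.n = na / np.where(norms > 0, norms, 1.0)
    return out


# ---------------------------------------------------------------------------
# derived tensors


def velocity_gradient(fields: FieldSequence) -> np.ndarray:
    g = fields.grid
    gradu = np.empty(g.shape + (2, 2))
    for i in range(2):
        for j in range(2):
            gradu[..., i, j] = central_diff(fields.u[..., j], i, g.spacing(i))
    return gradu


def derived_fields(fields: FieldSequence) -> DerivedFields:
    """All kinematic tensors used by the discovery pipeline."""

    n = fields.n
    Qbar = n[..., :, None] * n[..., None, :] - 0.5 * np.eye(2)
    gradu = velocity_gradient(fields)
    A = 0.5 * (gradu + np.swapaxes(gradu, -1, -2))
    Omega = 0.5 * (gradu - np.swapaxes(gradu, -1, -2))
    div = np.trace(A, axis1=-2, axis2=-1)
    Abar = A - 0.5 * div[..., None, None] * np.eye(2)
    omega = -2.0 * Omega[..., 0, 1]
    Pperp = np.eye(2) - n[..., :, None] * n[..., None, :]
    return DerivedFields(
        Qbar=Qbar, gradu=gradu, A=A, Abar=Abar, Omega=Omega, omega=omega, div=div, Pperp=Pperp
    )


def director_gradient_norm(fields: FieldSequence) -> np.ndarray:
    """Pointwise Frobenius norm of the spatial director gradient (gauge even)."""

    g = fields.grid
    total = np.zeros(g.shape)
    for i in range(2):
        dn = director_diff(fields.n, i, g.spacing(i))
        total += np.sum(dn * dn, axis=-1)
    return np.sqrt(total)


# ---------------------------------------------------------------------------
# masking


def build_mask(
    fields: FieldSequence, config: MaskConfig | None = None
) -> Mask:
    """Reliability mask: excludes dim regions and high director curvature.

    psi0 = 1 where phi >= intensity threshold AND ||grad n|| <= gradient
    threshold; psi is psi0 smoothed by repeated box filtering, clipped to
    [0, 1].
    """

    from scipy.ndimage import uniform_filter1d

    config = config or MaskConfig()
    if config.intensity_frac <= 0 or config.grad_factor <= 0:
        raise ValueError("mask thresholds must be positive")
    phi = fields.phi
    gn = director_gradient_norm(fields)
    thr_phi = config.intensity_frac * phi.max()
    thr_grad = config.grad_factor * max(np.median(gn), 1e-300)
    psi0 = (phi >= thr_phi) & (gn <= thr_grad)
    if fields.valid is not None:
        psi0 &= fields.valid
    psi = psi0.astype(float)
    for _ in range(config.passes):
        for ax in range(3):
            if psi.shape[ax] >= config.box:
                psi = uniform_filter1d(psi, size=config.box, axis=ax, mode="nearest")
    psi = np.clip(psi, 0.0, 1.0)
    return Mask(
        psi=psi,
        psi0=psi0,
        intensity_threshold=thr_phi,
        gradient_threshold=thr_grad,
        passes=config.passes,
    )


def unit_mask(grid: FieldGrid) -> Mask:
    ones = np.ones(grid.shape)
    return Mask(psi=ones, psi0=ones.astype(bool), intensity_threshold=0.0,
                gradient_threshold=np.inf, passes=0)


# ---------------------------------------------------------------------------
# nondimensionalization


def nondimensionalize(
    fields: FieldSequence, mask: Mask | None = None
) -> tuple[FieldSequence, NondimScales]:
    """Rescale length and time so mask-weighted <|u|> = <|omega|> = 1.

    Lengths are divided by ``length``, times by ``time``; velocities rescale
    by time/length and vorticity by time, so the two conditions determine both
    scales uniquely.
    """

    w = mask.psi if mask is not None else np.ones(fields.grid.shape)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("mask excludes all data")
    speed = np.linalg.norm(fields.u, axis=-1)
    d = derived_fields(fields)
    mean_u = float((w * speed).sum() / wsum)
    mean_w = float((w * np.abs(d.omega)).sum() / wsum)
    if mean_u == 0.0 or mean_w == 0.0:
        raise ValueError("degenerate field, cannot nondimensionalize")
    time = 1.0 / mean_w
    length = mean_u / mean_w
    g = fields.grid
    new_grid = FieldGrid(
        nx=g.nx, ny=g.ny, nt=g.nt,
        dx=g.dx / length, dy=g.dy / length, dt=g.dt / time,
        origin=(g.origin[0] / length, g.origin[1] / length, g.origin[2] / time),
    )
    out = FieldSequence(
        grid=new_grid,
        u=fields.u * (time / length),
        n=fields.n.copy(),
        phi=fields.phi.copy(),
        valid=None if fields.valid is None else fields.valid.copy(),
        periodic=fields.periodic,
    )
    return out, NondimScales(length=length, time=time)


# ---------------------------------------------------------------------------
# director extraction from image stacks


def extract_director(
    stack: np.ndarray,
    blur_inner: float = 1.0,
    blur_outer: float = 2.5,
    gap_tol: float = 1e-3,
):
    """Director and intensity proxy from a grayscale image stack.

    The director is the eigenvector of the Gaussian-smoothed intensity
    structure tensor associated with its *smallest* eigenvalue, i.e. the
    direction along which the intensity varies least (the local filament
    orientation).  Points whose structure tensor is nearly isotropic
    (eigenvalue gap below ``gap_tol`` relative to the trace) are flagged
    invalid.  ``phi`` is the blurred intensity rescaled to [0, 1] over the
    stack.

    Returns ``(n, phi, valid)`` with shapes (nt, ny, nx, 2) / (nt, ny, nx).
    """

    from skimage.feature import structure_tensor
    from scipy.ndimage import gaussian_filter

    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    nt, ny, nx = stack.shape
    n = np.zeros((nt, ny, nx, 2))
    valid = np.zeros((nt, ny, nx), dtype=bool)
    # absolute floor on the tensor trace: gradients below ~1e-8 of the
    # intensity scale are numerical fuzz, not orientation signal
    tr_floor = (1e-8 * (np.abs(stack).max() + 1.0)) ** 2
    for t in range(nt):
        # skimage orders rows (y) then cols (x): Arr = [Ayy, Ayx, Axx]
        Ayy, Axy, Axx = structure_tensor(
            stack[t], sigma=blur_outer, mode="nearest", order="rc"
        )
        tr = Axx + Ayy
        disc = np.sqrt((Axx - Ayy) ** 2 + 4 * Axy ** 2)
        gap_ok = (disc > gap_tol * np.maximum(tr, 1e-300)) & (tr > tr_floor)
        lam_min = 0.5 * (tr - disc)
        # eigenvector for lam_min: (Axx - lam_min) x + Axy y = 0
        vx = -Axy
        vy = Axx - lam_min
        deg = (np.abs(vx) + np.abs(vy)) < 1e-300
        alt_vx = Ayy - lam_min
        alt_vy = -Axy
        vx = np.where(deg, alt_vx, vx)
        vy = np.where(deg, alt_vy, vy)
        norm = np.hypot(vx, vy)
        ok = gap_ok & (norm > 0)
        n[t, ..., 0] = np.where(ok, vx / np.where(norm > 0, norm, 1.0), 1.0)
        n[t, ..., 1] = np.where(ok, vy / np.where(norm > 0, norm, 1.0), 0.0)
        valid[t] = ok
    phi = np.empty_like(stack)
    for t in range(nt):
        phi[t] = gaussian_filter(stack[t], blur_inner)
    lo, hi = phi.min(), phi.max()
    phi = (phi - lo) / (hi - lo) if hi > lo else np.ones_like(phi)
    return n, phi, valid


# ---------------------------------------------------------------------------
# IO


def save_fields(fields: FieldSequence, path: str) -> None:
    """Write a sequence to HDF5 (.h5/.hdf5), NetCDF3 (.nc) or CSV (.csv)."""

    path = str(path)
    g = fields.grid
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("u", data=fields.u)
            f.create_dataset("n", data=fields.n)
            f.create_dataset("phi", data=fields.phi)
            for k, v in (("dx", g.dx), ("dy", g.dy), ("dt", g.dt)):
                f.attrs[k] = v
            f.attrs["origin"] = np.asarray(g.origin)
            f.attrs["periodic"] = int(fields.periodic)
    elif path.endswith(".nc"):
        _to_xarray(fields).to_netcdf(path, engine="scipy")
    elif path.endswith(".csv"):
        _to_csv(fields, path)
    else:
        raise ValueError(f"unrecognized extension for {path!r}")


def load_fields(path: str) -> FieldSequence:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            u = f["u"][...]
            n = f["n"][...]
            phi = f["phi"][...]
            nt, ny, nx = phi.shape
            grid = FieldGrid(
                nx=nx, ny=ny, nt=nt,
                dx=float(f.attrs["dx"]), dy=float(f.attrs["dy"]), dt=float(f.attrs["dt"]),
                origin=tuple(np.asarray(f.attrs.get("origin", (0.0, 0.0, 0.0)))),
            )
            periodic = bool(f.attrs.get("periodic", 0))
        return FieldSequence(grid=grid, u=u, n=n, phi=phi, periodic=periodic)
    if path.endswith(".nc"):
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        return _from_xarray(ds)
    if path.endswith(".csv"):
        return _from_csv(path)
    raise ValueError(f"unrecognized extension for {path!r}")


def _to_xarray(fields: FieldSequence):
    import xarray as xr

    t, y, x = fields.grid.coords()
    ds = xr.Dataset(
        {
            "u": (("t", "y", "x", "comp"), fields.u),
            "n": (("t", "y", "x", "comp"), fields.n),
            "phi": (("t", "y", "x"), fields.phi),
        },
        coords={"t": t, "y": y, "x": x, "comp": [0, 1]},
        attrs={
            "dx": fields.grid.dx, "dy": fields.grid.dy, "dt": fields.grid.dt,
            "origin_x": fields.grid.origin[0], "origin_y": fields.grid.origin[1],
            "origin_t": fields.grid.origin[2], "periodic": int(fields.periodic),
        },
    )
    return ds


def _from_xarray(ds) -> FieldSequence:
    phi = np.asarray(ds["phi"].values)
    nt, ny, nx = phi.shape
    grid = FieldGrid(
        nx=nx, ny=ny, nt=nt,
        dx=float(ds.attrs["dx"]), dy=float(ds.attrs["dy"]), dt=float(ds.attrs["dt"]),
        origin=(
            float(ds.attrs.get("origin_x", 0.0)),
            float(ds.attrs.get("origin_y", 0.0)),
            float(ds.attrs.get("origin_t", 0.0)),
        ),
    )
    return FieldSequence(
        grid=grid,
        u=np.asarray(ds["u"].values),
        n=np.asarray(ds["n"].values),
        phi=phi,
        periodic=bool(ds.attrs.get("periodic", 0)),
    )


def _to_csv(fields: FieldSequence, path: str) -> None:
    t, y, x = fields.grid.coords()
    T, Y, X = np.meshgrid(t, y, x, indexing="ij")
    cols = np.column_stack(
        [
            T.ravel(), X.ravel(), Y.ravel(),
            fields.u[..., 0].ravel(), fields.u[..., 1].ravel(),
            fields.n[..., 0].ravel(), fields.n[..., 1].ravel(),
            fields.phi.ravel(),
        ]
    )
    header = "t,x,y,ux,uy,nx,ny,phi"
    np.savetxt(path, cols, delimiter=",", header=header, comments="")


def _from_csv(path: str) -> FieldSequence:
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = np.unique(data["t"])
    y = np.unique(data["y"])
    x = np.unique(data["x"])
    nt, ny, nx = len(t), len(y), len(x)
    if nt * ny * nx != data.shape[0]:
        raise ValueError("CSV rows do not form a complete regular grid")

    def _step(c):
        return float(c[1] - c[0]) if len(c) > 1 else 1.0

    grid = FieldGrid(
        nx=nx, ny=ny, nt=nt, dx=_step(x), dy=_step(y), dt=_step(t),
        origin=(float(x[0]), float(y[0]), float(t[0])),
    )
    it = np.searchsorted(t, data["t"])
    iy = np.searchsorted(y, data["y"])
    ix = np.searchsorted(x, data["x"])
    u = np.zeros((nt, ny, nx, 2))
    n = np.zeros((nt, ny, nx, 2))
    phi = np.zeros((nt, ny, nx))
    u[it, iy, ix, 0] = data["ux"]
    u[it, iy, ix, 1] = data["uy"]
    n[it, iy, ix, 0] = data["nx"]
    n[it, iy, ix, 1] = data["ny"]
    phi[it, iy, ix] = data["phi"]
    return FieldSequence(grid=grid, u=u, n=n, phi=phi)


def load_tiff_stack(path: str) -> np.ndarray:
    """Read a grayscale TIFF stack as a float array (nt, ny, nx) in [0, 1]."""

    import tifffile

    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.max() > 1.0:
        arr = arr / arr.max()
    return arr
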