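"""Synthetic active-nematic field sequences with known governing relations.

Fixtures plant the three relations the discovery pipeline targets on real
data: incompressibility (solenoidal stream-function flows), a director
evolution equation with prescribed advection/co-rotation/alignment
coefficients, and the extensional stress balance with a prescribed extension
rate.  The generator integrates the director *angle* on periodic grids (a
smooth scalar, free of nematic sign ambiguity), so the analysis path - not
the generation path - is what exercises sign alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .field_data import FieldGrid, FieldSequence

__all__ = [
    "SyntheticSpec",
    "extensional_flow",
    "cellular_flow",
    "solid_rotation",
    "director_dynamics",
    "defect_director",
    "random_smooth_fields",
    "add_noise",
    "make_fixture",
    "FIXTURES",
    "default_grid",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset."""

    grid: FieldGrid
    flow: str = "cellular"  # cellular | extensional | solid-rotation | random-smooth
    extension_rate: float = 0.56
    mean_flow_coeffs: tuple[float, ...] = ()  # cubic coefficient of f(x)=g(x)
    coefficients: tuple[float, float, float] = (1.0, -1.0, -1.0)
    defects: tuple = ()
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.extension_rate):
            raise ValueError("extension rate must be finite")
        if self.noise < 0:
            raise ValueError("noise level must be non-negative")
        for charge, *_ in self.defects:
            if abs(charge * 2 - round(charge * 2)) > 1e-12:
                raise ValueError("defect charges must be half-integers")


def default_grid(n: int = 64, nt: int = 64, cfl: float = 0.2, umax: float = 1.0) -> FieldGrid:
    """Periodic 2pi x 2pi spatial box; dt set by the advective CFL number."""

    dx = 2.0 * np.pi / n
    dt = cfl * dx / umax
    return FieldGrid(nx=n, ny=n, nt=nt, dx=dx, dy=dx, dt=dt)


def _mesh(grid: FieldGrid):
    t, y, x = grid.coords()
    return np.meshgrid(t, y, x, indexing="ij")


# ---------------------------------------------------------------------------
# flows


def extensional_flow(
    grid: FieldGrid, extension_rate: float, cubic: float = 0.0
) -> FieldSequence:
    """Steady extensional flow u = (E x + g'(y), -E y - f'(x)), n = x-hat.

    ``cubic`` is the coefficient of the cubic mean-flow profiles
    f(x) = g(x) = cubic * x^3, which add vorticity without altering the
    extensional strain felt along the director.
    """

    T, Y, X = _mesh(grid)
    u = np.zeros(grid.shape + (2,))
    u[..., 0] = extension_rate * X + 3.0 * cubic * Y ** 2
    u[..., 1] = -extension_rate * Y - 3.0 * cubic * X ** 2
    n = np.zeros(grid.shape + (2,))
    n[..., 0] = 1.0
    return FieldSequence(grid=grid, u=u, n=n, periodic=False)


def cellular_flow(grid: FieldGrid, amplitude: float = 1.0, wavenumber: int = 1) -> np.ndarray:
    """Periodic solenoidal cell flow from psi = (a/k) sin(kx) sin(ky)."""

    T, Y, X = _mesh(grid)
    u = np.zeros(grid.shape + (2,))
    u[..., 0] = amplitude * np.sin(wavenumber * X) * np.cos(wavenumber * Y)
    u[..., 1] = -amplitude * np.cos(wavenumber * X) * np.sin(wavenumber * Y)
    return u


def traveling_cellular_flow(
    grid: FieldGrid,
    amplitudes: tuple = (0.7, 0.35),
    wavenumbers: tuple = (1, 2),
    frequencies: tuple = (2.1, 3.3),
    phases: tuple = ((0.4, 1.1), (2.2, 0.3)),
):
    """Unsteady superposition of traveling cellular modes.

    psi(x, y, t) = sum_m (a_m / k_m) sin(k_m x - w_m t + p_m) sin(k_m y + q_m)
    gives an exactly solenoidal, time-dependent flow without the degenerate
    structure of a single steady cell (no eigenrelation Delta u = -2 k^2 u,
    no vanishing time derivatives), which would otherwise plant spurious
    exact relations in the term libraries.

    Returns ``(u, u_of_t)``: the sampled (nt, ny, nx, 2) array and a callable
    evaluating the flow at an arbitrary time (for the director integrator's
    substages).
    """

    t, y, x = grid.coords()
    Y, X = np.meshgrid(y, x, indexing="ij")

    def u_of_t(tt: float) -> np.ndarray:
        u = np.zeros((grid.ny, grid.nx, 2))
        for a, k, w, (p, q) in zip(amplitudes, wavenumbers, frequencies, phases):
            sx = np.sin(k * X - w * tt + p)
            cx = np.cos(k * X - w * tt + p)
            sy = np.sin(k * Y + q)
            cy = np.cos(k * Y + q)
            u[..., 0] += a * sx * cy
            u[..., 1] += -a * cx * sy
        return u

    u = np.stack([u_of_t(tt) for tt in t], axis=0)
    return u, u_of_t


def solid_rotation(grid: FieldGrid, omega0: float = 1.0) -> np.ndarray:
    """Rigid-body rotation about the domain center, u = (omega0/2)(-y, x)."""

    T, Y, X = _mesh(grid)
    Lx, Ly, _ = grid.extents
    xc = grid.origin[0] + Lx / 2.0
    yc = grid.origin[1] + Ly / 2.0
    u = np.zeros(grid.shape + (2,))
    u[..., 0] = -0.5 * omega0 * (Y - yc)
    u[..., 1] = 0.5 * omega0 * (X - xc)
    return u


# ---------------------------------------------------------------------------
# director dynamics


def _spectral_grad2d(f: np.ndarray, dx: float, dy: float):
    ny, nx = f.shape
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=dy)
    F = np.fft.fft2(f)
    fx = np.real(np.fft.ifft2(1j * kx[None, :] * F))
    fy = np.real(np.fft.ifft2(1j * ky[:, None] * F))
    return fx, fy


def director_dynamics(
    u: np.ndarray,
    theta0: np.ndarray,
    coefficients: tuple[float, float, float],
    grid: FieldGrid,
    substeps: int = 4,
    u_of_t=None,
    grad_method: str = "spectral",
) -> FieldSequence:
    """Integrate the planted director equation forward on a periodic grid.

    The director obeys  dt n + c1 (u.grad) n + c2 Omega n + c3 Pperp Abar n = 0
    with constant coefficients.  In terms of the angle theta this is the
    scalar equation

        dt theta = -c1 u.grad theta + c2 Omega_xy
                   + c3 (Abar_xx sin 2theta - Abar_xy cos 2theta)

    integrated with classical RK4 (``substeps`` stages per stored frame).
    ``u`` is either a steady field (ny, nx, 2) or the full sampled (nt, ny,
    nx, 2) array; an unsteady flow additionally supplies ``u_of_t`` so the
    integrator can evaluate it at substage times.  Flow gradients are Fourier
    by default; ``grad_method="fd"`` uses second-order finite differences for
    flows that are not periodic on the box (e.g. solid rotation).
    """

    c1, c2, c3 = coefficients
    dx, dy, dt = grid.dx, grid.dy, grid.dt
    u0 = u[0] if u.ndim == 4 else u
    if u_of_t is None:
        steady = u0
        u_of_t = lambda tt: steady  # noqa: E731
    umax = float(np.abs(u).max())
    if umax * dt / min(dx, dy) > 0.5:
        raise ValueError("CFL violation: max|u| dt/dx > 0.5")

    flow_cache: dict[float, tuple] = {}

    def grad2d(f):
        if grad_method == "fd":
            dyf, dxf = np.gradient(f, dy, dx, edge_order=2)
            return dxf, dyf
        return _spectral_grad2d(f, dx, dy)

    def flow(tt: float):
        if tt not in flow_cache:
            uu = u_of_t(tt)
            dxux, dyux = grad2d(uu[..., 0])
            dxuy, dyuy = grad2d(uu[..., 1])
            Omega_xy = 0.5 * (dxuy - dyux)
            div = dxux + dyuy
            flow_cache.clear()
            flow_cache[tt] = (
                uu, Omega_xy, dxux - 0.5 * div, 0.5 * (dxuy + dyux)
            )
        return flow_cache[tt]

    def rhs(theta, tt):
        uu, Omega_xy, Abar_xx, Abar_xy = flow(tt)
        tx, ty = _spectral_grad2d(theta, dx, dy)
        return (
            -c1 * (uu[..., 0] * tx + uu[..., 1] * ty)
            + c2 * Omega_xy
            + c3 * (Abar_xx * np.sin(2 * theta) - Abar_xy * np.cos(2 * theta))
        )

    theta = np.empty(grid.shape)
    theta[0] = theta0
    h = dt / substeps
    t0 = grid.origin[2]
    cur = np.array(theta0, dtype=float)
    for k in range(1, grid.nt):
        for s in range(substeps):
            tt = t0 + (k - 1) * dt + s * h
            k1 = rhs(cur, tt)
            k2 = rhs(cur + 0.5 * h * k1, tt + 0.5 * h)
            k3 = rhs(cur + 0.5 * h * k2, tt + 0.5 * h)
            k4 = rhs(cur + h * k3, tt + h)
            cur = cur + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        theta[k] = cur
    n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    ufull = u if u.ndim == 4 else np.broadcast_to(u0, grid.shape + (2,)).copy()
    return FieldSequence(grid=grid, u=ufull, n=n, periodic=True)


def defect_director(
    grid: FieldGrid,
    charge: float,
    position: tuple[float, float],
    theta_offset: float = 0.0,
):
    """Director of an isolated half-integer topological defect.

    Returns (n, valid): theta_n = charge * atan2(y - y0, x - x0) + offset;
    the core point(s) within half a grid cell are flagged invalid.
    """

    if abs(abs(charge) - 0.5) > 1e-12 and abs(charge * 2 - round(charge * 2)) > 1e-12:
        raise ValueError("charge must be a half-integer")
    T, Y, X = _mesh(grid)
    x0, y0 = position
    r = np.hypot(X - x0, Y - y0)
    theta = charge * np.arctan2(Y - y0, X - x0) + theta_offset
    n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    valid = r > 0.5 * min(grid.dx, grid.dy)
    return n, valid


# ---------------------------------------------------------------------------
# random smooth probes and noise


def _bandlimited_3d(grid: FieldGrid, cutoff: int, decay: float, rng) -> np.ndarray:
    shape = grid.shape
    for npts in shape:
        if cutoff >= npts // 2:
            raise ValueError("spectral cutoff must be below the grid Nyquist mode")
    F = np.fft.fftn(rng.standard_normal(shape))
    kt = np.fft.fftfreq(shape[0]) * shape[0]
    ky = np.fft.fftfreq(shape[1]) * shape[1]
    kx = np.fft.fftfreq(shape[2]) * shape[2]
    K = np.sqrt(
        kt[:, None, None] ** 2 + ky[None, :, None] ** 2 + kx[None, None, :] ** 2
    )
    filt = np.exp(-0.5 * (K / decay) ** 2) * (K <= cutoff)
    f = np.real(np.fft.ifftn(F * filt))
    rms = np.sqrt(np.mean(f ** 2))
    return f / rms if rms > 0 else f


def random_smooth_fields(
    grid: FieldGrid,
    cutoff: int = 3,
    seed: int = 0,
    u_rms: float = 1.0,
    theta_rms: float = 0.35,
    decay: float = 1.2,
) -> FieldSequence:
    """Band-limited random periodic fields (generally compressible flow).

    Used as probe data: physical relations fail on these fields while true
    identities hold to near machine precision.  The defaults keep the
    *director* spectrum (harmonics of the band-limited angle) far below the
    grid Nyquist mode, so Fourier differentiation of n is accurate to ~1e-9
    on a 32-point axis; rougher angles would alias and blur the sharp
    identity/physical separation the probes exist to provide.
    """

    rng = np.random.default_rng(seed)
    ux = u_rms * _bandlimited_3d(grid, cutoff, decay, rng)
    uy = u_rms * _bandlimited_3d(grid, cutoff, decay, rng)
    theta = theta_rms * _bandlimited_3d(grid, cutoff, decay, rng)
    u = np.stack([ux, uy], axis=-1)
    n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    return FieldSequence(grid=grid, u=u, n=n, periodic=True)


def add_noise(fields: FieldSequence, level: float, seed: int = 0) -> FieldSequence:
    """Additive Gaussian noise: per-component u noise with SD = level * RMS,
    director angle perturbed by a Gaussian of SD = level radians."""

    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level == 0:
        return fields.copy()
    rng = np.random.default_rng(seed)
    out = fields.copy()
    for c in range(2):
        rms = np.sqrt(np.mean(fields.u[..., c] ** 2))
        out.u[..., c] = fields.u[..., c] + rng.normal(0.0, level * rms, fields.grid.shape)
    theta = np.arctan2(fields.n[..., 1], fields.n[..., 0])
    theta = theta + rng.normal(0.0, level, fields.grid.shape)
    out.n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    return out


# ---------------------------------------------------------------------------
# fixtures


def _smooth_theta0(grid: FieldGrid, seed: int, amplitude: float = 0.5, cutoff: int = 2):
    # amplitude/cutoff keep max |grad theta| dx well below 1 even after the
    # cellular flow shears the field over the run, so the director stays
    # resolved on the mesh (as experimental data is on its mesh)
    rng = np.random.default_rng(seed)
    ny, nx = grid.ny, grid.nx
    F = np.fft.fft2(rng.standard_normal((ny, nx)))
    ky = np.fft.fftfreq(ny) * ny
    kx = np.fft.fftfreq(nx) * nx
    K = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    filt = np.exp(-0.5 * (K / 1.5) ** 2) * (K <= cutoff)
    f = np.real(np.fft.ifft2(F * filt))
    rms = np.sqrt(np.mean(f ** 2))
    return amplitude * f / rms if rms > 0 else f


def _fixture_eq3(grid, noise, seed, coefficients=(1.0, -1.0, -1.0), **kw):
    u, u_of_t = traveling_cellular_flow(grid)
    theta0 = _smooth_theta0(grid, seed + 1)
    fields = director_dynamics(u, theta0, coefficients, grid, u_of_t=u_of_t)
    truth = {"relation": "incompressibility", "support": ["div_u"], "coefficients": [1.0]}
    return add_noise(fields, noise, seed), truth


def _fixture_eq4(grid, noise, seed, coefficients=(1.0, -1.0, -1.0), **kw):
    # coefficient identification needs data spanning several correlation
    # times (the experimental dataset covers ~17 nondimensional time units),
    # so this fixture defaults to a longer time axis than the others
    fields, _ = _fixture_eq3(grid, 0.0, seed, coefficients=coefficients)
    c1, c2, c3 = coefficients
    truth = {
        "relation": "director evolution",
        "coefficients": {"c1": c1, "c2": c2, "c3": c3},
        # raw-term expansion: dt n, u.grad n, d_i u_a n_a, d_a u_i n_a, n (n A n)
        "raw_support": ["dt_n", "advect_n", "gradu_n_free_deriv", "gradu_n_free_comp", "n_nAn"],
        "raw_coefficients": [1.0, c1, 0.5 * (c2 + c3), 0.5 * (c3 - c2), -c3],
    }
    return add_noise(fields, noise, seed), truth


def _extensional_grid(n: int = 64, nt: int = 64) -> FieldGrid:
    dx = 2.0 / (n - 1)
    return FieldGrid(nx=n, ny=n, nt=nt, dx=dx, dy=dx, dt=0.05, origin=(-1.0, -1.0, 0.0))


def _fixture_eq9(grid, noise, seed, extension_rate=0.56, cubic=0.2, **kw):
    grid = grid if grid is not None else _extensional_grid()
    fields = extensional_flow(grid, extension_rate, cubic=cubic)
    truth = {
        "relation": "stress balance",
        "extension_rate": extension_rate,
        "c5": -extension_rate,
        "scalar_support": ["nnA", "const"],
        "sym_support": ["nn_nnA", "nn"],
    }
    return add_noise(fields, noise, seed), truth


def _fixture_defect_mask(grid, noise, seed, charge=0.5, core_radius=0.6, **kw):
    n, valid = defect_director(
        grid, charge, position=(np.pi, np.pi), theta_offset=0.1
    )
    T, Y, X = _mesh(grid)
    r = np.hypot(X - np.pi, Y - np.pi)
    phi = r ** 2 / (r ** 2 + core_radius ** 2)
    u = cellular_flow(grid, amplitude=0.3, wavenumber=1)
    fields = FieldSequence(grid=grid, u=u, n=n, phi=phi, valid=valid, periodic=False)
    truth = {"relation": None, "defect_charge": charge, "core_radius": core_radius}
    return add_noise(fields, noise, seed), truth


FIXTURES = {
    "eq3": _fixture_eq3,
    "eq4": _fixture_eq4,
    "eq5": _fixture_eq9,
    "eq9": _fixture_eq9,
    "defect-mask": _fixture_defect_mask,
}


def make_fixture(
    name: str,
    grid: Optional[FieldGrid] = None,
    noise: float = 0.0,
    seed: int = 0,
    **kwargs,
):
    """Standard fixture datasets with their ground-truth relations."""

    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    if grid is None:
        if name in ("eq5", "eq9"):
            grid = _extensional_grid()
        elif name == "eq4":
            grid = default_grid(nt=192)
        else:
            grid = default_grid()
    return FIXTURES[name](grid, noise, seed, **kwargs)
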