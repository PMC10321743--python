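"""Weak-form evaluation: windowed integrals of library terms over random
spatiotemporal subdomains, assembled into the linear system G c = 0.

Each weight function is a product of (i) a boundary-vanishing envelope
(1-x^2)^tau (1-y^2)^tau (1-t^2)^tau on the subdomain mapped to the reference
cube [-1,1]^3, (ii) an optional single-axis cosine modulation with a random
phase, and (iii) the data-reliability mask.  Because the envelope vanishes on
the subdomain boundary together with tau-1 derivatives, integration by parts
transfers derivatives from (noisy) data onto the (smooth, analytic) weight
with no boundary terms.  Integrals use the trapezoidal rule.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .field_data import FieldGrid, FieldSequence, Mask, central_diff, unit_mask
from .term_library import Factor, LibraryTerm, TermLibrary
from .evaluation import TermEvaluator, SlicedEvaluator, LEVI_CIVITA, seamless_gauge

__all__ = [
    "Subdomain",
    "WeightSpec",
    "WeightFunction",
    "WeakFormConfig",
    "FeatureMatrix",
    "sample_subdomains",
    "make_weight",
    "transfer_derivatives",
    "integrate_term",
    "build_feature_matrix",
    "envelope_1d",
]

_MIN_EXTENT = 9
_DEFAULT_EXTENTS = (54, 54, 65)  # (x, y, t) grid points per subdomain
_COMPONENTS = {"scalar": 1, "vector": 2, "sym": 2, "antisym": 1}


@dataclass(frozen=True)
class Subdomain:
    """Axis-aligned box of grid points with its map to the reference cube."""

    start: tuple[int, int, int]   # (it, iy, ix)
    extent: tuple[int, int, int]  # (pt, py, px) points per axis

    def __post_init__(self):
        if min(self.extent) < _MIN_EXTENT:
            raise ValueError(f"subdomain extents must be >= {_MIN_EXTENT} points")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(s, s + p) for s, p in zip(self.start, self.extent))

    def reference_coords(self):
        """1D reference coordinates in [-1, 1] per axis (t, y, x)."""
        return tuple(np.linspace(-1.0, 1.0, p) for p in self.extent)

    def half_lengths(self, grid: FieldGrid) -> tuple[float, float, float]:
        steps = (grid.dt, grid.dy, grid.dx)
        return tuple(0.5 * (p - 1) * h for p, h in zip(self.extent, steps))


@dataclass(frozen=True)
class WeightSpec:
    """Envelope power, modulation axis and phase, mask inclusion."""

    tau: int = 4
    modulation: str = "none"  # none | x | y | t
    phase: float = 0.0
    use_mask: bool = True

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.modulation not in ("none", "x", "y", "t"):
            raise ValueError("modulation must be one of none/x/y/t")
        if not (0.0 <= self.phase < 2.0 * np.pi):
            raise ValueError("phase must lie in [0, 2 pi)")


def envelope_1d(xi: np.ndarray, tau: int, order: int = 0) -> np.ndarray:
    """The 1D envelope (1 - xi^2)^tau or its derivative of given order."""

    poly = np.polynomial.Polynomial([1.0, 0.0, -1.0]) ** tau
    return poly.deriv(order)(xi) if order else poly(xi)


def _axis_profile(xi, tau, modulated, phase, order):
    """d^order/dxi^order of envelope(xi) * cos(pi xi - phase) (reference coords)."""

    if not modulated:
        return envelope_1d(xi, tau, order)
    total = np.zeros_like(xi)
    for j in range(order + 1):
        k = order - j  # cosine derivative order
        cos_d = np.pi ** k * np.cos(np.pi * xi - phase + k * np.pi / 2.0)
        total += math.comb(order, j) * envelope_1d(xi, tau, j) * cos_d
    return total


@dataclass
class WeightFunction:
    """Sampled weight and its derivatives on one subdomain."""

    spec: WeightSpec
    subdomain: Subdomain
    derivs: dict  # (ndx, ndy, ndt) -> array of shape extent (t, y, x)
    quad: np.ndarray  # trapezoid weights x physical cell volume, same shape

    def __post_init__(self):
        self._wq: dict = {}

    @property
    def w(self) -> np.ndarray:
        return self.derivs[(0, 0, 0)]

    def _weighted(self, deriv):
        if deriv not in self._wq:
            self._wq[deriv] = self.quad * self.derivs[deriv]
        return self._wq[deriv]

    def integrate(self, integrand: np.ndarray, deriv=(0, 0, 0)) -> float:
        return float(np.sum(self._weighted(deriv) * integrand))


def sample_subdomains(
    grid: FieldGrid,
    count: int,
    extents: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> list[Subdomain]:
    """Subdomains with centers uniform over all admissible positions."""

    ext = resolve_extents(grid, extents)
    rng = np.random.default_rng(seed)
    limits = [n - p for n, p in zip(grid.shape, (ext[2], ext[1], ext[0]))]
    if min(limits) < 0:
        raise ValueError("subdomain extents exceed the grid")
    out = []
    for _ in range(count):
        start = tuple(int(rng.integers(0, lim + 1)) for lim in limits)
        out.append(Subdomain(start=start, extent=(ext[2], ext[1], ext[0])))
    return out


def resolve_extents(grid: FieldGrid, extents=None) -> tuple[int, int, int]:
    """Requested (x, y, t) extents clamped to the grid (warn when shrunk)."""

    req = tuple(extents) if extents is not None else _DEFAULT_EXTENTS
    sizes = (grid.nx, grid.ny, grid.nt)
    out = []
    for want, n in zip(req, sizes):
        if want > n:
            use = max(_MIN_EXTENT, int(0.42 * n))
            warnings.warn(
                f"subdomain extent {want} exceeds grid axis of {n} points; using {use}",
                stacklevel=2,
            )
            want = use
        if want < _MIN_EXTENT:
            want = _MIN_EXTENT
        if want > n:
            raise ValueError("grid too small for minimum subdomain extent")
        out.append(int(want))
    return tuple(out)


def make_weight(
    subdomain: Subdomain,
    spec: WeightSpec,
    grid: FieldGrid,
    mask: Optional[Mask] = None,
    orders: Optional[set] = None,
) -> WeightFunction:
    """Sample the weight and its derivatives (physical-coordinate) needed for
    the requested transfer ``orders`` (set of (ndx, ndy, ndt) multi-indices).
    """

    orders = set(orders or ()) | {(0, 0, 0)}
    base = _base_weight_arrays(
        subdomain.extent, subdomain.half_lengths(grid), spec, tuple(sorted(orders))
    )
    derivs = dict(base)
    mask_trivial = mask is None or float(mask.psi.min()) >= 1.0
    if spec.use_mask and not mask_trivial:
        psi = mask.psi[subdomain.slices()]
        steps = {"x": grid.dx, "y": grid.dy, "t": grid.dt}
        psi_d = {(0, 0, 0): psi}

        def mask_deriv(o):
            if o in psi_d:
                return psi_d[o]
            for pos, ax in ((0, 0), (1, 1), (2, "t")):
                if o[pos] > 0:
                    lower = list(o)
                    lower[pos] -= 1
                    prev = mask_deriv(tuple(lower))
                    h = grid.dx if pos == 0 else grid.dy if pos == 1 else grid.dt
                    psi_d[o] = central_diff(prev, ax if pos < 2 else "t", h)
                    return psi_d[o]
            raise KeyError(o)

        derivs = {}
        for o in base:
            total = np.zeros(subdomain.extent)
            for sub in itertools.product(
                range(o[0] + 1), range(o[1] + 1), range(o[2] + 1)
            ):
                comb = (
                    math.comb(o[0], sub[0])
                    * math.comb(o[1], sub[1])
                    * math.comb(o[2], sub[2])
                )
                rest = (o[0] - sub[0], o[1] - sub[1], o[2] - sub[2])
                total += comb * base[sub] * mask_deriv(rest)
            derivs[o] = total
    # trapezoid weights in physical coordinates
    qt = _trap_1d(subdomain.extent[0]) * grid.dt
    qy = _trap_1d(subdomain.extent[1]) * grid.dy
    qx = _trap_1d(subdomain.extent[2]) * grid.dx
    quad = qt[:, None, None] * qy[None, :, None] * qx[None, None, :]
    return WeightFunction(spec=spec, subdomain=subdomain, derivs=derivs, quad=quad)


_BASE_CACHE: dict = {}


def _base_weight_arrays(extent, halves, spec: WeightSpec, orders) -> dict:
    """Envelope x modulation separable arrays, cached across subdomains
    (they depend on the extents and weight spec only)."""

    key = (tuple(extent), tuple(halves), spec.tau, spec.modulation, spec.phase, orders)
    if key in _BASE_CACHE:
        return _BASE_CACHE[key]
    max_order = (
        max(o[0] for o in orders),
        max(o[1] for o in orders),
        max(o[2] for o in orders),
    )
    ref = [np.linspace(-1.0, 1.0, p) for p in extent]  # (t, y, x)
    ht, hy, hx = halves
    prof = {}
    for axis, (xi, half) in (("x", (ref[2], hx)), ("y", (ref[1], hy)), ("t", (ref[0], ht))):
        modulated = spec.modulation == axis
        prof[axis] = [
            _axis_profile(xi, spec.tau, modulated, spec.phase, k) / half ** k
            for k in range(max(max_order) + 1)
        ]
    base = {}
    for o in itertools.product(
        range(max_order[0] + 1), range(max_order[1] + 1), range(max_order[2] + 1)
    ):
        base[o] = (
            prof["t"][o[2]][:, None, None]
            * prof["y"][o[1]][None, :, None]
            * prof["x"][o[0]][None, None, :]
        )
    if len(_BASE_CACHE) > 64:
        _BASE_CACHE.clear()
    _BASE_CACHE[key] = base
    return base


def _trap_1d(n: int) -> np.ndarray:
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


# ---------------------------------------------------------------------------
# integration by parts


@dataclass(frozen=True)
class TransferPlan:
    """How a term is evaluated weakly.

    ``transferred`` is True when every derivative of the (single) field factor
    moves onto the weight; the residual is the bare factor plus any eps
    factors.  Otherwise the term is integrated directly (derivatives on data).
    """

    transferred: bool
    sign: int = 1
    field_factor: Optional[Factor] = None
    eps_factors: tuple = ()


def transfer_derivatives(term: LibraryTerm, tau: int = 4) -> TransferPlan:
    """Integration-by-parts plan for one term.

    Only derivatives attached to a term that consists of a single field
    factor (plus constant eps factors) can be isolated without product-rule
    splitting; those are all moved onto the weight, one sign flip each.
    Derivatives locked inside multi-factor products stay on the data.
    """

    fields = [f for f in term.factors if f.symbol in ("u", "n")]
    epses = tuple(f for f in term.factors if f.symbol == "eps")
    if len(fields) == 1 and fields[0].order > 0:
        order = fields[0].order
        if order > tau - 1:
            raise ValueError(
                f"transfer order {order} exceeds tau - 1 = {tau - 1}"
            )
        return TransferPlan(
            transferred=True,
            sign=(-1) ** order * term.sign,
            field_factor=fields[0],
            eps_factors=epses,
        )
    return TransferPlan(transferred=False, sign=1)


def required_weight_orders(library: TermLibrary, tau: int = 4) -> set:
    """All (ndx, ndy, ndt) weight-derivative orders the library can request."""

    orders = {(0, 0, 0)}
    for term in library.terms:
        plan = transfer_derivatives(term, tau)
        if not plan.transferred:
            continue
        f = plan.field_factor
        nsd = len(f.derivs)
        for ndx in range(nsd + 1):
            orders.add((ndx, nsd - ndx, f.dt))
    return orders


def integrate_term(
    term: LibraryTerm,
    weight: WeightFunction,
    evaluator: TermEvaluator,
    tau: int = 4,
) -> list[float]:
    """Weak integral of the term against one weight, one value per projected
    tensor component (see ``TermEvaluator.projected_components``)."""

    plan = transfer_derivatives(term, tau)
    if not plan.transferred:
        comps = evaluator.projected_components(term)
        vals = [weight.integrate(c) for c in comps]
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite weak integral (unmasked bad data?)")
        return vals
    raw = _transferred_components(term, plan, weight, evaluator)
    if term.symclass == "scalar":
        vals = [raw[()]]
    elif term.symclass == "vector":
        vals = [raw[(0,)], raw[(1,)]]
    elif term.symclass == "sym":
        vals = [0.5 * (raw[(0, 0)] - raw[(1, 1)]), 0.5 * (raw[(0, 1)] + raw[(1, 0)])]
    else:  # antisym
        vals = [0.5 * (raw[(0, 1)] - raw[(1, 0)])]
    if not all(np.isfinite(vals)):
        raise ValueError("non-finite weak integral (unmasked bad data?)")
    return vals


def _transferred_components(term, plan, weight, evaluator):
    f = plan.field_factor
    free = term.free_labels()
    bound = sorted(
        {lab for lab in f.labels() if lab not in free}
        | {lab for e in plan.eps_factors for lab in e.comps if lab not in free}
    )
    out = {}
    for fv in itertools.product((0, 1), repeat=term.rank):
        assign = dict(zip(free, fv))
        total = 0.0
        for bv in itertools.product((0, 1), repeat=len(bound)):
            local = dict(assign)
            local.update(zip(bound, bv))
            scalar = float(plan.sign)
            for e in plan.eps_factors:
                scalar *= LEVI_CIVITA[local[e.comps[0]], local[e.comps[1]]]
            if scalar == 0.0:
                continue
            ndx = sum(1 for d in f.derivs if local[d] == 0)
            ndy = len(f.derivs) - ndx
            data = evaluator.factor_array(f.symbol, local[f.comps[0]], 0, 0, 0)
            total += scalar * weight.integrate(data, deriv=(ndx, ndy, f.dt))
        out[fv] = total
    return out


# ---------------------------------------------------------------------------
# feature matrix assembly


@dataclass
class WeakFormConfig:
    n_subdomains: Optional[int] = None     # default: rows >= 10 x columns
    extents: Optional[tuple[int, int, int]] = None  # (x, y, t); None = default
    tau: int = 4
    use_mask: bool = True
    rows_per_column: int = 10
    xi_max_subdomains: int = 4  # subdomain sample for the single-term scales
    seed: int = 0


@dataclass
class FeatureMatrix:
    """Weak-form linear system for one library."""

    G: np.ndarray
    xi: np.ndarray               # per-column single-term scale
    col_keys: list[str]
    row_meta: np.ndarray         # (row, 3): subdomain, weight, component
    library: TermLibrary
    config: WeakFormConfig
    subdomains: list[Subdomain]
    weight_specs: list[WeightSpec]

    @property
    def n_rows(self) -> int:
        return self.G.shape[0]

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("G", data=self.G)
            f.create_dataset("xi", data=self.xi)
            f.create_dataset("row_meta", data=self.row_meta)
            f.attrs["col_keys"] = json.dumps(self.col_keys)
            f.attrs["library"] = self.library.to_json()
            f.attrs["seed"] = self.config.seed
            f.attrs["tau"] = self.config.tau

    @staticmethod
    def load(path: str) -> "FeatureMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            lib = TermLibrary.from_json(f.attrs["library"])
            cfg = WeakFormConfig(seed=int(f.attrs["seed"]), tau=int(f.attrs["tau"]))
            return FeatureMatrix(
                G=f["G"][...],
                xi=f["xi"][...],
                col_keys=json.loads(f.attrs["col_keys"]),
                row_meta=f["row_meta"][...],
                library=lib,
                config=cfg,
                subdomains=[],
                weight_specs=[],
            )


def default_weight_specs(tau: int, use_mask: bool, rng) -> list[WeightSpec]:
    """The four modulation choices, each with an independent random phase."""

    specs = [WeightSpec(tau=tau, modulation="none", use_mask=use_mask)]
    for mod in ("x", "y", "t"):
        specs.append(
            WeightSpec(tau=tau, modulation=mod, phase=float(rng.uniform(0, 2 * np.pi)),
                       use_mask=use_mask)
        )
    return specs


def build_feature_matrix(
    library: TermLibrary,
    fields: FieldSequence,
    mask: Optional[Mask] = None,
    config: Optional[WeakFormConfig] = None,
) -> FeatureMatrix:
    """Assemble G for one library: rows = (subdomain, weight, component).

    Each subdomain gets its own evaluator built on the sliced fields, with the
    director re-gauged locally, so weak integrals are independent of the
    stored nematic signs.  Per-column single-term scales ``xi`` are Frobenius
    norms over rows of the weak integrals of each term's *uncontracted*
    tensor, estimated over a capped subdomain sample.
    """

    if len(library) == 0:
        raise ValueError("library is empty")
    config = config or WeakFormConfig()
    grid = fields.grid
    rng = np.random.default_rng(config.seed)
    ncomp = _COMPONENTS[library.spec.symclass]
    weight_specs = default_weight_specs(config.tau, config.use_mask, rng)
    nw = len(weight_specs)
    count = config.n_subdomains
    if count is None:
        count = int(np.ceil(config.rows_per_column * len(library) / (nw * ncomp)))
    subdomains = sample_subdomains(
        grid, count, config.extents, seed=int(rng.integers(0, 2 ** 31))
    )
    orders = required_weight_orders(library, config.tau)
    if mask is None:
        mask = unit_mask(grid)
    # fast path: with a seam-free global director gauge every term can be
    # evaluated once on the full mesh (centered stencils throughout) and
    # sliced per subdomain; defect-bearing fields fall back to independent
    # per-subdomain gauges
    seamless = fields.valid is None and seamless_gauge(fields.n)
    parent = TermEvaluator(fields, method="fd") if seamless else None

    G = np.zeros((count * nw * ncomp, len(library)))
    xi_sq = np.zeros(len(library))
    row_meta = np.zeros((G.shape[0], 3), dtype=int)
    xi_subs = min(count, config.xi_max_subdomains)
    for l in range(count):
        for k in range(nw):
            for c in range(ncomp):
                row_meta[(l * nw + k) * ncomp + c] = (l, k, c)

    def _row(l, k, c):
        return (l * nw + k) * ncomp + c

    def _evaluator(l):
        if seamless:
            return SlicedEvaluator(parent, subdomains[l].slices(), _slice_grid(grid, subdomains[l]))
        return TermEvaluator(_slice_fields(fields, subdomains[l]), method="fd")

    mask_trivial = float(mask.psi.min()) >= 1.0
    slices = [sub.slices() for sub in subdomains]

    # weight values (order (0,0,0)) times quadrature, flattened per (l, k);
    # with a trivial mask all subdomains share the same four arrays
    if mask_trivial:
        shared = [
            make_weight(subdomains[0], spec, grid, mask=None, orders={(0, 0, 0)})
            for spec in weight_specs
        ]
        wq000 = [np.stack([wt._weighted((0, 0, 0)).ravel() for wt in shared])] * count
    else:
        wq000 = []
        for sub in subdomains:
            wts = [
                make_weight(sub, spec, grid, mask=mask, orders={(0, 0, 0)})
                for spec in weight_specs
            ]
            wq000.append(np.stack([wt._weighted((0, 0, 0)).ravel() for wt in wts]))

    plans = [transfer_derivatives(t, config.tau) for t in library.terms]

    # direct terms, term-major: evaluate each projected component once on the
    # full mesh (seamless) or per subdomain (fallback), then reduce against
    # the weight vectors
    if seamless:
        from .evaluation import _projected_components as _proj

        for r, term in enumerate(library.terms):
            if plans[r].transferred:
                continue
            comps = _proj(parent, term)  # full-grid arrays
            for c, garr in enumerate(comps):
                for l in range(count):
                    seg = garr[slices[l]].ravel()
                    vals = wq000[l] @ seg  # all weights at once
                    for k in range(nw):
                        G[_row(l, k, c), r] = vals[k]
            # evict the full-grid term products (keep derivative arrays)
            parent._cache = {
                key: v for key, v in parent._cache.items() if key[0] != "tc"
            }
    else:
        for l in range(count):
            ev = _evaluator(l)
            for r, term in enumerate(library.terms):
                if plans[r].transferred:
                    continue
                for c, arr in enumerate(ev.projected_components(term)):
                    vals = wq000[l] @ arr.ravel()
                    for k in range(nw):
                        G[_row(l, k, c), r] = vals[k]

    # transferred terms: few (single-factor) columns; weights need their
    # derivative arrays, rebuilt per subdomain only when the mask is active
    transferred_cols = [r for r in range(len(library)) if plans[r].transferred]
    if transferred_cols:
        if mask_trivial:
            full_weights = [[
                make_weight(subdomains[0], spec, grid, mask=None, orders=orders)
                for spec in weight_specs
            ]] * count
        else:
            full_weights = None
        for l in range(count):
            ev = _evaluator(l)
            wts = (
                full_weights[l]
                if full_weights is not None
                else [
                    make_weight(subdomains[l], spec, grid, mask=mask, orders=orders)
                    for spec in weight_specs
                ]
            )
            for r in transferred_cols:
                term = library.terms[r]
                for k, wt in enumerate(wts):
                    vals = integrate_term(term, wt, ev, config.tau)
                    for c in range(ncomp):
                        G[_row(l, k, c), r] = vals[c]

    # single-term scales: Frobenius norm over rows of the weak integrals of
    # each term's uncontracted tensor, estimated on a subdomain sample
    for l in range(xi_subs):
        ev = _evaluator(l)
        for r, term in enumerate(library.terms):
            unc = ev.uncontracted_tensor(term)
            flat = unc.reshape(wq000[l].shape[1], -1)
            contrib = wq000[l] @ flat  # (weights, components)
            xi_sq[r] += float(np.sum(contrib ** 2))
    # scale the sampled xi estimate up to the full row population
    xi = np.sqrt(xi_sq * (count / max(xi_subs, 1)))
    if not np.any(np.abs(G) > 0):
        raise ValueError("no usable data: all weak-form rows are zero")
    if G.shape[0] < config.rows_per_column * G.shape[1]:
        warnings.warn("feature matrix has fewer rows than 10x the column count")
    return FeatureMatrix(
        G=G,
        xi=xi,
        col_keys=library.keys(),
        row_meta=row_meta,
        library=library,
        config=config,
        subdomains=subdomains,
        weight_specs=weight_specs,
    )


def _slice_grid(g: FieldGrid, sub: Subdomain) -> FieldGrid:
    origin = (
        g.origin[0] + sub.start[2] * g.dx,
        g.origin[1] + sub.start[1] * g.dy,
        g.origin[2] + sub.start[0] * g.dt,
    )
    return FieldGrid(
        nx=sub.extent[2], ny=sub.extent[1], nt=sub.extent[0],
        dx=g.dx, dy=g.dy, dt=g.dt, origin=origin,
    )


def _slice_fields(fields: FieldSequence, sub: Subdomain) -> FieldSequence:
    sl = sub.slices()
    grid = _slice_grid(fields.grid, sub)
    return FieldSequence(
        grid=grid,
        u=fields.u[sl],
        n=fields.n[sl],
        phi=fields.phi[sl],
        valid=None if fields.valid is None else fields.valid[sl],
        periodic=False,
    )
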