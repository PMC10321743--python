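"""Pointwise numeric evaluation of library terms on gridded fields.

The evaluator resolves a symbolic :class:`~spider2d.term_library.LibraryTerm`
into arrays on the grid of a :class:`~spider2d.field_data.FieldSequence`.
Derivatives of the director are taken on a smoothly gauged copy of ``n``
(sweep sign alignment), so results are independent of the stored nematic
signs.

Two derivative backends are available: second-order finite differences
(``method="fd"``, the analysis path) and Fourier differentiation
(``method="spectral"``, exact for the band-limited periodic probe fields used
for identity classification and fingerprint deduplication).

For weak-form assembly over many subdomains a :class:`SlicedEvaluator` views
into a single full-grid evaluator, so each term is evaluated once on the
whole mesh (with proper centered stencils) and merely sliced per subdomain.
This requires a seam-free global director gauge; fields containing
topological defects fall back to independent per-subdomain evaluators.
"""

from __future__ import annotations

import itertools

import numpy as np

from .field_data import FieldSequence, align_director, central_diff, spectral_diff
from .term_library import LibraryTerm

__all__ = ["TermEvaluator", "SlicedEvaluator", "LEVI_CIVITA", "seamless_gauge"]

LEVI_CIVITA = np.array([[0.0, 1.0], [-1.0, 0.0]])


def seamless_gauge(n: np.ndarray) -> bool:
    """True when sweep alignment yields a globally smooth gauge (all
    nearest-neighbor dot products non-negative) - i.e. no defect seams."""

    a = align_director(n)
    for axis in range(3):
        lead = [slice(None)] * 3
        lag = [slice(None)] * 3
        lead[axis] = slice(1, None)
        lag[axis] = slice(None, -1)
        dots = np.sum(a[tuple(lead)] * a[tuple(lag)], axis=-1)
        if dots.min() < 0.0:
            return False
    return True


# ---------------------------------------------------------------------------
# shared evaluation kernels (operate on any object exposing factor_array,
# grid shape and a cache dict)


def _term_component(ev, term: LibraryTerm, free_values: tuple[int, ...]) -> np.ndarray:
    if len(free_values) != term.rank:
        raise ValueError("free_values must match the term rank")
    shape = ev.shape
    if term.is_constant:
        return np.ones(shape)
    assign = {lab: v for lab, v in zip(term.free_labels(), free_values)}
    bound = sorted(
        {lab for f in term.factors for lab in f.labels() if lab not in assign}
    )
    total = np.zeros(shape)
    for values in itertools.product((0, 1), repeat=len(bound)):
        local = dict(assign)
        local.update(zip(bound, values))
        prod = None
        scalar = float(term.sign)
        for f in term.factors:
            if f.symbol == "eps":
                scalar *= LEVI_CIVITA[local[f.comps[0]], local[f.comps[1]]]
                if scalar == 0.0:
                    break
                continue
            ndx = sum(1 for d in f.derivs if local[d] == 0)
            ndy = len(f.derivs) - ndx
            arr = ev.factor_array(f.symbol, local[f.comps[0]], f.dt, ndx, ndy)
            prod = arr if prod is None else prod * arr
        if scalar == 0.0:
            continue
        total += scalar * (prod if prod is not None else np.ones(shape))
    return total


def _projected_components(ev, term: LibraryTerm) -> list[np.ndarray]:
    if term.symclass == "scalar":
        return [ev.term_component(term, ())]
    if term.symclass == "vector":
        return [ev.term_component(term, (0,)), ev.term_component(term, (1,))]
    T00 = ev.term_component(term, (0, 0))
    T01 = ev.term_component(term, (0, 1))
    T10 = ev.term_component(term, (1, 0))
    if term.symclass == "sym":
        T11 = ev.term_component(term, (1, 1))
        return [0.5 * (T00 - T11), 0.5 * (T01 + T10)]
    if term.symclass == "antisym":
        return [0.5 * (T01 - T10)]
    raise ValueError(f"unknown symmetry class {term.symclass!r}")


def _uncontracted_tensor(ev, term: LibraryTerm) -> np.ndarray:
    """Tensor with every contracted pair opened, via one einsum.

    Output axes: grid + free indices + first occurrences of each bound label
    (sorted) + second occurrences (same order).
    """

    shape = ev.shape
    if term.is_constant:
        return np.ones(shape)
    free = list(term.free_labels())
    bound = sorted(
        {lab for f in term.factors for lab in f.labels() if lab not in free}
    )
    n_open = term.rank + 2 * len(bound)
    letters = "abcdefghijkl"[:n_open]
    seen: dict[str, int] = {}

    def _axis(lab):
        if lab in free:
            return free.index(lab)
        k = seen.get(lab, 0)
        seen[lab] = k + 1
        return term.rank + k * len(bound) + bound.index(lab)

    operands, scripts = [], []
    for f in term.factors:
        axes = [_axis(lab) for lab in f.labels()]
        if f.symbol == "eps":
            operands.append(LEVI_CIVITA)
            scripts.append("".join(letters[a] for a in axes))
            continue
        # factor tensor: grid x slot values; entry = field derivative with
        # comp = first slot, (ndx, ndy) = split of the deriv slots
        nslots = len(axes)
        B = np.empty(shape + (2,) * nslots)
        for vals in itertools.product((0, 1), repeat=nslots):
            ndx = sum(1 for v in vals[1:] if v == 0)
            ndy = (nslots - 1) - ndx
            B[(...,) + vals] = ev.factor_array(f.symbol, vals[0], f.dt, ndx, ndy)
        operands.append(B)
        scripts.append("z" + "".join(letters[a] for a in axes))
    sub = ",".join(scripts) + "->z" + letters
    flat = [
        op.reshape((-1,) + op.shape[3:]) if s.startswith("z") else op
        for op, s in zip(operands, scripts)
    ]
    out = np.einsum(sub, *flat, optimize=True)
    return float(term.sign) * out.reshape(shape + (2,) * n_open)


class _EvaluatorBase:
    def term_component(self, term, free_values=()):
        ckey = ("tc", term.key or repr(term), tuple(free_values))
        if ckey not in self._cache:
            self._cache[ckey] = _term_component(self, term, tuple(free_values))
        return self._cache[ckey]

    def projected_components(self, term):
        return _projected_components(self, term)

    def uncontracted_tensor(self, term):
        return _uncontracted_tensor(self, term)

    def full_tensor(self, term):
        if term.rank == 0:
            return self.term_component(term, ())
        comps = np.empty(self.shape + (2,) * term.rank)
        for values in itertools.product((0, 1), repeat=term.rank):
            comps[(...,) + values] = self.term_component(term, values)
        return comps


class TermEvaluator(_EvaluatorBase):
    """Evaluate tensor terms and their components on one field sequence."""

    def __init__(self, fields: FieldSequence, method: str = "fd"):
        if method not in ("fd", "spectral"):
            raise ValueError("method must be 'fd' or 'spectral'")
        self.fields = fields
        self.grid = fields.grid
        self.shape = fields.grid.shape
        self.method = method
        self._n_aligned = align_director(fields.n)
        self._cache: dict[tuple, np.ndarray] = {}

    def _diff(self, arr: np.ndarray, direction) -> np.ndarray:
        h = self.grid.spacing(direction)
        if self.method == "spectral":
            return spectral_diff(arr, direction, h)
        return central_diff(arr, direction, h)

    def factor_array(self, symbol: str, comp: int, dt: int, ndx: int, ndy: int) -> np.ndarray:
        """d_t^dt d_x^ndx d_y^ndy of field component ``comp`` on the grid."""

        key = (symbol, comp, dt, ndx, ndy)
        if key in self._cache:
            return self._cache[key]
        if dt + ndx + ndy == 0:
            base = self.fields.u[..., comp] if symbol == "u" else self._n_aligned[..., comp]
            arr = np.asarray(base, dtype=float)
        elif ndy > 0:
            arr = self._diff(self.factor_array(symbol, comp, dt, ndx, ndy - 1), 1)
        elif ndx > 0:
            arr = self._diff(self.factor_array(symbol, comp, dt, ndx - 1, ndy), 0)
        else:
            arr = self._diff(self.factor_array(symbol, comp, dt - 1, ndx, ndy), "t")
        self._cache[key] = arr
        return arr


class SlicedEvaluator(_EvaluatorBase):
    """Subdomain view into a full-grid evaluator (shared derivative caches,
    centered stencils across subdomain boundaries)."""

    def __init__(self, parent: TermEvaluator, slices, grid):
        self.parent = parent
        self.sl = tuple(slices)
        self.grid = grid
        self.shape = grid.shape
        self._cache: dict[tuple, np.ndarray] = {}

    def factor_array(self, symbol, comp, dt, ndx, ndy):
        return self.parent.factor_array(symbol, comp, dt, ndx, ndy)[self.sl]

    def term_component(self, term, free_values=()):
        return self.parent.term_component(term, tuple(free_values))[self.sl]
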