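"""Symbolic tensor term libraries for 2D nematic fields.

A *term* is a product of factors, each a (possibly differentiated) field
``u`` or ``n``, or the 2D Levi-Civita pseudotensor ``eps``.  Tensor slots
(component and derivative indices) carry string labels: the labels ``i`` and
``j`` are free (they set the tensor rank), every other label must occur
exactly twice and is summed over.  Libraries group terms of equal rank,
nematic parity (power of ``n`` mod 2) and rank-2 symmetry class, so that every
candidate relation ``sum_r c_r F^r = 0`` is consistent with rotation and
nematic symmetry.

Rank-2 terms are stored *unprojected*; the symmetric-traceless or
antisymmetric projection is applied at evaluation time.  Two raw terms that
coincide up to the i <-> j swap therefore canonicalize to the same key.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Factor",
    "LibraryTerm",
    "LibrarySpec",
    "TermLibrary",
    "canonicalize",
    "simplify_unit_director",
    "generate_library",
    "fingerprint_dedup",
    "pretty_print",
    "catalog",
]

_FREE = ("i", "j")
_BOUND = "abcdefgh"


@dataclass(frozen=True)
class Factor:
    """One factor of a tensor product term.

    ``derivs`` are spatial-derivative index labels (order is immaterial),
    ``comps`` the component labels: one for ``u``/``n``, two for ``eps``.
    ``dt`` is the time-derivative order.  ``eps`` carries no derivatives.
    """

    symbol: str
    dt: int = 0
    derivs: tuple[str, ...] = ()
    comps: tuple[str, ...] = ()

    def __post_init__(self):
        if self.symbol not in ("u", "n", "eps"):
            raise ValueError(f"unknown factor symbol {self.symbol!r}")
        if self.symbol == "eps" and (self.dt or self.derivs or len(self.comps) != 2):
            raise ValueError("eps carries two component labels and no derivatives")
        if self.symbol in ("u", "n") and len(self.comps) != 1:
            raise ValueError(f"{self.symbol} carries exactly one component label")
        if self.dt < 0:
            raise ValueError("negative time-derivative order")

    @property
    def order(self) -> int:
        """Total derivative order."""
        return self.dt + len(self.derivs)

    def labels(self) -> tuple[str, ...]:
        return self.comps + self.derivs


@dataclass(frozen=True)
class LibraryTerm:
    """Canonicalized product of factors with a deterministic string key."""

    factors: tuple[Factor, ...]
    rank: int
    symclass: str  # scalar | vector | sym | antisym
    sign: int = 1
    key: str = ""

    @property
    def parity(self) -> str:
        return "odd" if sum(f.symbol == "n" for f in self.factors) % 2 else "even"

    @property
    def n_fields(self) -> int:
        return sum(f.symbol in ("u", "n") for f in self.factors)

    @property
    def total_derivs(self) -> int:
        return sum(f.order for f in self.factors)

    @property
    def complexity(self) -> int:
        return self.n_fields + self.total_derivs

    @property
    def is_constant(self) -> bool:
        return len(self.factors) == 0

    def free_labels(self) -> tuple[str, ...]:
        return _FREE[: self.rank]

    def __str__(self) -> str:
        return pretty_print(self)


_CLASS_OF_RANK = {0: ("scalar",), 1: ("vector",), 2: ("sym", "antisym")}


def _check_indices(factors: tuple[Factor, ...], rank: int) -> None:
    counts: dict[str, int] = {}
    for f in factors:
        for lab in f.labels():
            counts[lab] = counts.get(lab, 0) + 1
    for lab in _FREE[:rank]:
        if counts.pop(lab, 0) != 1:
            raise ValueError(f"free index {lab!r} must appear exactly once")
    for lab, c in counts.items():
        if c != 2:
            raise ValueError(f"index {lab!r} appears {c} times; expected 2")


def _encodings(term: LibraryTerm):
    """All label-relabeled encodings of a term (for canonical minimization)."""

    rank, factors = term.rank, term.factors
    swaps = (False,) if rank < 2 else (False, True)
    for perm in itertools.permutations(range(len(factors))):
        ordered = [factors[p] for p in perm]
        deriv_orders = [list(itertools.permutations(f.derivs)) for f in ordered]
        eps_orders = [
            [(f.comps, 1), ((f.comps[1], f.comps[0]), -1)] if f.symbol == "eps" else [(f.comps, 1)]
            for f in ordered
        ]
        for dord in itertools.product(*deriv_orders):
            for cord in itertools.product(*eps_orders):
                for swap in swaps:
                    mapping: dict[str, str] = {}
                    if rank == 2 and swap:
                        mapping.update({"i": "j", "j": "i"})
                    sign = term.sign
                    if swap and term.symclass == "antisym":
                        sign = -sign
                    counter = 0
                    enc = []
                    ok = True
                    for f, ders, (comps, s) in zip(ordered, dord, cord):
                        sign *= s
                        labs = []
                        for lab in tuple(comps) + tuple(ders):
                            if lab in _FREE[:rank]:
                                labs.append(mapping.get(lab, lab))
                                continue
                            if lab not in mapping:
                                if counter >= len(_BOUND):
                                    ok = False
                                    break
                                mapping[lab] = _BOUND[counter]
                                counter += 1
                            labs.append(mapping[lab])
                        if not ok:
                            break
                        nc = len(comps)
                        enc.append((f.symbol, f.dt, tuple(labs[nc:]), tuple(labs[:nc])))
                    if ok:
                        yield tuple(enc), sign


def canonicalize(term: LibraryTerm) -> LibraryTerm:
    """Return the term with canonical index labels, factor order and key."""

    if term.symclass not in _CLASS_OF_RANK[term.rank]:
        raise ValueError(f"symmetry class {term.symclass!r} inconsistent with rank {term.rank}")
    _check_indices(term.factors, term.rank)
    if term.is_constant:
        return replace(term, key=f"1|{term.symclass}", sign=1)
    best = min(_encodings(term))
    enc, sign = best
    factors = tuple(Factor(symbol=s, dt=dt, derivs=d, comps=c) for s, dt, d, c in enc)
    key = f"{enc}|{term.symclass}"
    return LibraryTerm(factors=factors, rank=term.rank, symclass=term.symclass, sign=sign, key=key)


def simplify_unit_director(term: LibraryTerm) -> Optional[LibraryTerm]:
    """Rewrite using n.n = 1 and n.(single-derivative of n) = 0.

    Returns None when the term vanishes identically; the constant term 1 is
    returned (rank 0) when all factors cancel.
    """

    factors = list(term.factors)
    changed = True
    while changed:
        changed = False
        bare = [
            (k, f.comps[0])
            for k, f in enumerate(factors)
            if f.symbol == "n" and f.order == 0
        ]
        by_label: dict[str, list[int]] = {}
        for k, lab in bare:
            by_label.setdefault(lab, []).append(k)
        for lab, idxs in by_label.items():
            if len(idxs) == 2:  # n_a n_a = 1
                for k in sorted(idxs, reverse=True):
                    del factors[k]
                changed = True
                break
        if changed:
            continue
        # n_a (d n)_a = 0 for a single derivative (spatial or temporal)
        for k, lab in bare:
            for m, f in enumerate(factors):
                if m == k or f.symbol != "n" or f.order != 1:
                    continue
                if f.comps[0] == lab:
                    return None
    out = LibraryTerm(
        factors=tuple(factors), rank=term.rank, symclass=term.symclass, sign=term.sign
    )
    return canonicalize(out)


# ---------------------------------------------------------------------------
# library generation


_DEFAULT_MAX_FACTORS = {"scalar": 3, "vector": 4, "sym": 5, "antisym": 3}
# smallest fields+derivatives budget per class that still covers every term
# of the target relations (e.g. n_i n_a n_b d_a u_b needs 5; its Qbar-contracted
# rank-2 analogue needs 6)
_DEFAULT_MAX_COMPLEXITY = {"scalar": 5, "vector": 5, "sym": 6, "antisym": 5}


@dataclass
class LibrarySpec:
    """Bounds of the term grammar for one library."""

    rank: int
    parity: str  # even | odd
    symclass: str
    max_factors: Optional[int] = None
    max_space_derivs: int = 2
    max_time_derivs: int = 1
    max_complexity: Optional[int] = None  # fields + total derivative order
    include_constant: bool = True
    chiral: bool = False  # admit eps-bearing (mirror-breaking) terms
    raw_limit: int = 10_000

    def __post_init__(self):
        if self.symclass not in _CLASS_OF_RANK[self.rank]:
            raise ValueError(f"symmetry class {self.symclass!r} inconsistent with rank {self.rank}")
        if self.parity not in ("even", "odd"):
            raise ValueError("parity must be 'even' or 'odd'")
        if self.max_factors is None:
            self.max_factors = _DEFAULT_MAX_FACTORS[self.symclass]
        if self.max_complexity is None:
            self.max_complexity = _DEFAULT_MAX_COMPLEXITY[self.symclass]
        if min(self.max_factors, self.max_space_derivs + 1, self.max_time_derivs + 1) < 1:
            raise ValueError("bounds must be positive")

    def to_dict(self) -> dict:
        return dict(
            rank=self.rank, parity=self.parity, symclass=self.symclass,
            max_factors=self.max_factors, max_space_derivs=self.max_space_derivs,
            max_time_derivs=self.max_time_derivs, max_complexity=self.max_complexity,
            include_constant=self.include_constant, chiral=self.chiral,
        )


@dataclass
class TermLibrary:
    """Ordered, deduplicated term list together with its generating spec."""

    spec: LibrarySpec
    terms: list[LibraryTerm]
    removed: list[str] = field(default_factory=list)

    def keys(self) -> list[str]:
        return [t.key for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)

    def subset(self, indices: Iterable[int]) -> "TermLibrary":
        return TermLibrary(
            spec=self.spec, terms=[self.terms[k] for k in indices], removed=list(self.removed)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.to_dict(),
                "terms": [_term_to_dict(t) for t in self.terms],
                "removed": self.removed,
            },
            indent=1,
        )

    @staticmethod
    def from_json(text: str) -> "TermLibrary":
        data = json.loads(text)
        spec = LibrarySpec(**data["spec"])
        terms = [_term_from_dict(d) for d in data["terms"]]
        return TermLibrary(spec=spec, terms=terms, removed=list(data.get("removed", [])))


def _term_to_dict(t: LibraryTerm) -> dict:
    return {
        "factors": [
            {"symbol": f.symbol, "dt": f.dt, "derivs": list(f.derivs), "comps": list(f.comps)}
            for f in t.factors
        ],
        "rank": t.rank,
        "symclass": t.symclass,
        "sign": t.sign,
        "pretty": pretty_print(t),
    }


def _term_from_dict(d: dict) -> LibraryTerm:
    factors = tuple(
        Factor(symbol=f["symbol"], dt=f["dt"], derivs=tuple(f["derivs"]), comps=tuple(f["comps"]))
        for f in d["factors"]
    )
    return canonicalize(
        LibraryTerm(factors=factors, rank=d["rank"], symclass=d["symclass"], sign=d.get("sign", 1))
    )


def _compositions(total: int, parts: int, cap: int):
    if parts == 0:
        if total == 0:
            yield ()
        return
    for first in range(min(total, cap) + 1):
        for rest in _compositions(total - first, parts - 1, cap):
            yield (first,) + rest


def _pairings(slots: list):
    if not slots:
        yield []
        return
    first = slots[0]
    for k in range(1, len(slots)):
        rest = slots[1:k] + slots[k + 1 :]
        for sub in _pairings(rest):
            yield [(first, slots[k])] + sub


def generate_library(spec: LibrarySpec) -> TermLibrary:
    """Exhaustively enumerate, canonicalize, simplify and deduplicate terms.

    Every product of u/n factors within the grammar bounds is contracted to
    the target rank in all inequivalent ways.  Unit-director identities
    (n.n = 1, n.dn = 0) are applied; numerically dependent leftovers are
    handled separately by :func:`fingerprint_dedup`.
    """

    parity_bit = 0 if spec.parity == "even" else 1
    seen: dict[str, LibraryTerm] = {}
    removed: list[str] = []
    raw_count = 0
    for nf in range(1, spec.max_factors + 1):
        for nn in range(nf + 1):
            nu = nf - nn
            if nn % 2 != parity_bit:
                continue
            symbols = ["u"] * nu + ["n"] * nn
            eps_options = [0, 1] if spec.chiral else [0]
            for neps in eps_options:
                for ndt in range(spec.max_time_derivs + 1):
                    for nds in range(spec.max_space_derivs + 1):
                        if nf + ndt + nds > spec.max_complexity:
                            continue
                        for dts in _compositions(ndt, nf, spec.max_time_derivs):
                            for dss in _compositions(nds, nf, spec.max_space_derivs):
                                raw_count += _emit_terms(
                                    spec, symbols, neps, dts, dss, seen, removed
                                )
                                if raw_count > spec.raw_limit:
                                    raise ValueError(
                                        "grammar bounds generate more than "
                                        f"{spec.raw_limit} raw terms; tighten the spec"
                                    )
    terms = sorted(seen.values(), key=lambda t: (t.complexity, t.key))
    if spec.rank == 0 and spec.include_constant and spec.parity == "even":
        const = canonicalize(LibraryTerm(factors=(), rank=0, symclass="scalar"))
        if const.key not in {t.key for t in terms}:
            terms.insert(0, const)
    return TermLibrary(spec=spec, terms=terms, removed=removed)


def _emit_terms(spec, symbols, neps, dts, dss, seen, removed) -> int:
    """Enumerate index assignments for one factor/derivative multiset."""

    count = 0
    rank = spec.rank
    # slot list: per factor a component slot plus dss[k] derivative slots;
    # an optional eps factor contributes two component slots
    slots = []
    for k in range(len(symbols)):
        slots.append(("c", k, 0))
        for d in range(dss[k]):
            slots.append(("d", k, d))
    for e in range(neps):
        slots.append(("e", len(symbols), 0))
        slots.append(("e", len(symbols), 1))
    m = len(slots)
    if (m - rank) % 2 or m < rank:
        return 0
    for free_slots in itertools.permutations(range(m), rank):
        remaining = [s for s in range(m) if s not in free_slots]
        for pairs in _pairings(remaining):
            labels = {}
            for fi, s in enumerate(free_slots):
                labels[s] = _FREE[fi]
            for pi, (s1, s2) in enumerate(pairs):
                labels[s1] = labels[s2] = _BOUND[pi]
            factors = []
            for k, sym in enumerate(symbols):
                comp = labels[slots.index(("c", k, 0))]
                ders = tuple(
                    labels[slots.index(("d", k, d))] for d in range(dss[k])
                )
                factors.append(Factor(symbol=sym, dt=dts[k], derivs=ders, comps=(comp,)))
            if neps:
                e1 = labels[slots.index(("e", len(symbols), 0))]
                e2 = labels[slots.index(("e", len(symbols), 1))]
                if e1 == e2:
                    continue  # eps_aa = 0
                factors.append(Factor(symbol="eps", comps=(e1, e2)))
            count += 1
            term = canonicalize(
                LibraryTerm(factors=tuple(factors), rank=rank, symclass=spec.symclass)
            )
            simp = simplify_unit_director(term)
            if simp is None:
                removed.append(f"identically zero: {pretty_print(term)}")
                continue
            if simp.is_constant and not (spec.rank == 0 and spec.include_constant):
                continue
            if simp.key not in seen:
                seen[simp.key] = simp
    return count


# ---------------------------------------------------------------------------
# numeric deduplication


def fingerprint_dedup(
    library: TermLibrary,
    probes,
    n_samples: int = 200,
    seed: int = 0,
    rel_tol: float = 1e-7,
    zero_tol: float = 1e-9,
) -> TermLibrary:
    """Remove terms whose numeric fingerprints are linearly dependent.

    Each term is evaluated on several independent smooth random field sets at
    ``n_samples`` grid points; a term whose fingerprint vector lies (within
    tolerance) in the span of the retained earlier terms, or is numerically
    zero, is dropped and logged.  This catches identities the symbolic
    simplifier does not encode (e.g. contractions related by A + Omega =
    grad u, or Laplacian/|grad n|^2 integration-by-parts pairs).
    """

    from .evaluation import TermEvaluator

    rng = np.random.default_rng(seed)
    if len(probes) < 1:
        raise ValueError("need at least one probe field set")
    columns = []
    for term in library.terms:
        pieces = []
        for probe in probes:
            ev = TermEvaluator(probe, method="spectral" if probe.periodic else "fd")
            comps = ev.projected_components(term)
            for arr in comps:
                if not np.all(np.isfinite(arr)):
                    raise ValueError("probe evaluation produced non-finite values")
                pieces.append(arr.ravel())
        columns.append(np.concatenate(pieces))
    total = len(columns[0])
    idx = rng.choice(total, size=min(n_samples * len(probes), total), replace=False)
    F = np.stack([c[idx] for c in columns], axis=1)
    norms = np.linalg.norm(F, axis=0)
    scale = norms.max() if norms.size else 1.0
    kept: list[int] = []
    removed = list(library.removed)
    basis = np.zeros((F.shape[0], 0))
    for r, term in enumerate(library.terms):
        col = F[:, r]
        if norms[r] <= zero_tol * scale:
            removed.append(f"numerically zero: {pretty_print(term)}")
            continue
        if basis.shape[1]:
            coef, *_ = np.linalg.lstsq(basis, col, rcond=None)
            resid = col - basis @ coef
        else:
            resid = col
        if np.linalg.norm(resid) <= rel_tol * norms[r]:
            removed.append(f"linearly dependent: {pretty_print(term)}")
            continue
        kept.append(r)
        basis = np.column_stack([basis, col / norms[r]])
    out = library.subset(kept)
    out.removed = removed
    return out


# ---------------------------------------------------------------------------
# rendering


def _factor_str(f: Factor) -> str:
    if f.symbol == "eps":
        return f"eps_{''.join(f.comps)}"
    pre = "dt " * f.dt + "".join(f"d_{d} " for d in f.derivs)
    return f"{pre}{f.symbol}_{f.comps[0]}"


def pretty_print(obj) -> str:
    """Index-notation rendering of a term (or of a Relation, see
    :mod:`spider2d.sparse_regression` which delegates here per term)."""

    if isinstance(obj, LibraryTerm):
        if obj.is_constant:
            core = "1"
        else:
            core = " ".join(_factor_str(f) for f in obj.factors)
            if obj.sign < 0:
                core = f"-({core})"
        if obj.symclass == "sym":
            return f"[{core}]_ST"
        if obj.symclass == "antisym":
            return f"[{core}]_AS"
        return core
    raise TypeError(f"cannot pretty-print {type(obj)!r}")


# ---------------------------------------------------------------------------
# named terms used throughout tests, fixtures and reporting


def _t(factors, rank, symclass) -> LibraryTerm:
    return canonicalize(LibraryTerm(factors=tuple(factors), rank=rank, symclass=symclass))


class catalog:
    """Frequently referenced canonical terms."""

    @staticmethod
    def div_u() -> LibraryTerm:  # d_a u_a
        return _t([Factor("u", derivs=("a",), comps=("a",))], 0, "scalar")

    @staticmethod
    def const() -> LibraryTerm:  # 1
        return _t([], 0, "scalar")

    @staticmethod
    def nnA() -> LibraryTerm:  # n_a n_b d_a u_b  (= Qbar:Abar on solenoidal data)
        return _t(
            [
                Factor("n", comps=("a",)),
                Factor("n", comps=("b",)),
                Factor("u", derivs=("a",), comps=("b",)),
            ],
            0,
            "scalar",
        )

    @staticmethod
    def dt_n() -> LibraryTerm:  # dt n_i
        return _t([Factor("n", dt=1, comps=("i",))], 1, "vector")

    @staticmethod
    def advect_n() -> LibraryTerm:  # u_a d_a n_i
        return _t(
            [Factor("u", comps=("a",)), Factor("n", derivs=("a",), comps=("i",))], 1, "vector"
        )

    @staticmethod
    def gradu_n_free_deriv() -> LibraryTerm:  # d_i u_a n_a
        return _t(
            [Factor("u", derivs=("i",), comps=("a",)), Factor("n", comps=("a",))], 1, "vector"
        )

    @staticmethod
    def gradu_n_free_comp() -> LibraryTerm:  # d_a u_i n_a
        return _t(
            [Factor("u", derivs=("a",), comps=("i",)), Factor("n", comps=("a",))], 1, "vector"
        )

    @staticmethod
    def n_nAn() -> LibraryTerm:  # n_i n_a n_b d_a u_b
        return _t(
            [
                Factor("n", comps=("i",)),
                Factor("n", comps=("a",)),
                Factor("n", comps=("b",)),
                Factor("u", derivs=("a",), comps=("b",)),
            ],
            1,
            "vector",
        )

    @staticmethod
    def n_divu() -> LibraryTerm:  # n_i d_a u_a
        return _t(
            [Factor("n", comps=("i",)), Factor("u", derivs=("a",), comps=("a",))], 1, "vector"
        )

    @staticmethod
    def nn() -> LibraryTerm:  # n_i n_j (projects to Qbar)
        return _t([Factor("n", comps=("i",)), Factor("n", comps=("j",))], 2, "sym")

    @staticmethod
    def nn_nnA() -> LibraryTerm:  # n_i n_j n_a n_b d_a u_b (projects to (Qbar:Abar) Qbar ...)
        return _t(
            [
                Factor("n", comps=("i",)),
                Factor("n", comps=("j",)),
                Factor("n", comps=("a",)),
                Factor("n", comps=("b",)),
                Factor("u", derivs=("a",), comps=("b",)),
            ],
            2,
            "sym",
        )

    @staticmethod
    def nn_divu() -> LibraryTerm:  # n_i n_j d_a u_a
        return _t(
            [
                Factor("n", comps=("i",)),
                Factor("n", comps=("j",)),
                Factor("u", derivs=("a",), comps=("a",)),
            ],
            2,
            "sym",
        )

    @staticmethod
    def eps_nn() -> LibraryTerm:  # eps_ab n_a n_b  (identically zero)
        return _t(
            [
                Factor("eps", comps=("a", "b")),
                Factor("n", comps=("a",)),
                Factor("n", comps=("b",)),
            ],
            0,
            "scalar",
        )

    @staticmethod
    def n_dtn() -> LibraryTerm:  # n_a dt n_a (identically zero; kept for tests)
        return LibraryTerm(
            factors=(
                Factor("n", comps=("a",)),
                Factor("n", dt=1, comps=("a",)),
            ),
            rank=0,
            symclass="scalar",
            key="raw:n_dtn",
        )
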