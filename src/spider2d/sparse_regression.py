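"""Sparse identification of relations from a weak-form feature matrix.

The workhorse is sequentially thresholded regression (STR) on the
constrained least-squares problem G c = 0, ||c||_2 = 1, solved at every step
by the right singular vector of the active columns for the smallest singular
value.  The least significant term (smallest ||c_r G^r||_2) is discarded
until the relative residual jumps by more than a factor gamma.  Multiple
relations (and identities) coexisting in one library are extracted by
iterated STR with pruning; results are validated by exhaustive combinatorial
search and their coefficients are given half-sample resampling uncertainties.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .term_library import TermLibrary, pretty_print

logger = logging.getLogger(__name__)

__all__ = [
    "Relation",
    "DiscoveryConfig",
    "DiscoveryReport",
    "min_singular_vector",
    "residual_eta",
    "str_solve",
    "discover_all",
    "classify_identity",
    "combinatorial_search",
    "estimate_uncertainty",
]


@dataclass
class Relation:
    """A sparse relation sum_r c_r F^r = 0 with unit-norm coefficients."""

    support: list[str]            # term keys
    indices: list[int]            # column indices into the feature matrix
    coefficients: np.ndarray      # ||c|| = 1
    eta: float
    kind: str                     # multi-term | single-term
    classification: str = "unclassified"
    coeff_mean: Optional[np.ndarray] = None
    coeff_sd: Optional[np.ndarray] = None
    pretty: str = ""

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if abs(np.linalg.norm(self.coefficients) - 1.0) > 1e-12:
            raise ValueError("coefficients must have unit 2-norm")
        if self.eta < 0 or len(self.support) < 1:
            raise ValueError("invalid relation")

    def coefficient_for(self, key: str) -> float:
        return float(self.coefficients[self.support.index(key)])

    def percent_sd(self) -> Optional[np.ndarray]:
        if self.coeff_mean is None:
            return None
        denom = np.where(np.abs(self.coeff_mean) > 0, np.abs(self.coeff_mean), 1.0)
        return 100.0 * self.coeff_sd / denom

    def to_dict(self) -> dict:
        return {
            "support": self.support,
            "coefficients": self.coefficients.tolist(),
            "eta": self.eta,
            "kind": self.kind,
            "classification": self.classification,
            "coeff_mean": None if self.coeff_mean is None else self.coeff_mean.tolist(),
            "coeff_sd": None if self.coeff_sd is None else self.coeff_sd.tolist(),
            "pretty": self.pretty,
        }


@dataclass
class DiscoveryConfig:
    gamma: float = 1.15               # residual-jump stopping factor
    stop_residual: float = 0.4        # full-library residual halting pruning
    accept_residual: float = 0.1      # max eta for an accepted relation
    identity_cutoff: float = 1e-6     # probe residual below which = identity
    eta_floor: float = 1e-12          # jumps between sub-floor residuals ignored
    n_resample: int = 100
    resample_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 1.0:
            raise ValueError("gamma must exceed 1")
        if min(self.stop_residual, self.accept_residual, self.identity_cutoff) <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class DiscoveryReport:
    relations: list[Relation] = field(default_factory=list)
    traces: list[list] = field(default_factory=list)          # per STR run
    pruning: list[str] = field(default_factory=list)
    full_residuals: list[float] = field(default_factory=list)
    config: Optional[DiscoveryConfig] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "relations": [r.to_dict() for r in self.relations],
                "pruning": self.pruning,
                "full_residuals": self.full_residuals,
                "traces": [
                    [
                        {"support": list(s), "eta": e}
                        for (s, _c, e) in tr
                    ]
                    for tr in self.traces
                ],
                "config": None if self.config is None else vars(self.config),
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# core linear algebra


def min_singular_vector(G: np.ndarray) -> np.ndarray:
    """Unit vector minimizing ||G c||_2 (right singular vector of the
    smallest singular value); sign fixed so the largest-|entry| is positive."""

    G = np.asarray(G, dtype=float)
    if G.size == 0:
        raise ValueError("empty matrix")
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite entries in G")
    _, s, Vh = np.linalg.svd(G, full_matrices=False)
    if len(s) > 1 and s[-2] > 0 and (s[-2] - s[-1]) / s[-2] < 1e-12:
        logger.warning(
            "degenerate smallest singular value (gap below 1e-12); "
            "returning the SVD's last right singular vector"
        )
    c = Vh[-1]
    k = int(np.argmax(np.abs(c)))
    if c[k] < 0:
        c = -c
    return c


def term_magnitudes(G: np.ndarray, c: np.ndarray) -> np.ndarray:
    """||c_r G^r||_2 per active column."""

    return np.abs(c) * np.linalg.norm(G, axis=0)


def residual_eta(
    G: np.ndarray,
    c: np.ndarray,
    kind: str = "multi-term",
    xi: Optional[float] = None,
) -> float:
    """eta = ||G c||_2 / Xi.

    Multi-term: Xi = max_r ||c_r G^r||_2 (the largest term).  Single-term:
    Xi is the norm of the corresponding uncontracted tensor integrals and
    must be supplied.
    """

    num = float(np.linalg.norm(G @ c))
    if kind == "single-term":
        if xi is None or xi == 0:
            raise ValueError("degenerate normalization")
        return num / float(xi)
    mags = term_magnitudes(G, c)
    scale = float(mags.max()) if mags.size else 0.0
    if scale == 0:
        raise ValueError("degenerate normalization")
    return num / scale


def _multi_eta(G: np.ndarray, c: np.ndarray) -> float:
    """Multi-term eta, infinite when the normalization degenerates (all
    active terms numerically zero)."""

    try:
        return residual_eta(G, c)
    except ValueError:
        return float("inf")


def _single_etas(G: np.ndarray, xi) -> np.ndarray:
    """Single-term eta per column: ||G^r|| / xi_r.

    A term whose uncontracted scale xi vanishes is identically zero on the
    data (e.g. any time derivative of a steady field), so its relation holds
    trivially: eta 0.  Its weak column may still carry quadrature dust, which
    must not masquerade as structure.
    """

    col_norms = np.linalg.norm(np.asarray(G, dtype=float), axis=0)
    xi = np.asarray(xi, dtype=float)
    out = np.full(col_norms.shape, np.inf)
    ok = xi > 1e-14 * (xi.max() if xi.size else 0.0)
    out[ok] = col_norms[ok] / xi[ok]
    out[~ok] = 0.0
    out[col_norms == 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# sequentially thresholded regression


def str_solve(
    G: np.ndarray,
    xi: Sequence[float],
    gamma: float = 1.15,
    eta_floor: float = 1e-12,
    columns: Optional[Sequence[int]] = None,
):
    """One STR run over the given columns of G.

    Returns ``(trace, relation)``: the trace holds (active support, c, eta)
    per iteration; the selected relation is the last model before the
    residual jumped by more than ``gamma`` (jumps between residuals below
    ``eta_floor`` are numerical noise on exact relations and are ignored),
    or the single surviving term re-normalized by its uncontracted scale.
    """

    xi = np.asarray(xi, dtype=float)
    active = list(range(G.shape[1])) if columns is None else list(columns)
    if not active:
        raise ValueError("no columns to regress")
    # single-term residual of every column; the effective residual of a model
    # is the better of the multi-term eta and the best single-term eta still
    # active, so exact one-term relations (near-zero columns, for which the
    # multi-term normalization saturates at 1) do not derail the jump rule
    single_eta = _single_etas(G, xi)
    trace = []
    while True:
        Ga = G[:, active]
        c = min_singular_vector(Ga)
        if len(active) == 1:
            eta = float(single_eta[active[0]])
            trace.append((tuple(active), c.copy(), eta))
            break
        eta = min(_multi_eta(Ga, c), float(single_eta[active].min()))
        trace.append((tuple(active), c.copy(), eta))
        mags = term_magnitudes(Ga, c)
        # tie-break: among minimal magnitudes drop the latest column
        order = np.lexsort((-np.asarray(active), mags))
        drop_local = int(order[0])
        if len(trace) >= 2:
            prev = trace[-2][2]
            if eta > gamma * prev and eta > eta_floor:
                break
        del active[drop_local]
    # selection: if the loop ended by residual jump, the previous model wins
    sel = trace[-1]
    if len(trace) >= 2 and sel[2] > gamma * trace[-2][2] and sel[2] > eta_floor:
        sel = trace[-2]
    support, c, eta = sel
    # parsimony refinement: if one member alone already achieves the selected
    # model's residual (its column is a relation by itself), the extra terms
    # carry no information - prefer the single-term model
    if len(support) > 1:
        member = min(support, key=lambda r: single_eta[r])
        if single_eta[member] <= eta:
            support, c = (member,), np.array([1.0])
    support = list(support)
    kind = "single-term" if len(support) == 1 else "multi-term"
    if kind == "single-term":
        eta = float(single_eta[support[0]])
    return trace, (support, c, eta, kind)


def discover_all(
    library: TermLibrary,
    G: np.ndarray,
    xi: Sequence[float],
    config: Optional[DiscoveryConfig] = None,
) -> DiscoveryReport:
    """Iterated STR with pruning: find all parsimonious relations in G.

    After each accepted relation its largest-magnitude term is removed from
    the library and STR restarts, until the residual of the full pruned
    library exceeds ``stop_residual`` or no terms remain.  Candidates whose
    residual exceeds ``accept_residual`` are rejected but still pruned, so
    the search always terminates.
    """

    config = config or DiscoveryConfig()
    report = DiscoveryReport(config=config)
    keys = library.keys()
    active = list(range(G.shape[1]))
    single_eta = _single_etas(G, xi)
    exact_single = 1e-8  # single-term residual level marking an exact relation
    while active:
        Ga = G[:, active]
        if len(active) == 1:
            full_eta = float(single_eta[active[0]])
        else:
            c_full = min_singular_vector(Ga)
            full_eta = min(_multi_eta(Ga, c_full), float(single_eta[active].min()))
        report.full_residuals.append(full_eta)
        if full_eta > config.stop_residual:
            report.pruning.append(
                f"stopped: full-library residual {full_eta:.3g} exceeds "
                f"{config.stop_residual}"
            )
            break
        # machine-precision single-term relations (numerically zero columns)
        # are emitted directly: STR's magnitude ordering is meaningless there
        best = int(min(active, key=lambda r: single_eta[r]))
        if single_eta[best] <= exact_single:
            rel = Relation(
                support=[keys[best]],
                indices=[best],
                coefficients=np.array([1.0]),
                eta=float(single_eta[best]),
                kind="single-term",
                pretty=render_relation([library.terms[best]], [1.0]),
            )
            report.relations.append(rel)
            report.pruning.append(
                f"accepted exact single-term {rel.pretty} "
                f"(eta={rel.eta:.3g}); pruned {keys[best]}"
            )
            active.remove(best)
            continue
        trace, (support, c, eta, kind) = str_solve(
            G, xi, gamma=config.gamma, eta_floor=config.eta_floor, columns=active
        )
        report.traces.append(trace)
        mags = term_magnitudes(G[:, support], c)
        largest = support[int(np.argmax(mags))]
        if eta <= config.accept_residual:
            rel = Relation(
                support=[keys[r] for r in support],
                indices=list(support),
                coefficients=c / np.linalg.norm(c),
                eta=eta,
                kind=kind,
                pretty=render_relation([library.terms[r] for r in support], c),
            )
            report.relations.append(rel)
            report.pruning.append(
                f"accepted {rel.pretty} (eta={eta:.3g}); pruned {keys[largest]}"
            )
        else:
            report.pruning.append(
                f"rejected candidate with eta={eta:.3g}; pruned {keys[largest]}"
            )
        active.remove(largest)
    return report


# ---------------------------------------------------------------------------
# classification, validation, uncertainty


def classify_identity(
    relation: Relation,
    library: TermLibrary,
    probes,
    cutoff: float = 1e-6,
    n_samples: int = 400,
    seed: int = 0,
) -> str:
    """Label a relation 'identity' or 'physical' via random smooth probes.

    The relation's terms are re-evaluated pointwise on band-limited random
    synthetic fields (spectral derivatives).  A relation that still holds
    there (residual below ``cutoff`` relative to its largest term) is an
    identity of vector calculus / the unit director, not physics.
    """

    from .evaluation import TermEvaluator

    terms = {t.key: t for t in library.terms}
    rng = np.random.default_rng(seed)
    cols = []
    scales = []
    for key in relation.support:
        term = terms[key]
        pieces, spieces = [], []
        for probe in probes:
            ev = TermEvaluator(probe, method="spectral" if probe.periodic else "fd")
            for arr in ev.projected_components(term):
                pieces.append(arr.ravel())
            unc = ev.uncontracted_tensor(term)
            grid_size = int(np.prod(probe.grid.shape))
            spieces.append(unc.reshape(grid_size, -1))
        cols.append(np.concatenate(pieces))
        scales.append(np.concatenate(spieces, axis=0))
    npts = len(cols[0])
    idx = rng.choice(npts, size=min(n_samples, npts), replace=False)
    F = np.stack([c[idx] for c in cols], axis=1)
    if F.shape[1] == 1:
        xi = float(np.linalg.norm(scales[0]))
        xi *= math.sqrt(len(idx) / scales[0].shape[0])
        eta = float(np.linalg.norm(F[:, 0]) / xi) if xi > 0 else np.inf
    else:
        c = min_singular_vector(F)
        eta = residual_eta(F, c)
    return "identity" if eta < cutoff else "physical"


def combinatorial_search(
    G: np.ndarray,
    xi: Sequence[float],
    K: int,
    budget: int = 10 ** 6,
    columns: Optional[Sequence[int]] = None,
):
    """Exact minimizer of eta over all K-term supports (STR validation)."""

    cols = list(range(G.shape[1])) if columns is None else list(columns)
    # terms numerically zero on the data are their own (trivial) relations;
    # including them in K-term subsets only compares quadrature dust
    pre_single = _single_etas(G, xi)
    cols = [r for r in cols if pre_single[r] > 0.0]
    if not cols:
        raise ValueError("no nonzero columns to search")
    N = len(cols)
    n_combos = math.comb(N, K)
    if n_combos > budget:
        raise ValueError(
            f"C({N},{K}) = {n_combos} exceeds the budget {budget}; use STR "
            "plus greedy augmentation instead"
        )
    best = None
    single = _single_etas(G, xi)
    for combo in itertools.combinations(cols, K):
        sub = G[:, list(combo)]
        if K == 1:
            c = np.array([1.0])
            eta = float(single[combo[0]])
        else:
            c = min_singular_vector(sub)
            eta = _multi_eta(sub, c)
        if best is None or eta < best[2]:
            best = (list(combo), c, eta)
    return best


def estimate_uncertainty(
    G: np.ndarray,
    support: Sequence[int],
    n_resample: int = 100,
    fraction: float = 0.5,
    seed: int = 0,
):
    """Half-sample coefficient statistics for a fixed sparse support.

    The coefficients are re-fit (minimum singular vector) on ``n_resample``
    row subsamples, signs aligned with the full-matrix solution; returns
    (mean, sd) arrays over the draws.
    """

    rng = np.random.default_rng(seed)
    sub = G[:, list(support)]
    c0 = min_singular_vector(sub)
    nrows = G.shape[0]
    take = max(len(support) + 1, int(round(fraction * nrows)))
    draws = []
    skipped = 0
    for _ in range(n_resample):
        rows = rng.choice(nrows, size=take, replace=False)
        Gs = sub[rows]
        s = np.linalg.svd(Gs, compute_uv=False)
        if len(s) > 1 and s[0] > 0 and s[-2] / s[0] < 1e-12:
            skipped += 1
            continue
        c = min_singular_vector(Gs)
        if np.dot(c, c0) < 0:
            c = -c
        draws.append(c)
    if skipped:
        logger.info("estimate_uncertainty: skipped %d rank-deficient draws", skipped)
    if not draws:
        raise ValueError("all resampling draws were rank-deficient")
    draws = np.asarray(draws)
    return draws.mean(axis=0), draws.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# rendering


def render_relation(terms, coefficients) -> str:
    """Human-readable ``c_1 T_1 + ... = 0`` string (3 significant digits)."""

    parts = []
    for t, c in zip(terms, coefficients):
        parts.append(f"{c:+.3g} {pretty_print(t)}")
    return " ".join(parts) + " = 0"
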