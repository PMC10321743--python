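"""Weight functions, integration by parts, quadrature and feature assembly."""

import numpy as np
import pytest

from spider2d import synthetic_fields as sf
from spider2d.evaluation import TermEvaluator
from spider2d.field_data import FieldGrid, FieldSequence, Mask, unit_mask
from spider2d.term_library import Factor, LibrarySpec, LibraryTerm, TermLibrary, canonicalize, catalog
from spider2d.weak_form import (
    Subdomain,
    WeakFormConfig,
    WeightSpec,
    build_feature_matrix,
    envelope_1d,
    integrate_term,
    make_weight,
    sample_subdomains,
    transfer_derivatives,
)

ENVELOPE_1D_INTEGRAL = 256.0 / 315.0  # integral of (1 - x^2)^4 over [-1, 1]


def _grid_for(sub_extent=(20, 20, 20), dx=0.1):
    p = max(sub_extent)
    return FieldGrid(nx=p, ny=p, nt=p, dx=dx, dy=dx, dt=dx)


class TestWeights:
    def test_envelope_and_derivatives_vanish_on_boundary(self):
        grid = _grid_for((21, 21, 21))
        sub = Subdomain(start=(0, 0, 0), extent=(21, 21, 21))
        spec = WeightSpec(tau=4, modulation="none")
        wt = make_weight(sub, spec, grid, orders={(0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 1, 1)})
        w = wt.w
        assert abs(w[10, 10, 10] - 1.0) < 1e-12  # center value
        for key, arr in wt.derivs.items():
            assert np.abs(arr[0]).max() < 1e-10, key   # t boundary
            assert np.abs(arr[:, 0]).max() < 1e-10     # y boundary
            assert np.abs(arr[..., -1]).max() < 1e-10  # x boundary
        assert 0.0 <= w.max() <= 1.0 + 1e-12

    def test_envelope_cube_integral_closed_form(self):
        # trapezoid at 55^3 points matches (256/315)^3 to < 1e-4 relative
        grid = FieldGrid(nx=55, ny=55, nt=55, dx=2 / 54, dy=2 / 54, dt=2 / 54)
        sub = Subdomain(start=(0, 0, 0), extent=(55, 55, 55))
        wt = make_weight(sub, WeightSpec(tau=4), grid)
        val = wt.integrate(np.ones(sub.extent))
        exact = ENVELOPE_1D_INTEGRAL ** 3  # reference-cube volume = physical here
        assert abs(val - exact) / exact < 1e-4

    def test_zero_mask_kills_weight(self):
        grid = _grid_for()
        sub = Subdomain(start=(0, 0, 0), extent=(20, 20, 20))
        mask = unit_mask(grid)
        mask.psi = np.zeros(grid.shape)
        wt = make_weight(sub, WeightSpec(tau=4), grid, mask=mask)
        assert np.abs(wt.w).max() == 0.0

    def test_odd_modulation_annihilates_even_integrand(self):
        grid = FieldGrid(nx=41, ny=21, nt=21, dx=0.05, dy=0.1, dt=0.1)
        sub = Subdomain(start=(0, 0, 0), extent=(21, 21, 41))
        spec = WeightSpec(tau=4, modulation="x", phase=np.pi / 2)  # sin(pi x)
        wt = make_weight(sub, spec, grid)
        val = wt.integrate(np.ones(sub.extent))  # even in x
        ref = make_weight(sub, WeightSpec(tau=4), grid).integrate(np.ones(sub.extent))
        assert abs(val) < 1e-10 * abs(ref)


class TestSubdomains:
    def test_single_placement_grid(self):
        grid = FieldGrid(nx=12, ny=12, nt=12, dx=1, dy=1, dt=1)
        subs = sample_subdomains(grid, 5, extents=(12, 12, 12), seed=0)
        assert all(s.start == (0, 0, 0) for s in subs)

    def test_seed_reproducibility(self):
        grid = FieldGrid(nx=64, ny=64, nt=64, dx=1, dy=1, dt=1)
        a = sample_subdomains(grid, 20, extents=(16, 16, 16), seed=3)
        b = sample_subdomains(grid, 20, extents=(16, 16, 16), seed=3)
        c = sample_subdomains(grid, 20, extents=(16, 16, 16), seed=4)
        assert [s.start for s in a] == [s.start for s in b]
        assert [s.start for s in a] != [s.start for s in c]

    def test_centers_uniform(self):
        from scipy.stats import chisquare

        grid = FieldGrid(nx=200, ny=12, nt=12, dx=1, dy=1, dt=1)
        subs = sample_subdomains(grid, 2000, extents=(40, 12, 12), seed=1)
        starts = np.array([s.start[2] for s in subs])
        hist, _ = np.histogram(starts, bins=8, range=(0, 161))
        assert chisquare(hist).pvalue > 0.01

    def test_extent_exceeding_grid_is_clamped_with_warning(self):
        grid = FieldGrid(nx=40, ny=40, nt=40, dx=1, dy=1, dt=1)
        with pytest.warns(UserWarning, match="exceeds grid"):
            subs = sample_subdomains(grid, 1, extents=(54, 54, 65), seed=0)
        assert all(e <= 40 for e in subs[0].extent)

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError):
            Subdomain(start=(0, 0, 0), extent=(5, 9, 9))


class TestTransferPlans:
    def test_time_derivative_of_director_transfers(self):
        plan = transfer_derivatives(catalog.dt_n())
        assert plan.transferred and plan.sign == -1
        assert plan.field_factor.symbol == "n" and plan.field_factor.dt == 1

    def test_divergence_transfers_with_one_sign_flip(self):
        plan = transfer_derivatives(catalog.div_u())
        assert plan.transferred and plan.sign == -1

    def test_advection_is_locked(self):
        plan = transfer_derivatives(catalog.advect_n())
        assert not plan.transferred

    def test_transfer_order_beyond_tau_raises(self):
        term = canonicalize(LibraryTerm(
            factors=(Factor("u", dt=2, derivs=("a", "a", "i"), comps=("i",)),),
            rank=0, symclass="scalar",
        ))
        with pytest.raises(ValueError, match="tau"):
            transfer_derivatives(term, tau=4)


class TestIntegration:
    def test_ibp_oracle_time_derivative(self):
        # transferred -int (dt w) n  equals  int w (dt n) with the analytic
        # time derivative, to quadrature accuracy
        p = 81
        grid = FieldGrid(nx=p, ny=p, nt=p, dx=2 / (p - 1), dy=2 / (p - 1), dt=2 / (p - 1))
        T, Y, X = np.meshgrid(*grid.coords(), indexing="ij")
        omega = 1.5
        theta = omega * T + 0.3
        n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        seq = FieldSequence(grid=grid, u=np.zeros(grid.shape + (2,)), n=n)
        sub = Subdomain(start=(0, 0, 0), extent=(p, p, p))
        wt = make_weight(sub, WeightSpec(tau=4), grid, orders={(0, 0, 1)})
        ev = TermEvaluator(seq)
        transferred = integrate_term(catalog.dt_n(), wt, ev)
        dtn_exact = np.stack(
            [-omega * np.sin(theta), omega * np.cos(theta)], axis=-1
        )
        direct = [wt.integrate(dtn_exact[..., c]) for c in range(2)]
        scale = max(abs(d) for d in direct)
        for a, b in zip(transferred, direct):
            assert abs(a - b) < 1e-6 * scale

    def test_constant_term_integral_closed_form(self):
        p = 55
        grid = FieldGrid(nx=p, ny=p, nt=p, dx=1 / (p - 1), dy=2 / (p - 1), dt=3 / (p - 1))
        sub = Subdomain(start=(0, 0, 0), extent=(p, p, p))
        wt = make_weight(sub, WeightSpec(tau=4), grid)
        seq = FieldSequence(
            grid=grid,
            u=np.zeros(grid.shape + (2,)),
            n=np.stack([np.ones(grid.shape), np.zeros(grid.shape)], axis=-1),
        )
        val = integrate_term(catalog.const(), wt, TermEvaluator(seq))[0]
        jacobian = (0.5 * 1.0) * (0.5 * 2.0) * (0.5 * 3.0)  # physical half-lengths
        exact = ENVELOPE_1D_INTEGRAL ** 3 * jacobian
        assert abs(val - exact) / exact < 1e-4

    def test_trapezoid_second_order_convergence(self):
        # non-boundary-vanishing integrand: error should drop ~4x per halving
        errs = []
        for p in (17, 33):
            grid = FieldGrid(nx=p, ny=p, nt=p, dx=2 / (p - 1), dy=2 / (p - 1), dt=2 / (p - 1))
            sub = Subdomain(start=(0, 0, 0), extent=(p, p, p))
            wt = make_weight(sub, WeightSpec(tau=1), grid)
            T, Y, X = np.meshgrid(*grid.coords(), indexing="ij")
            integrand = np.sin(2.0 + 1.3 * X)
            val = wt.integrate(integrand)
            # high-resolution reference
            gref = FieldGrid(nx=257, ny=65, nt=65, dx=2 / 256, dy=2 / 64, dt=2 / 64)
            subref = Subdomain(start=(0, 0, 0), extent=(65, 65, 257))
            wref = make_weight(subref, WeightSpec(tau=1), gref)
            Tr, Yr, Xr = np.meshgrid(*gref.coords(), indexing="ij")
            ref = wref.integrate(np.sin(2.0 + 1.3 * Xr))
            errs.append(abs(val - ref))
        ratio = errs[0] / errs[1]
        assert 2.5 < ratio < 6.5


class TestFeatureMatrix:
    @pytest.fixture(scope="class")
    def small_library(self):
        return TermLibrary(
            spec=LibrarySpec(rank=0, parity="even", symclass="scalar"),
            terms=[catalog.div_u(), catalog.nnA(), catalog.const()],
        )

    def test_row_count_bookkeeping(self, small_library):
        fields = sf.random_smooth_fields(sf.default_grid(n=32, nt=32), seed=2)
        fm = build_feature_matrix(
            fields=fields, library=small_library,
            config=WeakFormConfig(n_subdomains=7, extents=(12, 12, 12), seed=0),
        )
        assert fm.G.shape == (7 * 4 * 1, 3)
        assert fm.row_meta.shape[0] == fm.G.shape[0]

    def test_divergence_column_small_on_solenoidal_flow(self, eq3_nondim):
        nf, _, _ = eq3_nondim
        lib = TermLibrary(
            spec=LibrarySpec(rank=0, parity="even", symclass="scalar"),
            terms=[catalog.div_u(), catalog.nnA()],
        )
        fm = build_feature_matrix(lib, nf, config=WeakFormConfig(n_subdomains=20, seed=3))
        div_ratio = np.linalg.norm(fm.G[:, 0]) / fm.xi[0]
        assert div_ratio < 1e-3  # far below the gradient scale

    def test_subdomain_count_stability_of_coefficients(self, eq9_clean):
        from spider2d import field_data as fd
        from spider2d.sparse_regression import min_singular_vector

        nf, _ = fd.nondimensionalize(eq9_clean[0])
        lib = TermLibrary(
            spec=LibrarySpec(rank=0, parity="even", symclass="scalar"),
            terms=[catalog.nnA(), catalog.const()],
        )
        ratios = []
        for nsub in (20, 40):
            fm = build_feature_matrix(
                lib, nf, config=WeakFormConfig(n_subdomains=nsub, seed=5)
            )
            c = min_singular_vector(fm.G)
            ratios.append(c[1] / c[0])
        assert np.isclose(ratios[0], ratios[1], rtol=1e-6)

    def test_serialization_round_trip(self, small_library, tmp_path):
        from spider2d.weak_form import FeatureMatrix

        fields = sf.random_smooth_fields(sf.default_grid(n=32, nt=32), seed=2)
        fm = build_feature_matrix(
            fields=fields, library=small_library,
            config=WeakFormConfig(n_subdomains=5, extents=(12, 12, 12), seed=0),
        )
        path = tmp_path / "fm.h5"
        fm.save(str(path))
        back = FeatureMatrix.load(str(path))
        assert np.allclose(back.G, fm.G)
        assert np.allclose(back.xi, fm.xi)
        assert back.col_keys == fm.col_keys


class TestNoiseRobustness:
    def test_weak_survives_noise_strong_does_not(self, eq3_clean):
        """At 50% velocity noise the weak residual of div u = 0 stays small
        while the pointwise (strong-form) residual is order one."""

        from spider2d import field_data as fd
        from spider2d.sparse_regression import residual_eta

        fields, _ = eq3_clean
        noisy = sf.add_noise(fields, 0.5, seed=9)
        nf, _ = fd.nondimensionalize(noisy)
        lib = TermLibrary(
            spec=LibrarySpec(rank=0, parity="even", symclass="scalar"),
            terms=[catalog.div_u()],
        )
        fm = build_feature_matrix(lib, nf, config=WeakFormConfig(n_subdomains=30, seed=4))
        weak_eta = residual_eta(
            fm.G[:, :1], np.array([1.0]), "single-term", xi=fm.xi[0]
        )
        assert weak_eta < 0.1
        d = fd.derived_fields(nf)
        strong = np.sqrt(np.mean(d.div ** 2)) / np.sqrt(
            np.mean(np.sum(d.gradu ** 2, axis=(-2, -1)))
        )
        assert strong > 0.5  # pointwise differentiation amplifies the noise
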