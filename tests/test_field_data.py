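"""Field handling: differentiation, smoothing, masking, nondimensionalization."""

import numpy as np
import pytest

from spider2d import field_data as fd
from spider2d import synthetic_fields as sf
from spider2d.field_data import (
    FieldGrid,
    FieldSequence,
    MaskConfig,
    align_director,
    build_mask,
    central_diff,
    derived_fields,
    director_diff,
    extract_director,
    mls_smooth,
    nondimensionalize,
)


def _grid(nx=16, ny=14, nt=12, dx=0.5, dy=0.4, dt=0.2):
    return FieldGrid(nx=nx, ny=ny, nt=nt, dx=dx, dy=dy, dt=dt)


def _uniform_director(shape):
    n = np.zeros(shape + (2,))
    n[..., 0] = 1.0
    return n


class TestCentralDiff:
    def test_constant_field_has_zero_derivative(self):
        f = np.full((8, 8, 8), 3.7)
        for direction, h in ((0, 0.3), (1, 0.4), ("t", 0.5)):
            # one-sided boundary stencils leave rounding-level residue
            assert np.abs(central_diff(f, direction, h)).max() < 1e-13

    def test_quadratic_is_differentiated_exactly(self):
        # centered and one-sided second-order stencils are exact for x^2
        x = 0.25 * np.arange(10)
        f = np.broadcast_to(x ** 2, (6, 7, 10)).copy()
        d = central_diff(f, 0, 0.25)
        assert np.allclose(d, np.broadcast_to(2 * x, f.shape), atol=1e-12)

    def test_linear_exact_including_boundaries(self):
        y = 1.5 * np.arange(9)
        f = np.broadcast_to(2.0 + 3.0 * y[:, None], (5, 9, 6)).copy()
        d = central_diff(f, 1, 1.5)
        assert np.allclose(d, 3.0, atol=1e-12)

    def test_axis_out_of_range_raises(self):
        with pytest.raises(ValueError):
            central_diff(np.zeros((5, 5)), 0, 1.0)  # x axis is ndim 2 here

    def test_second_order_convergence(self):
        # halving dx reduces the max error on sin(x) by about 4
        errs = []
        for m in (64, 128):
            x = np.linspace(0, np.pi, m)
            f = np.broadcast_to(np.sin(x), (5, 5, m)).copy()
            d = central_diff(f, 0, x[1] - x[0])
            errs.append(np.abs(d - np.cos(x)).max())
        ratio = errs[0] / errs[1]
        assert 4 * 0.9 < ratio < 4 * 1.35


class TestDirectorDiff:
    def test_uniform_director_with_random_signs(self, rng):
        n = _uniform_director((8, 8, 8))
        s = np.where(rng.random((8, 8, 8)) < 0.5, -1.0, 1.0)[..., None]
        d = director_diff(n * s, 0, 0.5)
        assert np.abs(d).max() < 1e-14

    def test_rotating_director_gradient_magnitude(self, rng):
        k = 0.3
        x = 0.5 * np.arange(20)
        theta = k * x
        n = np.zeros((5, 5, 20, 2))
        n[..., 0] = np.cos(theta)
        n[..., 1] = np.sin(theta)
        s = np.where(rng.random(n.shape[:3]) < 0.5, -1.0, 1.0)[..., None]
        d = director_diff(n * s, 0, 0.5)
        mag = np.linalg.norm(d, axis=-1)
        # |d n / dx| = k for a uniformly rotating director; the per-point
        # stored sign carries through as an overall +-1 per point
        assert np.allclose(mag[:, :, 1:-1], k, rtol=1e-2)

    def test_global_flip_leaves_qbar_and_gradnorm(self, rng):
        grid = _grid()
        theta = 0.4 * np.sin(np.linspace(0, 2, grid.nx))
        n = np.zeros(grid.shape + (2,))
        n[..., 0] = np.cos(theta)
        n[..., 1] = np.sin(theta)
        u = np.zeros(grid.shape + (2,))
        a = FieldSequence(grid=grid, u=u, n=n)
        b = FieldSequence(grid=grid, u=u, n=-n)
        assert np.allclose(derived_fields(a).Qbar, derived_fields(b).Qbar)
        assert np.allclose(
            fd.director_gradient_norm(a), fd.director_gradient_norm(b)
        )


class TestAlignDirector:
    def test_alignment_is_gauge_invariant(self, rng):
        grid = _grid()
        T, Y, X = np.meshgrid(*grid.coords(), indexing="ij")
        theta = 0.5 * np.sin(X) + 0.3 * Y / 4 + 0.2 * T
        n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        s = np.where(rng.random(grid.shape) < 0.5, -1.0, 1.0)[..., None]
        assert np.allclose(align_director(n), align_director(n * s))


class TestMLS:
    def test_reproduces_fit_degree_polynomial(self):
        t, y, x = np.meshgrid(
            np.arange(10.0), np.arange(9.0), np.arange(11.0), indexing="ij"
        )
        f = 1 + 2 * x - y + 0.5 * t + 0.3 * x * y - 0.2 * t * x + 0.1 * y ** 2
        assert np.abs(mls_smooth(f) - f).max() < 1e-10

    def test_reduces_noise_variance(self, rng):
        noise = rng.normal(size=(16, 16, 16))
        assert mls_smooth(noise).var() < noise.var()

    def test_improves_rms_against_clean_signal(self, rng):
        x = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        clean = np.broadcast_to(np.sin(x), (16, 16, 32)).copy()
        noisy = clean + rng.normal(0, 0.2, clean.shape)
        sm = mls_smooth(noisy)
        rms_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_after = np.sqrt(np.mean((sm - clean) ** 2))
        assert rms_after < rms_before

    def test_window_larger_than_grid_raises(self):
        with pytest.raises(ValueError):
            mls_smooth(np.zeros((4, 10, 10)), window=5)


class TestDerivedFields:
    def test_uniform_x_director_gives_half_diagonal_qbar(self):
        grid = _grid()
        seq = FieldSequence(
            grid=grid, u=np.zeros(grid.shape + (2,)), n=_uniform_director(grid.shape)
        )
        d = derived_fields(seq)
        assert np.allclose(d.Qbar[..., 0, 0], 0.5)
        assert np.allclose(d.Qbar[..., 1, 1], -0.5)
        assert np.allclose(d.Qbar[..., 0, 1], 0.0)

    def test_extensional_flow_tensors(self):
        E = 0.7
        grid = FieldGrid(nx=16, ny=16, nt=6, dx=0.1, dy=0.1, dt=0.1,
                         origin=(-0.75, -0.75, 0.0))
        seq = sf.extensional_flow(grid, E)
        d = derived_fields(seq)
        assert np.allclose(d.Abar[..., 0, 0], E, atol=1e-10)
        assert np.allclose(d.Abar[..., 1, 1], -E, atol=1e-10)
        assert np.abs(d.div).max() < 1e-10
        assert np.abs(d.Omega).max() < 1e-10

    def test_pointwise_invariants(self, rng):
        grid = _grid()
        theta = rng.normal(0, 0.5, grid.shape)
        n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        seq = FieldSequence(grid=grid, u=rng.normal(size=grid.shape + (2,)), n=n)
        d = derived_fields(seq)
        assert np.abs(np.trace(d.Qbar, axis1=-2, axis2=-1)).max() < 1e-12
        assert np.allclose(d.A + d.Omega, d.gradu)
        assert np.abs(np.trace(d.Abar, axis1=-2, axis2=-1)).max() < 1e-12
        Pn = np.einsum("...ij,...j->...i", d.Pperp, n)
        assert np.abs(Pn).max() < 1e-12


class TestMask:
    def test_uniform_data_gives_unit_mask(self):
        grid = _grid()
        seq = FieldSequence(
            grid=grid, u=np.zeros(grid.shape + (2,)), n=_uniform_director(grid.shape)
        )
        mask = build_mask(seq)
        assert np.allclose(mask.psi, 1.0)

    def test_intensity_hole_is_excluded(self):
        grid = sf.default_grid(n=48, nt=8)
        T, Y, X = np.meshgrid(*grid.coords(), indexing="ij")
        r = np.hypot(X - np.pi, Y - np.pi)
        phi = np.clip((r > 1.8).astype(float), 0.0, 1.0)
        seq = FieldSequence(
            grid=grid, u=np.zeros(grid.shape + (2,)),
            n=_uniform_director(grid.shape), phi=phi,
        )
        mask = build_mask(seq)
        it, iy, ix = 4, 24, 24  # disk center
        assert mask.psi[it, iy, ix] < 0.1
        assert mask.psi[it, iy, 2] > 0.95
        # monotone transition along the +x ray from the center outwards
        ray = mask.psi[it, iy, ix : ix + 20]
        assert np.all(np.diff(ray) > -1e-9)

    def test_defect_core_is_excluded_by_gradient(self):
        grid = sf.default_grid(n=48, nt=8)
        n, valid = sf.defect_director(grid, 0.5, (np.pi, np.pi))
        seq = FieldSequence(
            grid=grid, u=np.zeros(grid.shape + (2,)), n=n, valid=valid
        )
        mask = build_mask(seq)
        assert mask.psi[4, 24, 24] < 0.5
        assert mask.psi[4, 4, 4] > 0.9

    def test_nonpositive_threshold_raises(self):
        grid = _grid()
        seq = FieldSequence(
            grid=grid, u=np.zeros(grid.shape + (2,)), n=_uniform_director(grid.shape)
        )
        with pytest.raises(ValueError):
            build_mask(seq, MaskConfig(intensity_frac=0.0))


class TestNondimensionalize:
    def test_contract_on_fixture(self, eq3_nondim):
        nf, scales, _ = eq3_nondim
        d = derived_fields(nf)
        speed = np.linalg.norm(nf.u, axis=-1)
        assert abs(speed.mean() - 1.0) < 1e-10
        assert abs(np.abs(d.omega).mean() - 1.0) < 1e-10

    def test_already_normalized_is_identity(self, eq3_nondim):
        nf, _, _ = eq3_nondim
        again, scales = nondimensionalize(nf)
        assert abs(scales.length - 1.0) < 1e-10
        assert abs(scales.time - 1.0) < 1e-10
        assert np.allclose(again.u, nf.u)

    def test_shear_flow_oracle(self):
        # u = (k y, 0): brute-force means, then verify the rescaled contract
        k, L = 0.8, 2.0
        grid = FieldGrid(nx=32, ny=32, nt=6, dx=L / 31, dy=L / 31, dt=0.1,
                         origin=(0.0, 0.0, 0.0))
        T, Y, X = np.meshgrid(*grid.coords(), indexing="ij")
        u = np.zeros(grid.shape + (2,))
        u[..., 0] = k * Y
        seq = FieldSequence(grid=grid, u=u, n=_uniform_director(grid.shape))
        # oracle: <|u|> = k <y>, omega = -2 Omega_xy = d_y u_x - d_x u_y = k
        mean_u = k * Y.mean()
        mean_w = k
        out, scales = nondimensionalize(seq)
        assert np.isclose(scales.time, 1.0 / mean_w, rtol=1e-10)
        assert np.isclose(scales.length, mean_u / mean_w, rtol=1e-6)
        d = derived_fields(out)
        assert abs(np.linalg.norm(out.u, axis=-1).mean() - 1.0) < 1e-10
        assert abs(np.abs(d.omega).mean() - 1.0) < 1e-10

    def test_zero_flow_raises(self):
        grid = _grid()
        seq = FieldSequence(
            grid=grid, u=np.zeros(grid.shape + (2,)), n=_uniform_director(grid.shape)
        )
        with pytest.raises(ValueError, match="degenerate"):
            nondimensionalize(seq)


class TestExtractDirector:
    def test_stripes_give_transverse_director(self):
        x = np.arange(64)
        img = np.broadcast_to(0.5 + 0.5 * np.cos(0.6 * x), (3, 64, 64)).copy()
        n, phi, valid = extract_director(img)
        inner = (slice(None), slice(10, -10), slice(10, -10))
        assert valid[inner].mean() > 0.9
        # intensity varies along x -> director along y (up to sign)
        ny = np.abs(n[inner + (1,)][valid[inner]])
        assert ny.min() > 0.99

    def test_constant_image_is_invalid_everywhere(self):
        img = np.full((2, 32, 32), 0.5)
        _, _, valid = extract_director(img)
        assert not valid.any()

    def test_rotated_stripes(self):
        yy, xx = np.mgrid[0:80, 0:80]
        img = (0.5 + 0.5 * np.cos(0.5 * (xx + yy) / np.sqrt(2)))[None]
        n, _, valid = extract_director(img)
        inner = (slice(None), slice(15, -15), slice(15, -15))
        ang = np.degrees(np.arctan2(n[..., 1], n[..., 0]))[inner]
        ang = np.where(ang < 0, ang + 180.0, ang)  # nematic: fold to [0,180)
        ok = valid[inner]
        # stripes vary along (1,1)/sqrt2 -> director along (1,-1): 135 degrees
        assert np.abs(ang[ok] - 135.0).max() < 2.0


class TestIO:
    @pytest.mark.parametrize("ext", ["h5", "nc", "csv"])
    def test_round_trip(self, tmp_path, ext):
        grid = FieldGrid(nx=6, ny=5, nt=5, dx=0.5, dy=0.25, dt=0.1,
                         origin=(1.0, -2.0, 0.5))
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 0.3, grid.shape)
        n = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        seq = FieldSequence(
            grid=grid, u=rng.normal(size=grid.shape + (2,)), n=n,
            phi=rng.random(grid.shape),
        )
        path = tmp_path / f"fields.{ext}"
        fd.save_fields(seq, str(path))
        back = fd.load_fields(str(path))
        assert np.allclose(back.u, seq.u, atol=1e-6)
        assert np.allclose(back.n, seq.n, atol=1e-6)
        assert np.allclose(back.phi, seq.phi, atol=1e-6)
        assert np.isclose(back.grid.dx, grid.dx)
        assert np.isclose(back.grid.origin[0], grid.origin[0])

    def test_tiff_stack_reader(self, tmp_path):
        import tifffile

        stack = (255 * np.random.default_rng(0).random((4, 16, 16))).astype("uint8")
        p = tmp_path / "stack.tif"
        tifffile.imwrite(p, stack)
        arr = fd.load_tiff_stack(p)
        assert arr.shape == (4, 16, 16)
        assert 0.0 <= arr.min() and arr.max() <= 1.0
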