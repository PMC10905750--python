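"""SH encoding: sampling, expansion, reconstruction, Hausdorff, QC."""

import numpy as np
import pytest
import trimesh
from scipy import integrate

from neuroshape import (
    SHCoefficients,
    directed_hausdorff,
    fit_exclusion_gmm,
    reconstruction_error,
    sh_expand,
    sh_reconstruct,
    spherical_parameterize,
)
from neuroshape.shparam import (
    RadiusGrid,
    _gauss_grid,
    sh_evaluate,
    spherical_parameterize_field,
)

TWO_SQRT_PI = 2.0 * np.sqrt(np.pi)


def _analytic_ellipsoid_grid(a, b, c, n_theta=64, n_phi=128):
    theta, _, phi = _gauss_grid(n_theta, n_phi)
    tg, pg = np.meshgrid(theta, phi, indexing="ij")
    r = 1.0 / np.sqrt(
        (np.sin(tg) * np.cos(pg) / a) ** 2
        + (np.sin(tg) * np.sin(pg) / b) ** 2
        + (np.cos(tg) / c) ** 2
    )
    return RadiusGrid(radii=r, center=np.zeros(3))


class TestParameterize:
    def test_unit_sphere_radius_one(self, unit_sphere):
        g = spherical_parameterize(unit_sphere)
        assert np.allclose(g.radii, 1.0, atol=2e-3)
        assert g.violating_rays == 0

    def test_ellipsoid_matches_closed_form(self, ellipsoid):
        g = spherical_parameterize(ellipsoid)
        ref = _analytic_ellipsoid_grid(1.0, 0.8, 0.6)
        assert np.max(np.abs(g.radii - ref.radii) / ref.radii) < 0.01

    def test_center_outside_refused(self, unit_sphere):
        with pytest.raises(ValueError):
            spherical_parameterize(unit_sphere, center=np.array([5.0, 0, 0]))

    def test_field_path_agrees_with_mesh_path(self):
        """Voxel-field ray marching equals mesh ray casting."""
        shape = (40, 40, 40)
        zz, yy, xx = np.indices(shape)
        q = ((zz - 20.0) ** 2 / 144 + (yy - 20.0) ** 2 / 100
             + (xx - 20.0) ** 2 / 64)
        field = 2.0 - q  # smooth; the level-1 surface is the ellipsoid
        g = spherical_parameterize_field(field, (0.5, 0.5, 0.5), level=1.0)
        ref = _analytic_ellipsoid_grid(
            np.sqrt(64) * 0.5, np.sqrt(100) * 0.5, np.sqrt(144) * 0.5
        )
        assert np.max(np.abs(g.radii - ref.radii) / ref.radii) < 0.03


class TestExpand:
    def test_sphere_single_coefficient(self, unit_sphere):
        """Quadrature oracle: integral of Y00 over the unit sphere."""
        c = sh_expand(spherical_parameterize(unit_sphere), 16)
        y00 = 1.0 / TWO_SQRT_PI
        expect, _ = integrate.dblquad(
            lambda t, p: y00 * np.sin(t), 0, 2 * np.pi, 0, np.pi
        )
        assert expect == pytest.approx(TWO_SQRT_PI, abs=1e-9)
        assert c.ccoeff[0, 0] == pytest.approx(expect, rel=1e-2)
        rest = c.vector.copy()
        rest[0] = 0.0
        assert np.max(np.abs(rest)) < 1e-3

    def test_vector_length_is_2178_at_lmax_32(self, unit_sphere):
        c = sh_expand(spherical_parameterize(unit_sphere), 32)
        assert c.vector.size == 2178
        assert c.vector.size == 2 * (32 + 1) ** 2

    @pytest.mark.parametrize("lmax", [0, 1, 4, 8])
    def test_coefficient_count_formula(self, lmax):
        g = _analytic_ellipsoid_grid(1, 1, 1)
        assert sh_expand(g, lmax).vector.size == 2 * (lmax + 1) ** 2

    def test_prolate_ellipsoid_even_zonal_only(self):
        """An axis-aligned spheroid has only even-degree m=0 terms."""
        g = _analytic_ellipsoid_grid(0.8, 0.8, 1.4)
        c = sh_expand(g, 16)
        mask = np.zeros_like(c.ccoeff, dtype=bool)
        mask[0::2, 0] = True
        assert np.abs(c.ccoeff[~mask]).max() < 1e-9
        assert np.abs(c.scoeff).max() < 1e-9

    def test_under_resolved_grid_rejected(self):
        g = _analytic_ellipsoid_grid(1, 1, 1, n_theta=16, n_phi=32)
        with pytest.raises(ValueError, match="under-resolved"):
            sh_expand(g, 32)

    def test_scaling_equivariance(self, ellipsoid):
        c1 = sh_expand(spherical_parameterize(ellipsoid), 8)
        big = ellipsoid.copy()
        big.apply_scale(2.5)
        c2 = sh_expand(spherical_parameterize(big), 8)
        assert np.allclose(c2.vector, 2.5 * c1.vector, rtol=1e-6, atol=1e-9)

    def test_serialization_roundtrip(self):
        g = _analytic_ellipsoid_grid(1.0, 0.7, 0.5)
        c = sh_expand(g, 8)
        c2 = SHCoefficients.from_vector(c.vector, 8)
        assert np.array_equal(c.ccoeff, c2.ccoeff)
        assert np.array_equal(c.scoeff, c2.scoeff)
        assert len(SHCoefficients.column_names(8)) == c.vector.size


class TestReconstruct:
    def test_sphere_roundtrip_under_half_percent(self, unit_sphere):
        g = spherical_parameterize(unit_sphere)
        c = sh_expand(g, 32)
        err = reconstruction_error(unit_sphere, c, g.center)
        assert err / g.radii.mean() < 0.005

    def test_pure_degree_zero_is_sphere(self):
        n = 33
        cc = np.zeros((n, n))
        cc[0, 0] = TWO_SQRT_PI * 1.7
        mesh = sh_reconstruct(SHCoefficients(32, cc, np.zeros((n, n))))
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.allclose(r, 1.7, atol=1e-6)

    def test_truncation_error_monotone_in_lmax(self):
        """Truncation error on an exact radius function only shrinks."""
        g = _analytic_ellipsoid_grid(1.0, 0.8, 0.6)
        c32 = sh_expand(g, 32)
        theta, _, phi = _gauss_grid(48, 96)
        tg, pg = np.meshgrid(theta, phi, indexing="ij")
        ref = _analytic_ellipsoid_grid(1.0, 0.8, 0.6, 48, 96).radii
        errs = []
        for lmax in (4, 8, 16, 32):
            r = sh_evaluate(c32.truncated(lmax), tg.ravel(), pg.ravel())
            errs.append(np.max(np.abs(r.reshape(ref.shape) - ref)))
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs, errs[1:]))


class TestDirectedHausdorff:
    def test_identical_sets_zero(self):
        pts = np.random.default_rng(0).normal(size=(30, 3))
        assert directed_hausdorff(pts, pts) == 0.0

    def test_three_four_five(self):
        assert directed_hausdorff(
            np.array([[0.0, 0, 0]]), np.array([[3.0, 4.0, 0]])
        ) == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3))
        brute = max(min(np.linalg.norm(p - q) for q in b) for p in a)
        assert directed_hausdorff(a, b) == pytest.approx(brute, abs=0.0)

    def test_asymmetry(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert directed_hausdorff(a, b) == 0.0
        assert directed_hausdorff(b, a) == 10.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            directed_hausdorff(np.empty((0, 3)), np.zeros((1, 3)))


class TestExclusionGMM:
    def test_recovers_planted_high_error_component(self):
        """84%/16% mixture: nearly all high-error draws are flagged."""
        rng = np.random.default_rng(0)
        n_hi = 80
        lo = rng.normal(0.1, 0.02, 420)
        hi = rng.normal(1.0, 0.1, n_hi)
        errors = np.concatenate([lo, hi])
        qc, info = fit_exclusion_gmm(errors, seed=0)
        flags = np.array([q.excluded for q in qc])
        assert flags[420:].mean() >= 0.95
        assert flags[:420].mean() <= 0.02

    def test_identical_errors_no_exclusions(self):
        with pytest.warns(UserWarning):
            qc, info = fit_exclusion_gmm(np.full(25, 0.3), seed=0)
        assert not any(q.excluded for q in qc)

    def test_unimodal_no_exclusions(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning):
            qc, _ = fit_exclusion_gmm(rng.normal(0.5, 0.05, 200), seed=0)
        assert not any(q.excluded for q in qc)

    def test_flagged_fraction_scale_invariant(self):
        rng = np.random.default_rng(2)
        errors = np.concatenate(
            [rng.normal(0.1, 0.02, 168), rng.normal(1.0, 0.1, 32)]
        )
        qc1, _ = fit_exclusion_gmm(errors, seed=0)
        qc2, _ = fit_exclusion_gmm(errors * 10.0, seed=0)
        f1 = [q.excluded for q in qc1]
        f2 = [q.excluded for q in qc2]
        assert f1 == f2

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            fit_exclusion_gmm(np.linspace(0, 1, 10))
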