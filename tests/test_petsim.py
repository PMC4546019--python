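"""Projector and OP-OSEM reconstruction: closed-form and fixed-point oracles."""

import math

import numpy as np
import pytest

from muinpaint.grids import MuMap, VoxelGrid3D
from muinpaint.petsim import (
    ProjectionGeometry,
    ReconParams,
    attenuation_factors,
    forward_project,
    poisson_loglik,
    reconstruct_osem,
    sample_counts,
    scale_to_counts,
    system_matrix,
)

S = 2.6  # in-plane voxel size, mm


def antialiased_disc(n=96, radius_mm=80.0, supersample=9):
    """Disc indicator with sub-voxel edge weights (9x9 supersampling)."""
    c = (n - 1) / 2 * S
    x = np.arange(n) * S - c
    sub = ((np.arange(supersample) + 0.5) / supersample - 0.5) * S
    acc = np.zeros((n, n))
    for dx in sub:
        for dy in sub:
            acc += (x[:, None] + dx) ** 2 + (x[None, :] + dy) ** 2 <= radius_mm**2
    return acc / supersample**2


def disc_mu(radius_mm=80.0, mu=0.1, nz=1):
    disc = antialiased_disc(radius_mm=radius_mm)
    vals = np.repeat((mu * disc)[:, :, None], nz, axis=2)
    grid = VoxelGrid3D(vals, (S, S, 3.1))
    body = grid.with_values(np.repeat((disc > 0.5)[:, :, None], nz, axis=2))
    return MuMap(grid, body, "truth"), disc


@pytest.fixture(scope="module")
def centered_geom():
    # odd bin count so one ray passes exactly through the center
    return ProjectionGeometry(n_angles=63, n_bins=97)


class TestAttenuationFactors:
    def test_zero_mu_gives_unit_factors(self, geometry):
        g = VoxelGrid3D(np.zeros((32, 32, 2)), (S, S, 3.1))
        mu = MuMap(g, g.with_values(np.zeros((32, 32, 2), dtype=bool)), "truth")
        np.testing.assert_allclose(attenuation_factors(mu, geometry), 1.0)

    def test_central_ray_through_uniform_disc_matches_chord_formula(self, centered_geom):
        # survival along a diameter of a mu=0.1/cm disc of radius R: exp(-0.1*2R)
        radius = 80.0
        mu, _ = disc_mu(radius_mm=radius)
        att = attenuation_factors(mu, centered_geom)
        central = att[0, centered_geom.n_bins // 2, 0]
        expected = math.exp(-0.1 * 2 * radius / 10.0)
        assert abs(central - expected) / expected < 0.005

    def test_less_attenuating_map_gives_larger_factors(self, geometry):
        mu_true, disc = disc_mu()
        voided = mu_true.values.copy()
        voided[40:56, 40:56, :] = 0.0
        mu_void = mu_true.with_values(voided)
        f_void = attenuation_factors(mu_void, geometry)
        f_true = attenuation_factors(mu_true, geometry)
        assert (f_void >= f_true - 1e-12).all()

    def test_negative_mu_rejected(self, geometry):
        g = VoxelGrid3D(np.zeros((8, 8, 1)), (S, S, 3.1))
        mu = MuMap(g, g.with_values(np.zeros((8, 8, 1), dtype=bool)), "truth")
        object.__setattr__(mu.grid, "values", -np.ones((8, 8, 1)))
        with pytest.raises(ValueError):
            attenuation_factors(mu, geometry)


class TestForwardProject:
    def test_zero_activity_zero_sinogram(self, geometry):
        act = VoxelGrid3D(np.zeros((32, 32, 2)), (S, S, 3.1))
        sino = forward_project(act, None, geometry)
        assert sino.prompts.max() == 0.0

    def test_linear_in_activity(self, geometry, rng):
        act = VoxelGrid3D(rng.random((32, 32, 2)), (S, S, 3.1))
        s1 = forward_project(act, None, geometry, background_fraction=0.2)
        s2 = forward_project(act.with_values(2 * act.values), None, geometry, background_fraction=0.2)
        np.testing.assert_allclose(
            s2.prompts - s2.background, 2 * (s1.prompts - s1.background), rtol=1e-10
        )

    def test_point_source_traces_a_sinusoid(self):
        n = 64
        act = np.zeros((n, n, 1))
        i0, j0 = 44, 25
        act[i0, j0, 0] = 1.0
        grid = VoxelGrid3D(act, (S, S, 3.1))
        geom = ProjectionGeometry(n_angles=60, n_bins=95)
        sino = forward_project(grid, None, geom)
        c = (n - 1) / 2 * S
        px, py = i0 * S - c, j0 * S - c
        for a, theta in enumerate(geom.angles):
            r_expected = px * np.cos(theta) + py * np.sin(theta)
            peak = geom.bin_offsets[np.argmax(sino.prompts[a, :, 0])]
            assert abs(peak - r_expected) <= geom.bin_spacing_mm

    def test_adjoint_dot_product(self, geometry, rng):
        grid = VoxelGrid3D(np.zeros((96, 96, 1)), (S, S, 3.1))
        A = system_matrix(geometry, grid)
        x = rng.random(A.shape[1])
        y = rng.random(A.shape[0])
        lhs = (A @ x) @ y
        rhs = x @ (A.T @ y)
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)


class TestSampleCounts:
    def test_zero_expectation_zero_counts(self, geometry):
        act = VoxelGrid3D(np.zeros((32, 32, 1)), (S, S, 3.1))
        sino = sample_counts(forward_project(act, None, geometry), seed=0)
        assert sino.prompts.max() == 0.0

    def test_deterministic_per_seed(self, geometry, rng):
        act = VoxelGrid3D(10 * rng.random((32, 32, 1)), (S, S, 3.1))
        expected = forward_project(act, None, geometry)
        a = sample_counts(expected, seed=11)
        b = sample_counts(expected, seed=11)
        c = sample_counts(expected, seed=12)
        np.testing.assert_array_equal(a.prompts, b.prompts)
        assert not np.array_equal(a.prompts, c.prompts)

    def test_sample_mean_matches_expectation_clt(self):
        # 10^4 independent bins at expectation 50 ~ 10^4 seeded draws
        geom = ProjectionGeometry(n_angles=100, n_bins=100)
        act = VoxelGrid3D(np.zeros((8, 8, 1)), (S, S, 3.1))
        expected = forward_project(act, None, geom)
        expected = type(expected)(
            geometry=geom,
            grid_geometry=expected.grid_geometry,
            prompts=np.full_like(expected.prompts, 50.0),
            attenuation=expected.attenuation,
            background=expected.background,
        )
        drawn = sample_counts(expected, seed=3)
        assert abs(drawn.prompts.mean() - 50.0) <= 3 * math.sqrt(50.0 / 1e4)


class TestReconstruct:
    def test_uniform_disc_recovered_with_true_attenuation(self, centered_geom):
        # MLEM fixed point: noiseless data + true AC recovers the activity
        mu, disc = disc_mu()
        act = mu.grid.with_values(disc[:, :, None].copy())
        sino = forward_project(act, mu, centered_geom)
        rec = reconstruct_osem(
            sino, mu, ReconParams(n_iterations=20, n_subsets=1, postfilter_fwhm_mm=0.0)
        )
        interior = disc > 0.999
        interior &= _erode2d(interior, 3)
        assert abs(rec.values[:, :, 0][interior].mean() - 1.0) < 0.02

    def test_void_in_ac_map_underestimates_activity(self, geometry):
        mu_true, disc = disc_mu()
        act = mu_true.grid.with_values(disc[:, :, None].copy())
        voided = mu_true.values.copy()
        voided[40:60, 40:60, :] = 0.0
        mu_dixon = mu_true.with_values(voided)
        sino = forward_project(act, mu_true, geometry)
        rec_dixon = reconstruct_osem(sino, mu_dixon, ReconParams())
        rec_true = reconstruct_osem(sino, mu_true, ReconParams())
        void = np.zeros_like(disc, dtype=bool)
        void[40:60, 40:60] = True
        assert rec_dixon.values[:, :, 0][void].mean() < rec_true.values[:, :, 0][void].mean()

    def test_all_zero_sinogram_reconstructs_to_zero(self, geometry):
        act = VoxelGrid3D(np.zeros((48, 48, 2)), (S, S, 3.1))
        sino = forward_project(act, None, geometry)
        rec = reconstruct_osem(sino, None, ReconParams())
        assert rec.values.max() == 0.0

    def test_nonnegative_output_on_noisy_data(self, geometry, rng):
        mu, disc = disc_mu()
        act = mu.grid.with_values((disc * (1 + rng.random(disc.shape)))[:, :, None])
        sino = sample_counts(scale_to_counts(forward_project(act, mu, geometry), 2e5), 4)
        rec = reconstruct_osem(sino, mu, ReconParams())
        assert rec.values.min() >= 0.0

    def test_total_counts_preserved_without_background(self, centered_geom):
        # Poisson likelihood stationarity: refitted totals match the data
        mu, disc = disc_mu()
        act = mu.grid.with_values(disc[:, :, None].copy())
        sino = forward_project(act, mu, centered_geom)
        rec = reconstruct_osem(
            sino, mu, ReconParams(n_iterations=30, n_subsets=1, postfilter_fwhm_mm=0.0)
        )
        refit = forward_project(rec, mu, centered_geom)
        assert abs(refit.prompts.sum() - sino.prompts.sum()) <= 0.005 * sino.prompts.sum()

    def test_full_mlem_loglikelihood_is_monotone(self, centered_geom):
        mu, disc = disc_mu(radius_mm=60.0)
        act = mu.grid.with_values(disc[:, :, None].copy())
        sino = forward_project(act, mu, centered_geom)
        lls = []
        for k in range(1, 8):
            rec = reconstruct_osem(
                sino, mu, ReconParams(n_iterations=k, n_subsets=1, postfilter_fwhm_mm=0.0)
            )
            refit = forward_project(rec, mu, centered_geom)
            lls.append(poisson_loglik(sino.prompts, refit.prompts))
        diffs = np.diff(lls)
        assert (diffs >= -1e-6 * np.abs(np.array(lls[:-1]))).all()

    def test_subsets_must_divide_angles(self, centered_geom):
        act = VoxelGrid3D(np.zeros((16, 16, 1)), (S, S, 3.1))
        sino = forward_project(act, None, centered_geom)
        with pytest.raises(ValueError):
            reconstruct_osem(sino, None, ReconParams(n_subsets=10))

    def test_background_term_in_denominator_keeps_recon_stable(self, geometry):
        mu, disc = disc_mu()
        act = mu.grid.with_values(disc[:, :, None].copy())
        sino = forward_project(act, mu, geometry, background_fraction=0.2)
        rec = reconstruct_osem(sino, mu, ReconParams(background_fraction=0.2))
        interior = _erode2d(disc > 0.999, 4)
        assert abs(rec.values[:, :, 0][interior].mean() - 1.0) < 0.1


def _erode2d(mask, n):
    from scipy import ndimage

    return ndimage.binary_erosion(mask, iterations=n)
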