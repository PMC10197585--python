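import numpy as np
import pytest

from mccsd._sphere import axial_angle_deg
from mccsd.acquisition import AcquisitionScheme, cluster_shells
from mccsd.cascade import (
    DegenerateFitError,
    FitConfig,
    estimate_parallel_diffusivity,
    fit_isotropic_ball,
    fit_mc_voxel,
    fit_volume,
    fractional_anisotropy,
)
from mccsd.compartments import LAMBDA_ISO_BOUNDS, MCParams, mc_signal


class TestIsotropicPrefit:
    def test_recovers_single_ball(self, p3):
        sig = np.exp(-p3.b_si * 2e-9)
        fit = fit_isotropic_ball(sig, p3)
        assert fit.lambda_iso == pytest.approx(2e-9, abs=1e-12 * 1e9)

    def test_free_water_hits_upper_bound(self, p3):
        sig = np.exp(-p3.b_si * 3e-9)
        fit = fit_isotropic_ball(sig, p3)
        assert fit.lambda_iso == pytest.approx(3e-9, abs=1e-12 * 1e9)

    def test_matches_dense_grid_oracle_on_wm_signal(self, p3, wm_signal):
        # the prefit on a mixed anisotropic signal has no closed form;
        # compare against an exhaustive 1e5-point 1-D grid search
        fit = fit_isotropic_ball(wm_signal, p3)
        grid = np.linspace(*LAMBDA_ISO_BOUNDS, 100_000)
        rss = ((wm_signal[:, None] - np.exp(-np.outer(p3.b_si, grid))) ** 2).sum(0)
        oracle = grid[np.argmin(rss)]
        assert fit.lambda_iso == pytest.approx(oracle, rel=1e-4)
        assert fit.rss <= rss.min() + 1e-12

    def test_all_b0_scheme_rejected(self):
        bvals = np.zeros(3)
        scheme = AcquisitionScheme(bvals, np.zeros((3, 3)), cluster_shells(bvals))
        with pytest.raises(DegenerateFitError):
            fit_isotropic_ball(np.ones(3), scheme)


class TestMCVoxelFit:
    def test_matched_model_recovery(self, p3):
        truth = MCParams(fb=0.6, fcsf=0.5, fr=0.6, lambda_iso=2.5e-9,
                         lambda_par=1.7e-9, mu=[0.0, 0.0, 1.0])
        sig = mc_signal(truth, p3)
        fit = fit_mc_voxel(sig, p3, 1.7e-9)
        assert fit.fb == pytest.approx(truth.fb, abs=0.02)
        assert fit.fcsf == pytest.approx(truth.fcsf, abs=0.02)
        assert fit.fr == pytest.approx(truth.fr, abs=0.02)
        assert axial_angle_deg(fit.mu, truth.mu) < 2.0

    def test_pure_anisotropic_voxel(self, p3, wm_signal):
        fit = fit_mc_voxel(wm_signal, p3, 1.7e-9)
        assert fit.fb <= 0.02

    def test_free_water_collapse_is_binary(self, p3):
        # slow isotropic voxel: lambda_iso <= lambda_par forces fcsf = 1
        sig = np.exp(-p3.b_si * 1.5e-9)
        fit = fit_mc_voxel(sig, p3, 1.7e-9)
        assert fit.fcsf == 1.0
        assert fit.lambda_iso <= 1.7e-9

    def test_no_collapse_when_iso_fast(self, p3):
        truth = MCParams(fb=0.7, fcsf=0.3, fr=0.6, lambda_iso=2.6e-9,
                         lambda_par=1.7e-9, mu=[0.0, 0.0, 1.0])
        sig = mc_signal(truth, p3)
        fit = fit_mc_voxel(sig, p3, 1.7e-9)
        assert fit.lambda_iso > 1.7e-9
        assert fit.fcsf != 1.0

    def test_refinement_never_worsens_grid_cost(self, p3):
        rng = np.random.default_rng(11)
        config = FitConfig()
        for _ in range(5):
            mu = rng.standard_normal(3)
            mu /= np.linalg.norm(mu)
            truth = MCParams(
                fb=rng.uniform(0, 1), fcsf=rng.uniform(0, 1),
                fr=rng.uniform(0, 1), lambda_iso=rng.uniform(1.8e-9, 2.9e-9),
                lambda_par=1.7e-9, mu=mu,
            )
            sig = mc_signal(truth, p3)
            fit = fit_mc_voxel(sig, p3, 1.7e-9, config)
            # brute-force grid cost at the same resolution
            from mccsd._sphere import fibonacci_hemisphere
            from mccsd.cascade import _mixture_residuals

            iso = fit_isotropic_ball(sig, p3)
            axes = fibonacci_hemisphere(config.orientation_grid_size)
            ct2 = (p3.directions @ axes.T).T ** 2
            f = np.linspace(0, 1, config.grid_points_per_fraction)
            fb, fcsf, fr = np.meshgrid(f, f, f, indexing="ij")
            cost = _mixture_residuals(
                fb.ravel()[:, None, None], fcsf.ravel()[:, None, None],
                fr.ravel()[:, None, None], ct2[None], sig, p3.b_si,
                iso.lambda_iso, 1.7e-9,
            )
            assert fit.rss <= cost.min() + 1e-12

    def test_deterministic(self, p3, wm_signal):
        a = fit_mc_voxel(wm_signal, p3, 1.7e-9)
        b = fit_mc_voxel(wm_signal, p3, 1.7e-9)
        assert a.fb == b.fb and a.fcsf == b.fcsf and a.fr == b.fr
        np.testing.assert_array_equal(a.mu, b.mu)


def _prolate_tensor_signal(scheme, evals, axis):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    # D = l2*I + (l1 - l2) axis axis^T for an axially symmetric tensor
    ct2 = (scheme.directions @ axis) ** 2
    adc = evals[1] + (evals[0] - evals[1]) * ct2
    return np.exp(-scheme.b_si * adc)


class TestParallelDiffusivityEstimate:
    def test_homogeneous_prolate_phantom(self, p3):
        sig = _prolate_tensor_signal(p3, (1.7e-9, 0.3e-9), [0, 0, 1])
        dwi = np.tile(sig, (3, 3, 1, 1))
        mask = np.ones((3, 3, 1), dtype=bool)
        est = estimate_parallel_diffusivity(dwi, p3, mask)
        assert est == pytest.approx(1.7e-9, rel=1e-9)

    def test_isotropic_voxels_excluded(self, p3):
        # half the voxels are isotropic (FA ~ 0); selection must skip them
        aniso = _prolate_tensor_signal(p3, (1.6e-9, 0.2e-9), [1, 0, 0])
        iso = np.exp(-p3.b_si * 1.0e-9)
        dwi = np.zeros((4, 2, 1, p3.n_volumes))
        dwi[:, 0, 0] = aniso
        dwi[:, 1, 0] = iso
        mask = np.ones((4, 2, 1), dtype=bool)
        est = estimate_parallel_diffusivity(dwi, p3, mask)
        assert est == pytest.approx(1.6e-9, rel=1e-6)

    def test_fa_closed_form(self):
        # prolate (1.6, 0.2, 0.2): FA by the eigenvalue formula
        evals = np.array([0.2, 0.2, 1.6])
        md = evals.mean()
        expected = np.sqrt(1.5 * np.sum((evals - md) ** 2) / np.sum(evals**2))
        assert fractional_anisotropy(evals) == pytest.approx(expected)
        assert fractional_anisotropy(evals) > 0.8

    def test_single_shell_high_b_rejected(self):
        from mccsd.acquisition import build_protocol

        p2 = build_protocol("P2", 0)
        with pytest.raises(DegenerateFitError):
            estimate_parallel_diffusivity(
                np.ones((2, 2, 1, p2.n_volumes)), p2, np.ones((2, 2, 1))
            )


class TestFitVolume:
    def test_homogeneous_block_identical_params(self, p3, wm_signal):
        dwi = np.tile(wm_signal, (3, 3, 1, 1))
        mask = np.ones((3, 3, 1), dtype=bool)
        params, maps = fit_volume(dwi, p3, mask, 1.7e-9)
        assert len(params) == 9
        vals = {p.fb for p in params.values()}
        assert len(vals) == 1
        assert maps["failed"].sum() == 0

    def test_empty_mask(self, p3, wm_signal):
        dwi = np.tile(wm_signal, (2, 2, 1, 1))
        params, maps = fit_volume(dwi, p3, np.zeros((2, 2, 1)), 1.7e-9)
        assert params == {}
        assert maps["fb"].sum() == 0

    def test_blocks_ordered_by_isotropic_fraction(self, p3):
        edema = MCParams(fb=0.6, fcsf=0.4, fr=0.6, lambda_iso=2.2e-9,
                        lambda_par=1.7e-9, mu=[1.0, 0.0, 0.0])
        wm = MCParams(fb=0.1, fcsf=0.4, fr=0.6, lambda_iso=2.2e-9,
                      lambda_par=1.7e-9, mu=[1.0, 0.0, 0.0])
        dwi = np.zeros((2, 2, 1, p3.n_volumes))
        dwi[0] = mc_signal(edema, p3)
        dwi[1] = mc_signal(wm, p3)
        params, maps = fit_volume(dwi, p3, np.ones((2, 2, 1)), 1.7e-9)
        assert maps["fb"][0].mean() > maps["fb"][1].mean()

    def test_shape_mismatch_rejected(self, p3, wm_signal):
        dwi = np.tile(wm_signal, (2, 2, 1, 1))
        with pytest.raises(ValueError):
            fit_volume(dwi, p3, np.ones((3, 3, 1)), 1.7e-9)
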