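import numpy as np
import pytest

from mccsd._sphere import (
    axial_angle_deg,
    fibonacci_hemisphere,
    fibonacci_sphere,
    random_rotation,
)
from mccsd.compartments import MCParams, mc_signal
from mccsd.csd import (
    CSDConfig,
    FODCoefficients,
    SHBasis,
    convolve_fod,
    fit_csd,
    fit_super_csd,
    fod_amplitudes,
    kernel_rotational_harmonics,
    n_coefficients,
    sh_design_matrix,
)

Y00 = 1.0 / (2.0 * np.sqrt(np.pi))


class TestSHBasis:
    def test_coefficient_count(self):
        assert SHBasis(0).n_coeffs == 1
        assert SHBasis(8).n_coeffs == 45
        assert n_coefficients(12) == 91

    def test_odd_lmax_rejected(self):
        with pytest.raises(ValueError):
            SHBasis(7)

    def test_l0_is_constant(self):
        B = sh_design_matrix(fibonacci_hemisphere(50), SHBasis(0))
        np.testing.assert_allclose(B, Y00, rtol=1e-12)

    def test_orthonormal_by_quadrature(self):
        # Gram matrix over a near-uniform sphere approximates the identity
        pts = fibonacci_sphere(2000)
        B = sh_design_matrix(pts, SHBasis(8))
        G = B.T @ B * (4 * np.pi / 2000)
        assert np.abs(G - np.eye(B.shape[1])).max() < 1e-3

    def test_antipodal_columns_identical(self):
        d = fibonacci_hemisphere(30)
        Bp = sh_design_matrix(d, SHBasis(8))
        Bm = sh_design_matrix(-d, SHBasis(8))
        np.testing.assert_allclose(Bp, Bm, atol=1e-12)


class TestFODAmplitudes:
    def test_isotropic_coefficients(self):
        c = np.zeros(45)
        c[0] = 1.0
        amps = fod_amplitudes(c, fibonacci_hemisphere(100))
        np.testing.assert_allclose(amps, Y00, rtol=1e-12)

    def test_even_symmetry(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal(45)
        d = fibonacci_hemisphere(64)
        np.testing.assert_allclose(
            fod_amplitudes(c, d), fod_amplitudes(c, -d), atol=1e-12
        )


@pytest.fixture(scope="module")
def edema_params():
    return MCParams(fb=0.4, fcsf=0.3, fr=0.6, lambda_iso=2.4e-9,
                    lambda_par=1.7e-9, mu=[0.0, 0.0, 1.0])


class TestKernel:
    def test_pure_isotropic_has_no_angular_structure(self, p3):
        p = MCParams(fb=1.0, fcsf=0.4, fr=0.6, lambda_iso=2.4e-9,
                     lambda_par=1.7e-9, mu=[0.0, 0.0, 1.0])
        r = kernel_rotational_harmonics(p, p3, 8)
        assert np.abs(r[:, 1:]).max() < 1e-10

    def test_b0_shell_is_unit_constant(self, p3, edema_params):
        r = kernel_rotational_harmonics(edema_params, p3, 8)
        # shell 0 is b=0: kernel amplitude 1 everywhere -> r_0 = 2 sqrt(pi)
        assert r[0, 0] == pytest.approx(2.0 * np.sqrt(np.pi), rel=1e-10)
        assert np.abs(r[0, 1:]).max() < 1e-12

    def test_matches_direct_spherical_convolution(self, p3, edema_params):
        # brute-force oracle: (f * K)(n) = sum_u f(u) K(n.u) dOmega on a
        # dense sphere, compared with the SH-domain product
        rng = np.random.default_rng(0)
        lmax = 8
        r = kernel_rotational_harmonics(edema_params, p3, lmax)
        c = rng.standard_normal(n_coefficients(lmax))
        sph = fibonacci_sphere(20000)
        f = sh_design_matrix(sph, SHBasis(lmax)) @ c
        shell = 3  # b = 2000
        b_si = p3.shell_bvalues[shell] * 1e6
        p = edema_params
        lperp = p.lambda_perp

        def kern(ct2):
            iso = p.fcsf * np.exp(-b_si * p.lambda_csf) + (
                1 - p.fcsf
            ) * np.exp(-b_si * p.lambda_iso)
            aniso = p.fr * np.exp(-b_si * p.lambda_par * ct2) + (
                1 - p.fr
            ) * np.exp(-b_si * (lperp + (p.lambda_par - lperp) * ct2))
            return p.fb * iso + (1 - p.fb) * aniso

        test_dirs = fibonacci_hemisphere(10)
        direct = np.array(
            [np.sum(f * kern((sph @ n) ** 2)) * (4 * np.pi / len(sph)) for n in test_dirs]
        )
        cp = convolve_fod(r[shell], c, lmax)
        via_sh = sh_design_matrix(test_dirs, SHBasis(lmax)) @ cp
        assert np.abs(direct - via_sh).max() / np.abs(direct).max() < 1e-4

    def test_convolution_linearity(self, p3, edema_params):
        rng = np.random.default_rng(1)
        r = kernel_rotational_harmonics(edema_params, p3, 8)[2]
        c1, c2 = rng.standard_normal((2, 45))
        np.testing.assert_allclose(
            convolve_fod(r, 2.0 * c1 + c2, 8),
            2.0 * convolve_fod(r, c1, 8) + convolve_fod(r, c2, 8),
            rtol=1e-12,
        )


def _single_fiber_setup(p3, mu, fb=0.0):
    truth = MCParams(fb=fb, fcsf=0.0 if fb == 0 else 0.5, fr=0.6,
                     lambda_iso=2.4e-9, lambda_par=1.7e-9, mu=mu)
    return mc_signal(truth, p3), truth


class TestCSD:
    def test_single_fiber_peak_location(self, p3):
        sig, truth = _single_fiber_setup(p3, [0.0, 0.0, 1.0])
        fod = fit_csd(sig, p3, truth)
        sphere = fibonacci_hemisphere(5000)
        amps = fod.amplitudes(sphere)
        peak_dir = sphere[np.argmax(amps)]
        assert axial_angle_deg(peak_dir, [0, 0, 1]) < 2.0

    def test_pure_isotropic_fod_is_flat(self, p3):
        p = MCParams(fb=1.0, fcsf=0.4, fr=0.6, lambda_iso=2.4e-9,
                     lambda_par=1.7e-9, mu=[0.0, 0.0, 1.0])
        sig = mc_signal(p, p3)
        fod = fit_csd(sig, p3, p)
        assert np.abs(fod.c[1:]).max() <= 1e-6 * abs(fod.c[0])

    def test_sharpness_of_single_fiber_fod(self, p3):
        sig, truth = _single_fiber_setup(p3, [0.0, 0.0, 1.0])
        fod = fit_csd(sig, p3, truth)
        amps = fod.amplitudes(fibonacci_hemisphere(1000))
        assert amps.max() > 3.0 * amps.mean()

    def test_soft_nonnegativity_after_convergence(self, p3):
        # soft-constrained deconvolution suppresses but does not eliminate
        # negative lobes; residual negativity stays ~1% of the peak
        sig, truth = _single_fiber_setup(p3, [0.6, 0.0, 0.8])
        fod = fit_super_csd(sig, p3, truth, CSDConfig(lmax_final=12))
        amps = fod.amplitudes(fibonacci_hemisphere(724))
        assert amps.min() >= -0.02 * amps.max()

    def test_stronger_regularization_reduces_negativity(self, p3):
        # raising the constraint weight monotonically shrinks both the
        # deepest negative amplitude and the total negative mass
        sig, truth = _single_fiber_setup(p3, [0.6, 0.0, 0.8])
        sphere = fibonacci_hemisphere(724)
        depth, mass = [], []
        for lam in (0.2, 1.0, 5.0):
            fod = fit_super_csd(sig, p3, truth,
                                CSDConfig(reg_lambda=lam, lmax_final=12))
            a = fod.amplitudes(sphere)
            depth.append(a.min() / a.max())
            mass.append(a[a < 0].sum() / a.max())
        assert depth[0] <= depth[1] <= depth[2]
        assert mass[0] <= mass[1] <= mass[2]

    def test_super_csd_degenerates_to_csd(self, p3):
        sig, truth = _single_fiber_setup(p3, [0.0, 0.0, 1.0])
        cfg = CSDConfig(lmax_initial=8, lmax_final=8)
        a = fit_csd(sig, p3, truth, cfg)
        b = fit_super_csd(sig, p3, truth, cfg)
        np.testing.assert_allclose(a.c, b.c, atol=1e-10)

    def test_rotation_equivariance_of_recovered_peak(self, p3):
        rng = np.random.default_rng(5)
        R = random_rotation(rng)
        mu = np.array([0.0, 0.0, 1.0])
        sphere = fibonacci_hemisphere(5000)
        for m in (mu, R @ mu):
            sig, truth = _single_fiber_setup(p3, m)
            fod = fit_super_csd(sig, p3, truth, CSDConfig(lmax_final=12))
            peak = sphere[np.argmax(fod.amplitudes(sphere))]
            assert axial_angle_deg(peak, m) < 2.0

    def test_fod_image_axis_length(self):
        assert n_coefficients(12) == 91
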