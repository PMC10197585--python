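"""Spherical-harmonic machinery and constrained spherical deconvolution.

The FOD is expanded in a real, orthonormal, even-order symmetric SH basis
(l ascending, m from -l to l within each l). The per-voxel single-fiber
response is the full fixed multi-compartment signal with its axis along z;
because the isotropic bundle is rotation invariant it contributes only to
l = 0, so deconvolving with the full kernel implicitly removes the isotropic
(free + hindered water) signal from the angular structure of the FOD.

Deconvolution follows the iterative soft-constraint scheme of classical CSD:
re-solve a stacked least-squares system where directions on a dense
constraint sphere whose current FOD amplitude falls below a threshold tau are
driven toward zero, until the constraint set stops changing. Super-resolved
CSD re-solves at a higher lmax than the acquired directions support, with the
same data rows and the non-negativity rows regularizing the extra orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

from ._sphere import fibonacci_hemisphere
from .acquisition import AcquisitionScheme
from .compartments import MCParams


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

def n_coefficients(lmax: int) -> int:
    """Number of even-order real SH coefficients up to lmax."""
    return (lmax + 1) * (lmax + 2) // 2


@dataclass(frozen=True)
class SHBasis:
    """Real symmetric (even-l) orthonormal spherical-harmonic basis."""

    lmax: int

    def __post_init__(self):
        if self.lmax < 0 or self.lmax % 2 != 0:
            raise ValueError("lmax must be an even non-negative integer")

    @property
    def n_coeffs(self) -> int:
        return n_coefficients(self.lmax)

    @property
    def degrees(self) -> np.ndarray:
        """Degree l of each coefficient, in basis order."""
        out = []
        for l in range(0, self.lmax + 1, 2):
            out.extend([l] * (2 * l + 1))
        return np.array(out)

    @property
    def orders(self) -> np.ndarray:
        """Order m of each coefficient, in basis order."""
        out = []
        for l in range(0, self.lmax + 1, 2):
            out.extend(range(-l, l + 1))
        return np.array(out)


def _cart_to_sph(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return theta, phi


def sh_design_matrix(directions: np.ndarray, basis: SHBasis) -> np.ndarray:
    """Evaluate every basis function at every direction.

    Returns a (n_directions, n_coeffs) matrix B with B[i, k] = Y_k(n_i).
    Real basis from the complex harmonics Y_l^m: m = 0 keeps Re(Y_l^0);
    m > 0 maps to sqrt(2)(-1)^m Re(Y_l^m); m < 0 to sqrt(2)(-1)^m Im(Y_l^|m|).
    Even l only, so columns are identical at n and -n.
    """
    theta, phi = _cart_to_sph(directions)
    cols = []
    for l in range(0, basis.lmax + 1, 2):
        # complex harmonics for m = 0..l at all points, shape (l+1, N)
        y = sph_harm_y(l, np.arange(l + 1)[:, None], theta[None, :], phi[None, :])
        sign = (-1.0) ** np.arange(1, l + 1)[:, None]
        negm = np.sqrt(2.0) * sign * y[1:].imag  # m = -1..-l
        posm = np.sqrt(2.0) * sign * y[1:].real  # m = 1..l
        cols.append(np.vstack([negm[::-1], y[0].real[None, :], posm]))
    return np.vstack(cols).T


def fod_amplitudes(coeffs: np.ndarray, directions: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """FOD amplitude at each direction for a coefficient vector."""
    c = np.asarray(coeffs, dtype=float)
    if lmax is None:
        lmax = lmax_from_ncoeffs(len(c))
    return sh_design_matrix(directions, SHBasis(lmax)) @ c


def lmax_from_ncoeffs(n: int) -> int:
    lmax = int(np.rint((-3.0 + np.sqrt(1.0 + 8.0 * n)) / 2.0))
    if n_coefficients(lmax) != n:
        raise ValueError(f"{n} is not a valid even-order SH coefficient count")
    return lmax


@dataclass(frozen=True)
class FODCoefficients:
    """Even-order real SH coefficients of a fiber orientation distribution."""

    c: np.ndarray
    lmax: int
    converged: bool = True

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if len(c) != n_coefficients(self.lmax):
            raise ValueError("coefficient length inconsistent with lmax")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "c", c)

    def amplitudes(self, directions: np.ndarray) -> np.ndarray:
        return fod_amplitudes(self.c, directions, self.lmax)


# ---------------------------------------------------------------------------
# response kernel
# ---------------------------------------------------------------------------

_GL_NODES = 96  # Gauss-Legendre nodes over cos(theta); exact for l <= 190


def kernel_rotational_harmonics(
    params: MCParams, scheme: AcquisitionScheme, lmax: int
) -> np.ndarray:
    """Rotational harmonic coefficients r_l(shell) of the fixed-voxel kernel.

    For each shell the full mixture signal with mu along z is projected onto
    the m = 0 harmonics: r_l = 2*pi * int_{-1}^{1} E(t) Y_l0(t) dt with
    t = cos(theta), by Gauss-Legendre quadrature. Isotropic terms contribute
    only to l = 0. Returns an (n_shells, lmax//2 + 1) array indexed by shell
    id and l/2.
    """
    t, w = np.polynomial.legendre.leggauss(_GL_NODES)
    shell_b = scheme.shell_bvalues * 1e6
    ls = np.arange(0, lmax + 1, 2)
    # orthonormal zonal harmonic Y_l0(t) = sqrt((2l+1)/4pi) P_l(t)
    y_l0 = (
        np.sqrt((2 * ls[:, None] + 1) / (4 * np.pi)) * eval_legendre(ls[:, None], t)
    )
    lperp = params.lambda_perp
    out = np.empty((len(shell_b), len(ls)))
    for s, b in enumerate(shell_b):
        iso = params.fcsf * np.exp(-b * params.lambda_csf) + (
            1.0 - params.fcsf
        ) * np.exp(-b * params.lambda_iso)
        stick = np.exp(-b * params.lambda_par * t**2)
        zepp = np.exp(-b * (lperp + (params.lambda_par - lperp) * t**2))
        e = params.fb * iso + (1.0 - params.fb) * (
            params.fr * stick + (1.0 - params.fr) * zepp
        )
        out[s] = 2.0 * np.pi * (y_l0 * (w * e)[None, :]).sum(axis=1)
    return out


def convolve_fod(r_l: np.ndarray, coeffs: np.ndarray, lmax: int) -> np.ndarray:
    """SH-domain spherical convolution: c'_lm = c_lm * r_l * sqrt(4pi/(2l+1)).

    ``r_l`` is one row of :func:`kernel_rotational_harmonics` (a single shell).
    """
    basis = SHBasis(lmax)
    l = basis.degrees
    return np.asarray(coeffs) * r_l[l // 2] * np.sqrt(4.0 * np.pi / (2 * l + 1))


# ---------------------------------------------------------------------------
# constrained deconvolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSDConfig:
    """Settings of the constrained deconvolution.

    reg_lambda is the soft non-negativity weight and tau_fraction the
    amplitude threshold as a fraction of the mean initial FOD amplitude;
    their defaults (1 and 0.1) are the standard operating point of CSD.
    """

    reg_lambda: float = 1.0
    tau_fraction: float = 0.1
    constraint_sphere_size: int = 724
    max_iters: int = 50
    lmax_initial: int = 8
    lmax_final: int = 12

    def __post_init__(self):
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be non-negative")
        if self.lmax_final < self.lmax_initial:
            raise ValueError("lmax_final must be >= lmax_initial")


def _forward_matrix(
    scheme: AcquisitionScheme, params: MCParams, lmax: int
) -> np.ndarray:
    """Stacked per-shell convolution design matrix A with A @ c ~ signal."""
    basis = SHBasis(lmax)
    r = kernel_rotational_harmonics(params, scheme, lmax)
    B = sh_design_matrix(scheme.directions, basis)
    l = basis.degrees
    scale = np.sqrt(4.0 * np.pi / (2 * l + 1))
    # per-volume kernel factor, picking each volume's shell row of r
    factor = r[scheme.shell_ids][:, l // 2] * scale[None, :]
    A = B * factor
    # b=0 volumes carry no orientation: the convolved signal there is the
    # kernel's l=0 (mean) value regardless of direction
    b0 = scheme.b0_mask
    if np.any(b0):
        y00 = 1.0 / (2.0 * np.sqrt(np.pi))
        A[b0] = 0.0
        A[b0, 0] = r[scheme.shell_ids[b0], 0] * np.sqrt(4.0 * np.pi) * y00
    return A


def _iterate_constraints(
    A: np.ndarray,
    signal: np.ndarray,
    B_con: np.ndarray,
    c0: np.ndarray,
    tau: float,
    config: CSDConfig,
) -> tuple[np.ndarray, bool]:
    """Constraint-set fixed-point iteration shared by CSD and super-CSD."""
    # weight balancing the constraint block against the data block, so
    # reg_lambda = 1 is a comparable soft weight across protocols
    lam = config.reg_lambda * np.linalg.norm(A) / np.linalg.norm(B_con)
    c = c0.copy()
    prev: np.ndarray | None = None
    converged = False
    for _ in range(config.max_iters):
        amp = B_con @ c
        active = amp < tau
        if prev is not None and np.array_equal(active, prev):
            converged = True
            break
        prev = active
        if not np.any(active):
            converged = True
            break
        M = np.vstack([A, lam * B_con[active]])
        y = np.concatenate([signal, np.zeros(active.sum())])
        sol, *_ = np.linalg.lstsq(M, y, rcond=None)
        c = sol
    return c, converged


def fit_csd(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    params: MCParams,
    config: CSDConfig = CSDConfig(),
) -> FODCoefficients:
    """Deconvolve the voxel-specific kernel from the signal at lmax_initial.

    Initializes with the unconstrained least-squares FOD, then iterates the
    soft non-negativity constraint (amplitudes below tau on the constraint
    sphere pulled toward zero) to a constraint-set fixed point.
    """
    lmax = config.lmax_initial
    A = _forward_matrix(scheme, params, lmax)
    sphere = fibonacci_hemisphere(config.constraint_sphere_size)
    B_con = sh_design_matrix(sphere, SHBasis(lmax))
    signal = np.asarray(signal, dtype=float)

    c0, *_ = np.linalg.lstsq(A, signal, rcond=None)
    if not np.all(np.isfinite(c0)):
        iso = np.zeros(n_coefficients(lmax))
        iso[0] = 2.0 * np.sqrt(np.pi) * float(np.mean(signal[scheme.b0_mask]))
        return FODCoefficients(iso, lmax, converged=False)
    tau = config.tau_fraction * float(np.mean(B_con @ c0))
    c, converged = _iterate_constraints(A, signal, B_con, c0, tau, config)
    return FODCoefficients(c, lmax, converged=converged)


def fit_super_csd(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    params: MCParams,
    config: CSDConfig = CSDConfig(),
) -> FODCoefficients:
    """Super-resolved CSD at lmax_final, seeded by the lmax_initial fit.

    The data rows constrain only the acquired directions; the dense
    non-negativity rows regularize the orders the data alone cannot support,
    which is what lets lmax exceed the direction count.
    """
    init = fit_csd(signal, scheme, params, config)
    lmax = config.lmax_final
    if lmax == config.lmax_initial:
        return init
    A = _forward_matrix(scheme, params, lmax)
    sphere = fibonacci_hemisphere(config.constraint_sphere_size)
    B_con = sh_design_matrix(sphere, SHBasis(lmax))
    c0 = np.zeros(n_coefficients(lmax))
    c0[: len(init.c)] = init.c
    tau = config.tau_fraction * float(
        np.mean(sh_design_matrix(sphere, SHBasis(init.lmax)) @ init.c)
    )
    c, converged = _iterate_constraints(
        A, np.asarray(signal, dtype=float), B_con, c0, tau, config
    )
    return FODCoefficients(c, lmax, converged=converged and init.converged)
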