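"""Cascaded per-voxel fitting of the four-compartment mixture.

Stage 1 fits a single isotropic ball to estimate the hindered-water
diffusivity lambda_iso within [0.1, 3] x 1e-9 m^2/s. Stage 2 fits the full
mixture with lambda_iso and lambda_par held fixed: a brute-force grid over
the volume fractions and an axial orientation grid locates the basin, then a
bounded quasi-Newton (L-BFGS-B) refinement polishes it. If the prefit finds
lambda_iso <= lambda_par the isotropic bundle cannot be split from slow
hindered water, so fcsf collapses to 1 (pure free water) and only
(fb, fr, mu) remain free. lambda_perp is always tortuosity-derived.

For in vivo data lambda_par is estimated from high-FA white-matter voxels by
a single-tensor fit on the low-b shells; simulations fix it at the known
ground-truth value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._sphere import fibonacci_hemisphere
from .acquisition import AcquisitionScheme
from .compartments import LAMBDA_CSF, LAMBDA_ISO_BOUNDS, MCParams, canonical_axis


@dataclass(frozen=True)
class IsotropicFit:
    """Result of the single-ball prefit."""

    lambda_iso: float
    rss: float

    def __post_init__(self):
        lo, hi = LAMBDA_ISO_BOUNDS
        if not lo <= self.lambda_iso <= hi:
            raise ValueError("lambda_iso outside prefit bounds")


@dataclass(frozen=True)
class FitConfig:
    """Brute-force grid resolution and local-refinement settings.

    ``n_starts`` local refinements are launched from the best grid points;
    the mixture cost surface has shallow secondary basins (orientation vs
    fraction trade-offs) that a single start occasionally lands in.
    """

    grid_points_per_fraction: int = 5
    orientation_grid_size: int = 30
    max_local_iters: int = 200
    n_starts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.grid_points_per_fraction < 3:
            raise ValueError("need at least 3 grid points per fraction")
        if self.orientation_grid_size < 1:
            raise ValueError("orientation grid must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be positive")


class DegenerateFitError(ValueError):
    """Raised when a scheme cannot support the requested fit."""


def fit_isotropic_ball(
    signal: np.ndarray, scheme: AcquisitionScheme
) -> IsotropicFit:
    """Least-squares single-ball fit of lambda_iso over its bounded interval."""
    if np.all(scheme.b0_mask):
        raise DegenerateFitError("scheme has no diffusion-weighted volumes")
    signal = np.asarray(signal, dtype=float)
    b = scheme.b_si

    def cost(lam: float) -> float:
        r = signal - np.exp(-b * lam)
        return float(r @ r)

    lo, hi = LAMBDA_ISO_BOUNDS
    res = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-16})
    lam = float(np.clip(res.x, lo, hi))
    # bounded Brent can stall a hair inside the interval ends; check them
    for edge in (lo, hi):
        if cost(edge) < cost(lam):
            lam = edge
    return IsotropicFit(lambda_iso=lam, rss=cost(lam))


# ---------------------------------------------------------------------------
# full mixture fit
# ---------------------------------------------------------------------------

def _mixture_residuals(
    fb, fcsf, fr, ct2, signal, b, lambda_iso, lambda_par
):
    """Sum of squared residuals, broadcasting over parameter arrays.

    ct2 has shape (..., n_volumes) of squared direction cosines; fraction
    arguments broadcast against its leading axes.
    """
    iso = fcsf * np.exp(-b * LAMBDA_CSF) + (1.0 - fcsf) * np.exp(-b * lambda_iso)
    lperp = (1.0 - fr) * lambda_par
    stick = np.exp(-b * lambda_par * ct2)
    zepp = np.exp(-b * (lperp + (lambda_par - lperp) * ct2))
    model = fb * iso + (1.0 - fb) * (fr * stick + (1.0 - fr) * zepp)
    r = model - signal
    return np.sum(r * r, axis=-1)


def _sph_to_unit(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


_ANGLE_BOUNDS = [(-np.pi, 2 * np.pi), (-2 * np.pi, 3 * np.pi)]


def fit_mc_voxel(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    lambda_par: float,
    config: FitConfig = FitConfig(),
    iso_fit: IsotropicFit | None = None,
) -> MCParams:
    """Fit (fb, fcsf, fr, lambda_iso, mu) by grid search plus refinement.

    The brute-force stage evaluates the cost on the full Cartesian product of
    fraction grids and an axial orientation grid at the prefit lambda_iso;
    L-BFGS-B then refines fractions, orientation and lambda_iso (bounded to
    the prefit interval). If the refined lambda_iso does not exceed
    lambda_par the isotropic bundle is indistinguishable from free water:
    the collapse rule fixes fcsf = 1 and the voxel is refit without it.
    """
    signal = np.asarray(signal, dtype=float)
    if iso_fit is None:
        iso_fit = fit_isotropic_ball(signal, scheme)
    b = scheme.b_si

    axes = fibonacci_hemisphere(config.orientation_grid_size)
    ct2_grid = (scheme.directions @ axes.T).T ** 2  # (n_axes, n_volumes)
    fgrid = np.linspace(0.0, 1.0, config.grid_points_per_fraction)
    lo, hi = LAMBDA_ISO_BOUNDS

    def grid_init(collapsed: bool):
        """Best ``n_starts`` grid points (fractions + axis) and the grid cost."""
        if collapsed:
            fb_g, fr_g = np.meshgrid(fgrid, fgrid, indexing="ij")
            fcsf_g = np.ones_like(fb_g)
        else:
            fb_g, fcsf_g, fr_g = np.meshgrid(fgrid, fgrid, fgrid, indexing="ij")
        fb_g = fb_g.ravel()[:, None, None]
        fcsf_g = fcsf_g.ravel()[:, None, None]
        fr_g = fr_g.ravel()[:, None, None]
        cost = _mixture_residuals(
            fb_g, fcsf_g, fr_g, ct2_grid[None], signal, b,
            iso_fit.lambda_iso, lambda_par,
        )
        order = np.argsort(cost.ravel(), kind="stable")[: config.n_starts]
        starts = []
        for flat in order:
            k, a = np.unravel_index(flat, cost.shape)
            mu0 = axes[a]
            theta0 = float(np.arccos(np.clip(mu0[2], -1.0, 1.0)))
            phi0 = float(np.arctan2(mu0[1], mu0[0]))
            starts.append(
                (fb_g.ravel()[k], fcsf_g.ravel()[k], fr_g.ravel()[k],
                 theta0, phi0)
            )
        return starts, float(cost.ravel()[order[0]])

    def refine(collapsed: bool, x_start=None):
        grid_starts, grid_cost = grid_init(collapsed)

        def local_cost(x: np.ndarray) -> float:
            if collapsed:
                fb, fr, th, ph = x
                fcsf, liso = 1.0, iso_fit.lambda_iso
            else:
                fb, fcsf, fr, liso9, th, ph = x
                liso = liso9 * 1e-9
            mu = _sph_to_unit(th, ph)
            ct2 = (scheme.directions @ mu) ** 2
            return float(
                _mixture_residuals(fb, fcsf, fr, ct2, signal, b, liso, lambda_par)
            )

        if collapsed:
            starts = [[fb0, fr0, th0, ph0] for fb0, _, fr0, th0, ph0 in grid_starts]
            bounds = [(0.0, 1.0)] * 2 + _ANGLE_BOUNDS
        else:
            # lambda_iso optimized in units of 1e-9 m^2/s so all variables
            # are O(1) for the quasi-Newton line search
            starts = [
                [fb0, fcsf0, fr0, iso_fit.lambda_iso * 1e9, th0, ph0]
                for fb0, fcsf0, fr0, th0, ph0 in grid_starts
            ]
            bounds = [(0.0, 1.0)] * 3 + [(lo * 1e9, hi * 1e9)] + _ANGLE_BOUNDS
        if x_start is not None:
            starts.append(x_start)
        best_x, best_f = np.array(starts[0]), grid_cost
        for s in starts:
            res = minimize(
                local_cost, s, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.max_local_iters,
                         "ftol": 1e-16, "gtol": 1e-12},
            )
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
        return best_x, best_f

    x, rss = refine(collapsed=False)
    fb, fcsf, fr, liso9, th, ph = x
    lambda_iso = float(liso9 * 1e-9)
    if lambda_iso <= lambda_par:
        # free-water collapse: refit with the isotropic bundle as one
        # free-water ball (fcsf = 1), warm-started from the free solution;
        # lambda_iso keeps the prefit estimate (unused once fcsf = 1)
        x, rss = refine(collapsed=True, x_start=[fb, fr, th, ph])
        fb, fr, th, ph = x
        fcsf = 1.0
        lambda_iso = iso_fit.lambda_iso
    if not np.isfinite(rss):
        raise DegenerateFitError("non-finite cost in voxel fit")
    mu = canonical_axis(_sph_to_unit(th, ph))

    def clip01(v):
        return float(np.clip(v, 0.0, 1.0))

    return MCParams(
        fb=clip01(fb),
        fcsf=clip01(fcsf),
        fr=clip01(fr),
        lambda_iso=lambda_iso,
        lambda_par=lambda_par,
        mu=mu,
        rss=rss,
    )


# ---------------------------------------------------------------------------
# lambda_par from high-FA voxels
# ---------------------------------------------------------------------------

def _dti_design(scheme: AcquisitionScheme, keep: np.ndarray) -> np.ndarray:
    g = scheme.directions[keep]
    b = scheme.b_si[keep]
    gx, gy, gz = g.T
    return np.column_stack(
        [
            np.ones(len(b)),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def _tensor_eigs(coef: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    return np.linalg.eigvalsh(D)  # ascending


def fractional_anisotropy(eigs: np.ndarray) -> float:
    """FA of a tensor from its eigenvalues."""
    md = eigs.mean()
    num = np.sum((eigs - md) ** 2)
    den = np.sum(eigs**2)
    if den <= 0:
        return 0.0
    return float(np.sqrt(1.5 * num / den))


def estimate_parallel_diffusivity(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray,
    fa_threshold: float = 0.7,
    n_voxels: int = 300,
    max_bvalue: float = 1000.0,
) -> float:
    """Mean axial diffusivity over automatically selected high-FA voxels.

    Fits a single diffusion tensor per masked voxel by linear least squares
    on the log-signal, using only shells with b <= ``max_bvalue`` s/mm^2
    (Gaussian models degrade at stronger weighting). Selects up to
    ``n_voxels`` voxels with FA above ``fa_threshold`` (falling back to the
    top ``n_voxels`` by FA) and returns their mean largest eigenvalue.
    """
    keep = scheme.bvalues <= max_bvalue
    n_dirs = len(np.unique(np.round(scheme.directions[keep & ~scheme.b0_mask], 6), axis=0))
    if n_dirs < 6:
        raise DegenerateFitError("need >= 6 distinct directions at b <= 1000 s/mm^2")
    X = _dti_design(scheme, keep)
    pinv = np.linalg.pinv(X)

    vox = np.argwhere(np.asarray(mask) != 0)
    fas, axials = [], []
    for idx in vox:
        s = np.asarray(dwi[tuple(idx)], dtype=float)[keep]
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            continue
        beta = pinv @ np.log(s)
        eigs = _tensor_eigs(beta[1:])
        if eigs[0] < -1e-10:  # non-physical fit
            continue
        fas.append(fractional_anisotropy(eigs))
        axials.append(eigs[-1])
    if not fas:
        raise DegenerateFitError("no voxel admitted a valid tensor fit")
    fas = np.asarray(fas)
    axials = np.asarray(axials)
    qualified = np.flatnonzero(fas > fa_threshold)
    if len(qualified) >= 1:
        sel = qualified[np.argsort(fas[qualified])[::-1][:n_voxels]]
    else:
        sel = np.argsort(fas)[::-1][:n_voxels]
    return float(axials[sel].mean())


# ---------------------------------------------------------------------------
# whole-volume fit
# ---------------------------------------------------------------------------

def fit_volume(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray,
    lambda_par: float,
    config: FitConfig = FitConfig(),
):
    """Run the cascade in every masked voxel of a normalized 4D volume.

    Returns ``(params, maps)`` where ``params`` maps voxel index tuples to
    MCParams and ``maps`` is a dict of 3D float arrays (fb, fcsf, fr,
    lambda_iso, rss, failed); unmasked voxels are zero.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask)
    if dwi.shape[:3] != mask.shape:
        raise ValueError("mask shape does not match DWI grid")
    if dwi.shape[3] != scheme.n_volumes:
        raise ValueError("DWI volume count does not match scheme")
    shape = mask.shape
    maps = {
        k: np.zeros(shape) for k in ("fb", "fcsf", "fr", "lambda_iso", "rss", "failed")
    }
    params: dict[tuple[int, int, int], MCParams] = {}
    for idx in map(tuple, np.argwhere(mask != 0)):
        try:
            p = fit_mc_voxel(dwi[idx], scheme, lambda_par, config)
        except DegenerateFitError:
            maps["failed"][idx] = 1.0
            continue
        params[idx] = p
        maps["fb"][idx] = p.fb
        maps["fcsf"][idx] = p.fcsf
        maps["fr"][idx] = p.fr
        maps["lambda_iso"][idx] = p.lambda_iso
        maps["rss"][idx] = p.rss
    return params, maps
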