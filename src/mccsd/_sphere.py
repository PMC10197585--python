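"""Hemisphere point sets for sampling axial (antipodally symmetric) functions.

All direction sets returned here are unit vectors with z >= 0; a direction and
its antipode are regarded as the same axis throughout the package.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Near-uniform spiral point set on the upper hemisphere.

    Returns an (n, 3) array of unit vectors with z >= 0.
    """
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n)
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform spiral point set on the full sphere, (n, 3) unit vectors."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _antipodal_energy_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
    # Coulomb-like energy on axes: each pair interacts with both the point and
    # its antipode, so the optimum spreads axes rather than points.
    n = len(x)
    energy = 0.0
    grad = np.zeros_like(x)
    for i in range(n):
        d = x[i] - x[i + 1:]
        s = x[i] + x[i + 1:]
        dd = np.einsum("ij,ij->i", d, d)
        ss = np.einsum("ij,ij->i", s, s)
        energy += np.sum(1.0 / dd + 1.0 / ss)
        gi = -2.0 * d / dd[:, None] ** 2 + -2.0 * s / ss[:, None] ** 2
        grad[i] += gi.sum(axis=0)
        grad[i + 1:] -= -2.0 * d / dd[:, None] ** 2
        grad[i + 1:] += -2.0 * s / ss[:, None] ** 2
    return energy, grad


@lru_cache(maxsize=64)
def _electrostatic_cached(n: int, seed: int, iters: int) -> tuple:
    rng = np.random.default_rng(seed)
    x = fibonacci_hemisphere(n)
    x = x + 0.05 * rng.standard_normal(x.shape)
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 1.0 / n**2
    energy, grad = _antipodal_energy_grad(x)
    for _ in range(iters):
        # project gradient onto the tangent plane of each point
        g = grad - np.einsum("ij,ij->i", grad, x)[:, None] * x
        x_new = x - step * g
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        e_new, g_new = _antipodal_energy_grad(x_new)
        if e_new < energy:
            x, energy, grad = x_new, e_new, g_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-14:
                break
    x[x[:, 2] < 0] *= -1.0
    x.setflags(write=False)
    return (x,)


def electrostatic_hemisphere(n: int, seed: int = 0, iters: int = 300) -> np.ndarray:
    """Electrostatic-repulsion axial direction set (n, 3), deterministic in seed.

    Minimizes the pairwise Coulomb energy of each point together with its
    antipode, the standard construction for diffusion gradient tables.
    """
    return np.array(_electrostatic_cached(n, seed, iters)[0])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def axial_angle_deg(u: np.ndarray, v: np.ndarray) -> float | np.ndarray:
    """Angle between axes in degrees, in [0, 90]."""
    c = np.abs(np.sum(np.asarray(u) * np.asarray(v), axis=-1))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
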