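"""Closed-form Gaussian compartment signals and their four-compartment mixture.

The voxel model splits signal between an isotropic bundle (free water at the
fixed CSF diffusivity plus slower hindered water, two balls) and an
anisotropic bundle (restricted intra-axonal stick plus hindered extra-axonal
zeppelin sharing one parallel diffusivity). The zeppelin's perpendicular
diffusivity is tied to the intra-axonal fraction by the tortuosity relation
lambda_perp = (1 - fr) * lambda_par.

All b arguments here are SI (s/m^2); diffusivities are m^2/s, so every
exponent is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .acquisition import AcquisitionScheme

#: free-water (CSF) diffusivity, m^2/s
LAMBDA_CSF = 3.0e-9

#: search bounds of the isotropic prefit, m^2/s
LAMBDA_ISO_BOUNDS = (0.1e-9, 3.0e-9)


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if not np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=1e-6):
        raise ValueError(f"{name} must be a unit vector")
    return v


def ball_signal(b, lam: float):
    """Isotropic Gaussian attenuation exp(-b*lambda)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or lam < 0:
        raise ValueError("b and lambda must be non-negative")
    return np.exp(-b * lam)


def stick_signal(b, n, mu, lambda_par: float):
    """Zero-radius cylinder attenuation exp(-b*lambda_par*(n.mu)^2).

    Antipodally symmetric in both n and mu.
    """
    b = np.asarray(b, dtype=float)
    n = _check_unit(n, "n")
    mu = _check_unit(mu, "mu")
    ct = np.sum(n * mu, axis=-1)
    return np.exp(-b * lambda_par * ct**2)


def zeppelin_signal(b, n, mu, lambda_par: float, lambda_perp: float):
    """Axially symmetric Gaussian (zeppelin) attenuation.

    Closed form exp(-b*[l_perp + (l_par - l_perp)(n.mu)^2]) of the tensor
    exponential with eigenvalues (l_par, l_perp, l_perp) aligned to mu.
    """
    if lambda_perp > lambda_par:
        raise ValueError("lambda_perp must not exceed lambda_par")
    b = np.asarray(b, dtype=float)
    n = _check_unit(n, "n")
    mu = _check_unit(mu, "mu")
    ct = np.sum(n * mu, axis=-1)
    return np.exp(-b * (lambda_perp + (lambda_par - lambda_perp) * ct**2))


@dataclass(frozen=True)
class MCParams:
    """Fitted per-voxel parameters of the four-compartment mixture.

    fb is the isotropic-bundle fraction, fcsf the free-water share within it,
    fr the intra-axonal (stick) share of the anisotropic bundle; mu is the
    bundle axis (axial). lambda_perp is always derived, never stored.
    """

    fb: float
    fcsf: float
    fr: float
    lambda_iso: float
    lambda_par: float
    mu: np.ndarray
    lambda_csf: float = LAMBDA_CSF
    rss: float = np.nan

    def __post_init__(self):
        for name in ("fb", "fcsf", "fr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        mu = _check_unit(self.mu, "mu")
        mu = canonical_axis(mu)
        mu.setflags(write=False)
        object.__setattr__(self, "mu", mu)
        if self.lambda_iso <= self.lambda_par and self.fcsf != 1.0:
            raise ValueError(
                "free-water collapse violated: lambda_iso <= lambda_par requires fcsf = 1"
            )

    @property
    def lambda_perp(self) -> float:
        """Tortuosity-constrained perpendicular diffusivity (1-fr)*lambda_par."""
        return (1.0 - self.fr) * self.lambda_par

    def with_mu(self, mu) -> "MCParams":
        return replace(self, mu=np.asarray(mu, dtype=float))


def canonical_axis(mu: np.ndarray) -> np.ndarray:
    """Pick the antipodal representative with z > 0 (then y > 0, then x > 0)."""
    mu = np.array(mu, dtype=float)
    for k in (2, 1, 0):
        if abs(mu[k]) > 1e-12:
            if mu[k] < 0:
                mu = -mu
            break
    return mu


def mc_signal(params: MCParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Normalized mixture attenuation, one value per scheme volume.

    E = fb*[fcsf*ball(l_csf) + (1-fcsf)*ball(l_iso)]
      + (1-fb)*[fr*stick + (1-fr)*zeppelin], with the tortuosity-derived
    lambda_perp. b=0 volumes give exactly 1.
    """
    b = scheme.b_si
    n = scheme.directions
    mu = params.mu
    ct2 = np.where(scheme.b0_mask, 0.0, (n @ mu) ** 2)
    iso = params.fcsf * np.exp(-b * params.lambda_csf) + (
        1.0 - params.fcsf
    ) * np.exp(-b * params.lambda_iso)
    lperp = params.lambda_perp
    stick = np.exp(-b * params.lambda_par * ct2)
    zepp = np.exp(-b * (lperp + (params.lambda_par - lperp) * ct2))
    aniso = params.fr * stick + (1.0 - params.fr) * zepp
    return params.fb * iso + (1.0 - params.fb) * aniso
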