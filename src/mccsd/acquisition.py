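"""Multi-shell diffusion acquisition schemes and FSL-style gradient tables.

b-values are user-facing in s/mm^2 and converted to SI (s/m^2, factor 1e6)
wherever they multiply a diffusivity in m^2/s, so exponents b*lambda are
dimensionless. Gradient directions are treated as axial (n and -n equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sphere import electrostatic_hemisphere

#: b-values below this (s/mm^2) count as unweighted b=0 volumes.
B0_THRESHOLD = 50.0

#: default shell clustering tolerance, s/mm^2
SHELL_TOL = 50.0


class GradientTableError(ValueError):
    """Malformed or inconsistent bval/bvec input."""


def cluster_shells(bvalues: np.ndarray, tol: float = SHELL_TOL) -> np.ndarray:
    """Assign integer shell labels by 1-D gap partitioning of the b-values.

    Volumes whose sorted b-values are separated by gaps <= ``tol`` share a
    shell; labels are 0-based in order of ascending shell b-value. The result
    does not depend on the volume order of the input.
    """
    b = np.asarray(bvalues, dtype=float)
    order = np.argsort(b, kind="stable")
    sorted_b = b[order]
    labels_sorted = np.zeros(len(b), dtype=int)
    if len(b) > 1:
        labels_sorted[1:] = np.cumsum(np.diff(sorted_b) > tol)
    labels = np.empty(len(b), dtype=int)
    labels[order] = labels_sorted
    return labels


@dataclass(frozen=True)
class AcquisitionScheme:
    """A single-diffusion-encoding multi-shell acquisition.

    Parameters
    ----------
    bvalues : (N,) array, s/mm^2
    directions : (N, 3) array of unit vectors; zero vectors allowed for b=0
    shell_ids : (N,) int array grouping volumes into shells
    delta, Delta : optional pulse duration / separation in seconds. Stored as
        metadata only; the Gaussian compartment models are diffusion-time
        independent.
    """

    bvalues: np.ndarray
    directions: np.ndarray
    shell_ids: np.ndarray
    delta: float | None = None
    Delta: float | None = None

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        d = np.asarray(self.directions, dtype=float)
        if d.shape != (len(b), 3):
            raise GradientTableError(
                f"directions shape {d.shape} does not match {len(b)} b-values"
            )
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(d))):
            raise GradientTableError("non-finite entries in gradient table")
        if np.any(b < 0):
            raise GradientTableError("negative b-values")
        norms = np.linalg.norm(d, axis=1)
        weighted = b > B0_THRESHOLD
        if np.any(weighted & (norms < 1e-12)):
            raise GradientTableError("zero direction on a diffusion-weighted volume")
        d = d.copy()
        nz = norms > 1e-12
        d[nz] /= norms[nz, None]
        if not np.any(~weighted):
            raise GradientTableError("scheme has no b=0 volume")
        b.setflags(write=False)
        d.setflags(write=False)
        sid = np.asarray(self.shell_ids, dtype=int)
        sid.setflags(write=False)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "shell_ids", sid)

    # -- derived views ------------------------------------------------------
    @property
    def n_volumes(self) -> int:
        return len(self.bvalues)

    @property
    def b_si(self) -> np.ndarray:
        """b-values in SI units, s/m^2."""
        return self.bvalues * 1e6

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues <= B0_THRESHOLD

    @property
    def shell_bvalues(self) -> np.ndarray:
        """Mean b-value (s/mm^2) per shell id, indexable by shell id."""
        nshell = self.shell_ids.max() + 1
        return np.array(
            [self.bvalues[self.shell_ids == s].mean() for s in range(nshell)]
        )

    def summary(self) -> str:
        lines = ["shell  count  b (s/mm^2)"]
        for s, b in enumerate(self.shell_bvalues):
            count = int(np.sum(self.shell_ids == s))
            lines.append(f"{s:5d}  {count:5d}  {b:10.1f}")
        return "\n".join(lines)


def _parse_numeric_table(path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise GradientTableError(f"could not parse {path}: {exc}") from exc
    if not np.all(np.isfinite(arr)):
        raise GradientTableError(f"non-finite entries in {path}")
    return arr


def load_gradient_table(
    bval_path, bvec_path, shell_tol: float = SHELL_TOL
) -> AcquisitionScheme:
    """Read FSL-style bval/bvec files into a validated scheme.

    The bvec file may be 3xN (FSL convention) or Nx3; the orientation is
    auto-detected from the bval length. Directions are renormalized.
    """
    bvals = _parse_numeric_table(bval_path).ravel()
    bvecs = _parse_numeric_table(bvec_path)
    if bvecs.shape == (3, len(bvals)):
        bvecs = bvecs.T
    elif bvecs.shape != (len(bvals), 3):
        raise GradientTableError(
            f"bvec shape {bvecs.shape} incompatible with {len(bvals)} b-values"
        )
    return AcquisitionScheme(bvals, bvecs, cluster_shells(bvals, shell_tol))


def save_gradient_table(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write FSL-style bval (1xN) and bvec (3xN) text files."""
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.16g")


#: shell layout of the simulation protocols: (b-value s/mm^2, n directions)
PROTOCOLS = {
    "P1": [(800.0, 30)],
    "P2": [(2000.0, 64)],
    "P3": [(300.0, 15), (800.0, 30), (2000.0, 64)],
}


def build_protocol(
    name: str, directions_seed: int = 0, n_b0: int = 1
) -> AcquisitionScheme:
    """Construct one of the simulation protocols P1/P2/P3.

    P1: single shell b=800 (30 directions); P2: b=2000 (64); P3: multi-shell
    b=300/800/2000 with 15/30/64 directions. ``n_b0`` unweighted volumes are
    prepended. Per-shell direction sets are electrostatic-repulsion point
    sets, reproducible from ``directions_seed``.
    """
    if name not in PROTOCOLS:
        raise ValueError(f"unknown protocol {name!r}; expected one of {list(PROTOCOLS)}")
    bvals = [np.zeros(n_b0)]
    dirs = [np.zeros((n_b0, 3))]
    for k, (b, n) in enumerate(PROTOCOLS[name]):
        bvals.append(np.full(n, b))
        dirs.append(electrostatic_hemisphere(n, seed=directions_seed + 1000 * k))
    bvals = np.concatenate(bvals)
    dirs = np.vstack(dirs)
    return AcquisitionScheme(bvals, dirs, cluster_shells(bvals))
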