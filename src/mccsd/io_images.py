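"""NIfTI input/output with strict affine passthrough.

Volumes are kept in file axis order (x, y, z, volume); nothing here
re-orients, resamples, or rescales data silently, and every output image
carries the input affine verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionScheme, load_gradient_table


@dataclass
class ImageVolume:
    """A 3D or 4D image with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    meta: str = ""

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")


class MissingB0Error(ValueError):
    """DWI volume lacks the b=0 acquisition needed for normalization."""


def read_dwi(
    nifti_path, bval_path, bvec_path, normalize: bool = False
) -> tuple[ImageVolume, AcquisitionScheme]:
    """Load a 4D DWI and its gradient table, optionally b0-normalized."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    scheme = load_gradient_table(bval_path, bvec_path)
    if data.ndim != 4 or data.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"DWI has shape {data.shape} but gradient table lists "
            f"{scheme.n_volumes} volumes"
        )
    if normalize:
        data = normalize_dwi(data, scheme)
    vol = ImageVolume(data, img.affine, meta=str(img.header.get("descrip", "")))
    return vol, scheme


def normalize_dwi(data: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Divide by the per-voxel mean b=0 signal, clipping to [0, 1.5]."""
    if not np.any(scheme.b0_mask):
        raise MissingB0Error("no b=0 volume to normalize against")
    b0 = np.asarray(data, dtype=float)[..., scheme.b0_mask].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = data / b0[..., None]
    out[~np.isfinite(out)] = 0.0
    return np.clip(out, 0.0, 1.5)


def read_mask(nifti_path, like: ImageVolume | None = None) -> np.ndarray:
    """Load a binary mask; nonzero means included."""
    img = nib.load(str(nifti_path))
    mask = np.asarray(img.dataobj) != 0
    if like is not None and mask.shape != like.data.shape[:3]:
        raise ValueError("mask grid does not match the DWI")
    return mask


def save_image(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a float NIfTI-1 image with the given affine, verbatim."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def write_outputs(
    out_dir,
    affine: np.ndarray,
    scalar_maps: dict[str, np.ndarray] | None = None,
    fod_image: np.ndarray | None = None,
    peaks_image: np.ndarray | None = None,
    manifest: dict | None = None,
) -> list[Path]:
    """Write scalar maps, FOD coefficients, peaks and a run manifest.

    The FOD image stores SH coefficients along the 4th axis (basis:
    real symmetric even-order, l ascending, m from -l to l); peaks store
    3 components x max_peaks along the 4th axis.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, arr in (scalar_maps or {}).items():
        p = out_dir / f"{name}.nii.gz"
        save_image(arr, affine, p)
        written.append(p)
    if fod_image is not None:
        p = out_dir / "fod_sh.nii.gz"
        img = nib.Nifti1Image(np.asarray(fod_image, dtype=np.float32), affine)
        img.header["descrip"] = b"real symmetric even SH; l asc, m -l..l"
        nib.save(img, str(p))
        written.append(p)
    if peaks_image is not None:
        p = out_dir / "peaks.nii.gz"
        save_image(peaks_image, affine, p)
        written.append(p)
    if manifest is not None:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written.append(p)
    return written
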