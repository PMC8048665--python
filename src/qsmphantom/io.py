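"""NIfTI volume I/O and grid-consistency helpers."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["load_volume", "save_volume", "b0_axis_from_affine", "check_common_grid"]


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Load a NIfTI-1 volume; returns (data, spacing [mm], affine).

    Warns on sheared affines (the internal grid is the voxel lattice and a
    shear cannot be represented on it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = img.affine
    rot = affine[:3, :3]
    norms = np.linalg.norm(rot, axis=0)
    norms[norms == 0] = 1.0
    unit = rot / norms
    off = unit.T @ unit - np.eye(3)
    if np.max(np.abs(off)) > 1e-3:
        warnings.warn(f"{path.name}: affine has shear/obliquity; voxel lattice assumed", stacklevel=2)
    return data, spacing, affine


def save_volume(data: np.ndarray, spacing, path, description: str | None = None) -> None:
    """Write a volume as NIfTI-1 with a diagonal (RAS) affine."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(spacing))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def b0_axis_from_affine(affine: np.ndarray) -> int:
    """Voxel axis closest to the world superior (z) direction."""
    return int(np.argmax(np.abs(affine[2, :3])))


def check_common_grid(volumes: dict[str, tuple[np.ndarray, tuple]]) -> None:
    """Fail listing offending files if shapes/spacings differ."""
    ref_name = next(iter(volumes))
    ref_shape = volumes[ref_name][0].shape
    ref_spacing = volumes[ref_name][1]
    bad = [
        name
        for name, (data, spacing) in volumes.items()
        if data.shape != ref_shape or not np.allclose(spacing, ref_spacing)
    ]
    if bad:
        raise ValueError(
            f"volumes not on the grid of {ref_name!r} ({ref_shape}, {ref_spacing}): {bad}"
        )
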