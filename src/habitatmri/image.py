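"""Lightweight 3-D image containers used throughout the pipeline.

A :class:`VolumeImage` is a scalar grid plus its physical geometry (voxel
spacing, origin, axis orientation).  A :class:`DynamicSeries` is an ordered
stack of co-registered volumes with acquisition times — one pre-contrast
phase followed by the post-contrast phases of a DCE-MRI exam.

NIfTI round-tripping goes through :mod:`nibabel`; geometry is carried in the
affine (RAS, axis-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "DynamicSeries", "load_volume", "save_volume"]


@dataclass(frozen=True)
class VolumeImage:
    """A 3-D scalar grid with voxel spacing, origin and orientation.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar voxel values.  Must be finite.
    spacing_mm : tuple of 3 floats
        Voxel size along each grid axis, in millimetres.  All positive.
    origin : tuple of 3 floats
        Physical coordinates (mm) of the centre of voxel (0, 0, 0).
    orientation : str
        Axis orientation descriptor; only axis-aligned "RAS" is produced
        by this package.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing_mm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        """Same geometry, new voxel values."""
        return replace(self, values=np.asarray(values))

    def astype(self, dtype) -> "VolumeImage":
        return self.with_values(self.values.astype(dtype))


@dataclass(frozen=True)
class DynamicSeries:
    """Co-registered dynamic volumes with acquisition times (seconds).

    Phase 0 is the pre-contrast baseline; phases 1..N are post-contrast.
    All volumes share grid shape and geometry.
    """

    phases: tuple[VolumeImage, ...]
    times_s: tuple[float, ...]

    def __post_init__(self) -> None:
        phases = tuple(self.phases)
        times = tuple(float(t) for t in self.times_s)
        if len(phases) != len(times):
            raise ValueError("phases and times_s length mismatch")
        if len(phases) < 2:
            raise ValueError("a dynamic series needs at least 2 phases")
        geom = (phases[0].shape, phases[0].spacing_mm, phases[0].origin)
        for p in phases[1:]:
            if (p.shape, p.spacing_mm, p.origin) != geom:
                raise ValueError("all phases must share grid geometry")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("acquisition times must be strictly increasing")
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "times_s", times)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def stack(self) -> np.ndarray:
        """Phase-major array of shape (n_phases, nx, ny, nz)."""
        return np.stack([p.values for p in self.phases])

    def peak_phase_index(self, mask: np.ndarray | None = None) -> int:
        """Post-contrast phase with the highest mean signal (in-mask if given)."""
        means = []
        for p in self.phases[1:]:
            v = p.values[mask.astype(bool)] if mask is not None else p.values
            means.append(float(v.mean()))
        return 1 + int(np.argmax(means))


def save_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz inferred from *path*)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI volume; requires an axis-aligned affine."""
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError(f"{path}: only axis-aligned affines are supported")
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    return VolumeImage(
        values=np.asarray(img.get_fdata(), dtype=np.float64),
        spacing_mm=spacing,  # type: ignore[arg-type]
        origin=tuple(float(aff[i, 3]) for i in range(3)),  # type: ignore[arg-type]
    )
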