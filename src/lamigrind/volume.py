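"""CT volume container and grayscale normalization.

A CT volume is the pre-operative density map of the bone: voxel gray values
act as a proxy for local bone strength, and are mapped to the dimensionless
weight ``lambda`` in [0, 1] by a piecewise-linear ramp before entering the
force model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "NormalizationParams", "normalize_gray"]


@dataclass(frozen=True)
class CTVolume:
    """3-D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data
        Gray values (CT units, dimensionless), shape ``(nx, ny, nz)``.
        Axis order matches the workpiece coordinate system (WCS).
    spacing
        Per-axis voxel size in mm.
    origin
        Physical position (mm, WCS) of the corner of voxel (0, 0, 0).

    Voxel centers sit at ``origin + (index + 0.5) * spacing``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")
        if np.any(self.data < 0):
            raise ValueError("gray values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def size_mm(self) -> np.ndarray:
        """Physical extent of the volume along each axis (mm)."""
        return np.asarray(self.data.shape) * self.spacing

    def sample_nearest(self, points: np.ndarray, outside: float = 0.0) -> np.ndarray:
        """Gray value of the voxel containing each physical point.

        ``points`` has shape ``(..., 3)`` in WCS mm. Points outside the
        volume return ``outside`` (air).
        """
        pts = np.asarray(points, dtype=float)
        idx = np.floor((pts - self.origin) / self.spacing).astype(np.int64)
        shape = np.asarray(self.data.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=-1)
        idx_c = np.clip(idx, 0, shape - 1)
        vals = self.data[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]]
        return np.where(inside, vals, outside)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points lying inside the physical volume bounds."""
        pts = np.asarray(points, dtype=float)
        rel = pts - self.origin
        return np.all((rel >= 0) & (rel < self.size_mm), axis=-1)

    # ---- NIfTI round trip -------------------------------------------------

    def to_nifti(self, path: str) -> None:
        """Write the volume to a .nii/.nii.gz file (spacing in the affine)."""
        import nibabel as nib

        affine = np.diag(np.concatenate([self.spacing, [1.0]]))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data, affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "CTVolume":
        """Load a volume from a NIfTI file; spacing comes from the header."""
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.get_fdata(), dtype=float)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(data=data, spacing=spacing, origin=origin)


@dataclass(frozen=True)
class NormalizationParams:
    """Bounds and power coefficient of the gray-to-weight mapping.

    ``mmin``/``mmax`` delimit the linear ramp (CT units); ``mu`` is the
    power coefficient applied downstream when weighting the force model
    (bone strength scales as a power of density).
    """

    mmin: float = 80.0
    mmax: float = 1400.0
    mu: float = 1.815

    def __post_init__(self) -> None:
        if not self.mmax > self.mmin:
            raise ValueError("mmax must exceed mmin")
        if not self.mu > 0:
            raise ValueError("mu must be positive")


def normalize_gray(x, p: NormalizationParams):
    """Map CT gray values to the dimensionless weight lambda in [0, 1].

    Piecewise linear: 0 at or below ``p.mmin``, 1 at or above ``p.mmax``,
    linear in between. Total and continuous; accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    lam = np.clip((x - p.mmin) / (p.mmax - p.mmin), 0.0, 1.0)
    return lam if lam.ndim else float(lam)
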