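"""Synthetic CT phantoms.

Two generators cover the geometries the toolkit is exercised on:

* a stepped-gradient block — gray level constant within equal-width slabs
  along one axis, stepping monotonically across a gray range; used to probe
  the density sensitivity of the force model, and
* a lamina-like block — a dense cortical shell wrapped around a softer
  cancellous core with smooth seeded random texture; a stand-in for a
  segmented vertebral lamina so the whole pipeline runs without external
  CT data.

Both are pure functions of their arguments (plus seed) and return
:class:`~lamigrind.volume.CTVolume`.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import CTVolume

__all__ = ["make_step_phantom", "make_lamina_phantom"]


def _grid_shape(size_mm, voxel_mm) -> np.ndarray:
    size_mm = np.asarray(size_mm, dtype=float)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    if np.any(size_mm <= 0) or np.any(voxel_mm <= 0):
        raise ValueError("sizes and voxel dimensions must be positive")
    shape = size_mm / voxel_mm
    if not np.allclose(shape, np.round(shape), atol=1e-6):
        raise ValueError("size_mm must be divisible by voxel_mm on every axis")
    return np.round(shape).astype(int)


def make_step_phantom(
    size_mm=(12.0, 12.0, 6.0),
    voxel_mm=(0.25, 0.25, 0.25),
    n_levels: int = 10,
    gray_range=(0.0, 1400.0),
    gradient_axis: int = 0,
) -> CTVolume:
    """Block with a stepped gray gradient along one axis.

    The volume is split into ``n_levels`` equal-width slabs along
    ``gradient_axis``; slab ``q`` carries the constant gray
    ``lo + q * (hi - lo) / (n_levels - 1)`` so the levels step monotonically
    across ``gray_range``. The other axes are homogeneous.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    shape = _grid_shape(size_mm, voxel_mm)
    lo, hi = float(gray_range[0]), float(gray_range[1])
    n_vox = shape[gradient_axis]
    # slab index of each voxel along the gradient axis
    slab = np.minimum((np.arange(n_vox) * n_levels) // n_vox, n_levels - 1)
    if n_levels == 1:
        levels = np.full(1, lo)
    else:
        levels = lo + np.arange(n_levels) * (hi - lo) / (n_levels - 1)
    profile = levels[slab]
    data = np.zeros(tuple(shape), dtype=float)
    view = [None, None, None]
    view[gradient_axis] = slice(None)
    data += profile[tuple(view)]
    return CTVolume(data=data, spacing=np.asarray(voxel_mm, dtype=float))


def make_lamina_phantom(
    size_mm=(10.0, 14.0, 11.0),
    voxel_mm=(0.25, 0.25, 0.25),
    cortical_gray: float = 1200.0,
    cancellous_gray: float = 300.0,
    shell_mm: float = 1.2,
    smoothness: float = 2.0,
    texture_gray: float = 150.0,
    bone_margin_mm: float = 1.5,
    attached_margin_mm: float = 0.0,
    soft_gray: float = 40.0,
    seed: int | None = None,
) -> CTVolume:
    """Lamina-like bone slab with cortical shell, cancellous core and texture.

    A lamina is a narrow bone plate with a free lateral edge and a medial
    side that continues into the spinous process, and that asymmetric
    finite extent is what the volume emulates: the bone occupies the
    block inset by ``bone_margin_mm`` on the x sides and the low-y (free
    lateral) side, and by ``attached_margin_mm`` (default 0: bone runs to
    the volume boundary) on the high-y (attached medial) side, embedded
    in soft tissue at ``soft_gray`` (below the usual bone normalization
    window, i.e. force-neutral). The outer ``shell_mm`` of the bone takes
    the cortical gray level, the interior the cancellous level, blended
    smoothly at the interface. A zero-mean Gaussian random field,
    low-pass filtered to a correlation length of ``smoothness`` mm and
    scaled to an RMS amplitude of ``texture_gray`` inside the bone,
    emulates trabecular density variation; the result is clipped to
    [0, 1400]. Deterministic for a fixed seed.

    Parameters
    ----------
    smoothness
        Correlation length of the texture in mm; larger values approach a
        piecewise-constant shell/core volume.
    seed
        Mandatory; the phantom must be reproducible.
    """
    if seed is None:
        raise ValueError("seed is required: phantom generation must be reproducible")
    size_mm = np.asarray(size_mm, dtype=float)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    if not shell_mm < float(np.min(size_mm)) / 2:
        raise ValueError("shell_mm must be smaller than half the smallest extent")
    if not 2 * bone_margin_mm < float(np.min(size_mm[:2])):
        raise ValueError("bone margins must leave room for the bone slab")
    shape = _grid_shape(size_mm, voxel_mm)
    rng = np.random.default_rng(seed)

    # signed distance (mm) from each voxel center to the bone boundary;
    # margins: x both sides and low-y = free edges, high-y = attached
    # side, z = full extent (top surface is where milling starts)
    m = bone_margin_mm
    margins = [(m, m), (m, attached_margin_mm), (0.0, 0.0)]
    axes = []
    for (n, dv, size), (m_lo, m_hi) in zip(zip(shape, voxel_mm, size_mm), margins):
        c = (np.arange(n) + 0.5) * dv
        axes.append(np.minimum(c - m_lo, (size - m_hi) - c))
    d_face = np.minimum.reduce(np.meshgrid(*axes, indexing="ij"))

    blend_w = 2.0 * float(np.mean(voxel_mm))
    # soft tissue -> cortical shell over the bone boundary, then shell ->
    # core at the shell depth; both transitions ~2 voxels wide
    bone_frac = 1.0 / (1.0 + np.exp(-d_face / (blend_w / 4.0)))
    core_frac = 1.0 / (1.0 + np.exp(-(d_face - shell_mm) / (blend_w / 4.0)))
    base = soft_gray + (cortical_gray - soft_gray) * bone_frac \
        + (cancellous_gray - cortical_gray) * core_frac

    sigma_vox = smoothness / voxel_mm  # correlation length in voxel units
    noise = rng.standard_normal(tuple(shape))
    noise = gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    rms = float(np.sqrt(np.mean(noise**2)))
    if rms > 0:
        # RMS equals texture_gray at the 2 mm reference correlation length
        # and falls off as smoothness^{-3/2} (3-D low-pass attenuation), so
        # a very smooth core tends to the constant cancellous level.
        noise *= texture_gray / rms * (2.0 / smoothness) ** 1.5
    data = np.clip(base + bone_frac * noise, 0.0, 1400.0)
    return CTVolume(data=data, spacing=voxel_mm)
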