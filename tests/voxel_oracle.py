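"""Brute-force voxel-occupancy oracle for cutter-workpiece engagement.

Material removal is simulated on a fine boolean voxel grid: every ball
position along an executed pass deletes the voxels whose centers fall
inside the sphere. A point is engaged when the voxel containing it is
still occupied. Entirely independent of the package's analytic
capsule-union engagement test, which it cross-validates.
"""

from __future__ import annotations

import numpy as np


class VoxelOracle:
    def __init__(self, lo, hi, voxel: float = 0.1):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.voxel = float(voxel)
        self.shape = np.ceil((self.hi - self.lo) / voxel - 1e-9).astype(int)
        self.occ = np.ones(tuple(self.shape), dtype=bool)

    def _centers_box(self, lo_idx, hi_idx):
        axes = [self.lo[d] + (np.arange(lo_idx[d], hi_idx[d]) + 0.5) * self.voxel
                for d in range(3)]
        return axes

    def remove_sphere(self, center: np.ndarray, radius: float) -> None:
        """Delete voxels whose centers lie strictly inside the ball."""
        center = np.asarray(center, dtype=float)
        lo_idx = np.clip(np.floor((center - radius - self.lo) / self.voxel).astype(int),
                         0, self.shape)
        hi_idx = np.clip(np.ceil((center + radius - self.lo) / self.voxel).astype(int),
                         0, self.shape)
        if np.any(lo_idx >= hi_idx):
            return
        ax, ay, az = self._centers_box(lo_idx, hi_idx)
        d2 = ((ax - center[0])[:, None, None] ** 2
              + (ay - center[1])[None, :, None] ** 2
              + (az - center[2])[None, None, :] ** 2)
        sub = self.occ[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
        sub &= ~(d2 < radius**2)

    def occupied(self, points: np.ndarray) -> np.ndarray:
        """True where the voxel containing the point still holds material."""
        p = np.asarray(points, dtype=float)
        idx = np.floor((p - self.lo) / self.voxel).astype(int)
        inside = np.all((idx >= 0) & (idx < self.shape), axis=-1)
        idx_c = np.clip(idx, 0, self.shape - 1)
        vals = self.occ[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]]
        return vals & inside
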