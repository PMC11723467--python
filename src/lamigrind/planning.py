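"""Layer-by-layer milling plan and grid decomposition.

The planned workspace is a rectangular box milled in horizontal layers.
Within a layer, straight paths run along the WCS x-axis (the feed
direction), separated by the step distance ``w`` along y; successive
layers descend by the milling depth ``d`` along -z. Each path is divided
into consecutive grids of physical length ``l = vd * ns / fs`` — the
distance the cutter feeds during one force-signal segment — and every
grid (layer i, path j, grid k) later receives one predicted force
sequence and one landmark position.

Coordinate convention (WCS, right-handed): x = feed direction, y = step
direction, z normal to the milling layers pointing out of the bone; the
stock top surface lies at ``z = workspace_origin[2]`` and the tip of the
cutter on layer i runs at ``z = z0 - i * d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import CTVolume

__all__ = ["MillingPlan", "GridIndex", "PathRecord", "build_plan", "extract_grid_grays"]


@dataclass(frozen=True)
class GridIndex:
    """1-based (layer i, path j, grid k) ordinal triple."""

    i: int
    j: int
    k: int

    def __post_init__(self) -> None:
        if min(self.i, self.j, self.k) < 1:
            raise ValueError("grid indices are 1-based")


@dataclass(frozen=True)
class PathRecord:
    """Planned straight path: tip-level start/end points in WCS (mm)."""

    i: int
    j: int
    start: np.ndarray
    end: np.ndarray

    @property
    def direction(self) -> np.ndarray:
        v = self.end - self.start
        return v / np.linalg.norm(v)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class MillingPlan:
    """Geometry and kinematic parameters of a layer-by-layer milling task.

    Parameters
    ----------
    n_layers, n_paths_per_layer
        Plan extent; layer 1 is at the bone surface.
    path_length_mm
        Length of every straight path along x (mm).
    depth_d
        Per-layer milling depth (mm).
    step_w
        Step distance between adjacent paths along y (mm).
    feed_vd
        Nominal feed rate (mm/s).
    spin_N
        Spindle speed (RPM).
    incline_deg
        Incline angle of the tool axis, rotation about the x-axis (deg).
    workspace_origin
        WCS position (mm) of the first path's start at the stock top:
        (x of path starts, y of path 1, z of the original bone surface).
    ns, fs
        Segment length (samples) and force sampling rate (Hz); together
        with ``feed_vd`` they set the grid length ``l``.
    bidirectional
        If True, even-numbered paths run along -x (serpentine order);
        default is unidirectional (+x only).
    """

    n_layers: int = 3
    n_paths_per_layer: int = 4
    path_length_mm: float = 12.0
    depth_d: float = 0.8
    step_w: float = 2.8
    feed_vd: float = 0.5
    spin_N: float = 800.0
    incline_deg: float = 30.0
    workspace_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ns: int = 15
    fs: float = 20.0
    bidirectional: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "workspace_origin", np.asarray(self.workspace_origin, dtype=float)
        )
        if min(self.n_layers, self.n_paths_per_layer) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("path_length_mm", "depth_d", "step_w", "feed_vd", "spin_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ns < 2:
            raise ValueError("ns must be >= 2")

    # ---- derived geometry -------------------------------------------------

    @property
    def segment_length(self) -> float:
        """Physical length l (mm) swept during one ns-sample segment."""
        return self.feed_vd * self.ns / self.fs

    @property
    def grids_per_path(self) -> int:
        """floor(path length / l); the trailing remainder is truncated."""
        return int(np.floor(self.path_length_mm / self.segment_length + 1e-9))

    @property
    def samples_per_path(self) -> int:
        """Force samples recorded while traversing one full path."""
        return int(np.floor(self.path_length_mm / self.feed_vd * self.fs + 1e-9))

    @property
    def n_paths_total(self) -> int:
        return self.n_layers * self.n_paths_per_layer

    def layer_z(self, i: int) -> float:
        """Tip height (mm, WCS z) of layer i: z0 - i*d."""
        return float(self.workspace_origin[2] - i * self.depth_d)

    def path_y(self, j: int) -> float:
        return float(self.workspace_origin[1] + (j - 1) * self.step_w)

    def path_record(self, i: int, j: int) -> PathRecord:
        if not (1 <= i <= self.n_layers and 1 <= j <= self.n_paths_per_layer):
            raise ValueError(f"path ({i},{j}) outside plan bounds")
        x0 = float(self.workspace_origin[0])
        y = self.path_y(j)
        z = self.layer_z(i)
        start = np.array([x0, y, z])
        end = np.array([x0 + self.path_length_mm, y, z])
        if self.bidirectional and j % 2 == 0:
            start, end = end, start
        return PathRecord(i=i, j=j, start=start, end=end)

    def paths(self) -> list[PathRecord]:
        """All paths in execution order: layer-major, path-minor."""
        return [
            self.path_record(i, j)
            for i in range(1, self.n_layers + 1)
            for j in range(1, self.n_paths_per_layer + 1)
        ]

    def check_index(self, idx: GridIndex) -> None:
        if not (
            1 <= idx.i <= self.n_layers
            and 1 <= idx.j <= self.n_paths_per_layer
            and 1 <= idx.k <= self.grids_per_path
        ):
            raise ValueError(f"{idx} outside plan bounds")

    def landmark(self, idx: GridIndex) -> np.ndarray:
        """Tip-level midpoint of a grid's centerline segment (WCS mm)."""
        self.check_index(idx)
        rec = self.path_record(idx.i, idx.j)
        s = (idx.k - 0.5) * self.segment_length
        return rec.start + s * rec.direction

    def grid_span(self, idx: GridIndex) -> tuple[np.ndarray, np.ndarray]:
        """Start/end points of a grid's tip-level centerline segment."""
        self.check_index(idx)
        rec = self.path_record(idx.i, idx.j)
        a = rec.start + (idx.k - 1) * self.segment_length * rec.direction
        b = rec.start + idx.k * self.segment_length * rec.direction
        return a, b


class InvalidPlanError(ValueError):
    """The planned workspace does not fit inside the CT volume."""


def build_plan(
    config: dict,
    volume: CTVolume | None = None,
    cutter_radius: float = 0.0,
) -> MillingPlan:
    """Build a :class:`MillingPlan` from a configuration mapping.

    ``config`` keys mirror the :class:`MillingPlan` fields. When a volume
    is supplied, the workspace (paths plus a cutter-radius margin in x/y
    and the total milling depth in z) must fit inside its physical bounds,
    otherwise :class:`InvalidPlanError` is raised.
    """
    plan = MillingPlan(**config)
    if volume is not None:
        o = plan.workspace_origin
        lo = np.array([o[0] - cutter_radius,
                       plan.path_y(1) - cutter_radius,
                       plan.layer_z(plan.n_layers)])
        hi = np.array([o[0] + plan.path_length_mm + cutter_radius,
                       plan.path_y(plan.n_paths_per_layer) + cutter_radius,
                       o[2]])
        vmin = volume.origin
        vmax = volume.origin + volume.size_mm
        if np.any(lo < vmin - 1e-9) or np.any(hi > vmax + 1e-9):
            raise InvalidPlanError(
                f"workspace [{lo}, {hi}] exceeds volume bounds [{vmin}, {vmax}]"
            )
    return plan


def extract_grid_grays(vol: CTVolume, plan: MillingPlan, idx: GridIndex) -> np.ndarray:
    """Ordered gray values of the voxels crossed by a grid's centerline.

    Nearest-voxel lookup along the tip-level segment of grid ``idx``: one
    value per voxel column crossed, in traversal order. Raises if the
    segment leaves the volume.
    """
    a, b = plan.grid_span(idx)
    if not (vol.contains(a) and vol.contains(b - 1e-9 * (b - a))):
        raise ValueError(f"grid {idx} centerline leaves the volume")
    # the segment is axis-aligned along x; enumerate crossed voxel columns
    sx = float(vol.spacing[0])
    x_lo, x_hi = sorted((a[0], b[0]))
    i_lo = int(np.floor((x_lo - vol.origin[0]) / sx + 1e-9))
    i_hi = int(np.ceil((x_hi - vol.origin[0]) / sx - 1e-9))
    centers_x = vol.origin[0] + (np.arange(i_lo, max(i_hi, i_lo + 1)) + 0.5) * sx
    if a[0] > b[0]:  # traversal order for reversed paths
        centers_x = centers_x[::-1]
    pts = np.stack(
        [centers_x, np.full_like(centers_x, a[1]), np.full_like(centers_x, a[2])],
        axis=-1,
    )
    return vol.sample_nearest(pts)
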