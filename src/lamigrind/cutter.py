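"""Ball-end cutter geometry and rigid-body kinematics.

The cutting edges of an n-flute ball-end cutter wind helically over the
hemisphere of radius R. Each edge is discretized into micro-edges indexed
by the axial position angle theta_m in [0, arccos(h/R)] (h is the offset
of the edge from the tool center at the apex); the circumferential angle
lags the flute start angle by sin(theta_m) * tan(beta_G) where beta_G is
the helix angle. Forces are later integrated over these micro-edges.

Four frames chain the geometry to the workpiece: the cutter-fixed MCCS,
the spin-following i-MCCS (x along feed), the path-local l-WCS (z normal
to the layer, reached by rotating the tool axis about x by the incline
angle), and the workpiece-fixed WCS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CutterSpec",
    "MicroEdge",
    "ToolPose",
    "edge_points",
    "edge_arrays",
    "pose_at",
    "feed_per_tooth",
    "check_phase_condition",
    "spin_rate",
    "incline_matrix",
    "rotz",
]


@dataclass(frozen=True)
class CutterSpec:
    """Geometry of an n-flute ball-end cutter.

    ``tip_offset_h`` is the distance from the cutting edge to the tool
    center in the bottom view: edges do not pass through the apex, so
    theta_m is capped at arccos(h/R). ``axial_step_dtheta`` is the
    discretization step of the axial position angle (rad).
    """

    radius_R: float = 2.0
    n_flutes: int = 4
    helix_beta: float = np.deg2rad(30.0)
    tip_offset_h: float = 0.25
    axial_step_dtheta: float = np.deg2rad(4.0)
    flute_start_angles: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.tip_offset_h < self.radius_R:
            raise ValueError("require 0 < tip_offset_h < radius_R")
        if self.n_flutes < 1:
            raise ValueError("need at least one flute")
        if not 0 < self.axial_step_dtheta < np.pi / 2:
            raise ValueError("axial step must lie in (0, pi/2)")
        if self.flute_start_angles is None:
            angles = 2.0 * np.pi * np.arange(self.n_flutes) / self.n_flutes
        else:
            angles = np.asarray(self.flute_start_angles, dtype=float)
            if angles.shape != (self.n_flutes,):
                raise ValueError("one start angle per flute required")
        object.__setattr__(self, "flute_start_angles", angles)

    @property
    def theta_max(self) -> float:
        """Upper bound of the axial position angle: arccos(h/R)."""
        return float(np.arccos(self.tip_offset_h / self.radius_R))


@dataclass(frozen=True)
class MicroEdge:
    """One micro-edge: flute id, angles and MCCS position (mm)."""

    flute: int
    theta_m: float
    phi_m: float
    position_mccs: np.ndarray


def _edge_position(R: float, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """MCCS position of micro-edges on the ball: z = -R sin(theta)."""
    return np.stack(
        [
            R * np.cos(theta) * np.cos(phi),
            R * np.cos(theta) * np.sin(phi),
            -R * np.sin(theta),
        ],
        axis=-1,
    )


def edge_arrays(spec: CutterSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized micro-edge table: (theta, phi, position) flat arrays.

    theta is sampled on [0, arccos(h/R)] with step dtheta for every flute;
    phi = phi0 - sin(theta) * tan(beta_G) (the helix lag angle).
    """
    n_steps = int(np.floor(spec.theta_max / spec.axial_step_dtheta + 1e-12)) + 1
    theta_1 = spec.axial_step_dtheta * np.arange(n_steps)
    theta = np.tile(theta_1, spec.n_flutes)
    phi0 = np.repeat(spec.flute_start_angles, n_steps)
    phi = phi0 - np.sin(theta) * np.tan(spec.helix_beta)
    pos = _edge_position(spec.radius_R, theta, phi)
    return theta, phi, pos


def edge_points(spec: CutterSpec) -> list[MicroEdge]:
    """Micro-edges of all flutes as a list of :class:`MicroEdge`."""
    theta, phi, pos = edge_arrays(spec)
    n_per = theta.size // spec.n_flutes
    return [
        MicroEdge(flute=t // n_per, theta_m=float(theta[t]), phi_m=float(phi[t]),
                  position_mccs=pos[t])
        for t in range(theta.size)
    ]


def spin_rate(spin_N: float) -> float:
    """Spindle angular rate omega (rad/s) from RPM."""
    return 2.0 * np.pi * spin_N / 60.0


def rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def incline_matrix(delta_m: float) -> np.ndarray:
    """i-MCCS -> l-WCS rotation: tool axis tilted about x by the incline."""
    c, s = np.cos(delta_m), np.sin(delta_m)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


@dataclass(frozen=True)
class ToolPose:
    """Tool pose at time t: homogeneous MCCS -> WCS transform."""

    t: float
    spin_phase: float
    feed_offset: float
    incline_dm: float
    T_t_W: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        return self.T_t_W[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.T_t_W[:3, 3]

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map MCCS points (..., 3) into the WCS."""
        return points @ self.rotation.T + self.translation


def pose_at(
    t: float,
    plan,
    path,
    spec: CutterSpec | None = None,
    phi0: float = 0.0,
    deviation=None,
) -> ToolPose:
    """Tool pose while traversing ``path`` (a PathRecord) at time t.

    t is measured from the start of the path; the ball center travels at
    the nominal feed rate from the path start (tip position plus R z-hat),
    spinning at omega = 2 pi N / 60 with initial phase ``phi0``. The chain
    is: spin about the tool axis, incline about x, then translation along
    the path; an optional rigid ``deviation`` (simulation harness) is
    composed on the WCS side.
    """
    duration = plan.path_length_mm / plan.feed_vd
    if not -1e-9 <= t <= duration + 1e-9:
        raise ValueError(f"t={t} outside the path traversal interval [0, {duration}]")
    radius = spec.radius_R if spec is not None else 0.0
    omega = spin_rate(plan.spin_N)
    phase = omega * t + phi0
    delta = np.deg2rad(plan.incline_deg)
    R_wcs = incline_matrix(delta) @ rotz(phase)
    feed = plan.feed_vd * t
    # ball center = tip + R z-hat; MCCS origin is the ball centroid
    center0 = path.start + np.array([0.0, 0.0, radius])
    trans = center0 + feed * path.direction
    T = np.eye(4)
    T[:3, :3] = R_wcs
    T[:3, 3] = trans
    if deviation is not None:
        T = deviation.matrix() @ T
    return ToolPose(t=t, spin_phase=phase, feed_offset=feed, incline_dm=delta, T_t_W=T)


def feed_per_tooth(vd: float, n: int, N: float) -> float:
    """Feed advance per tooth pass: 60 * vd / (n * N) (mm)."""
    if n * N <= 0:
        raise ZeroDivisionError("n * N must be positive")
    return 60.0 * vd / (n * N)


def check_phase_condition(
    vd: float, n: int, N: float, voxel_mm: float, threshold: float = 0.1
) -> tuple[float, bool]:
    """Ratio of feed-per-tooth to voxel size, and whether it is small.

    When the cutter spins much faster than it feeds (ratio well below 1),
    the random initial spin phase cannot displace the force pattern by a
    meaningful fraction of a voxel, so phase can be ignored in matching.
    The smallness threshold defaults to 0.1 and is configurable.
    """
    ratio = feed_per_tooth(vd, n, N) / voxel_mm
    return ratio, bool(ratio < threshold)
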