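"""Cutter-workpiece engagement (CWE).

Which micro-edges currently touch uncut material decides where cutting
force is generated. Under the layer-by-layer policy the uncut surface
seen by the cutter is the original stock minus the union of the volumes
swept by the ball on every previously completed pass — each swept volume
is exactly a capsule (all points within R of the ball-center segment of
that pass), which reproduces slot floors, spherical end caps and the
scallop ridges left between adjacent paths. The partially completed
current pass contributes the capsule from its start to the present ball
center, so material behind the cutter counts as removed.

Five qualitative engagement cases arise from the position of a path in
the plan (first/other path, top/lower layer); they are exposed as labels
for diagnostics and regression fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stock",
    "MachinedState",
    "CWECase",
    "CWE_CASES",
    "classify_case",
    "point_segment_distance",
    "is_engaged",
    "engaged_edges",
]

CWE_CASES = (
    "first-path-top-layer",
    "other-path-top-layer",
    "first-path-lower-layer",
    "middle-path-lower-layer",
    "last-path-lower-layer",
)

_TOL = 1e-6  # mm; strict-interior margin of the removed region


@dataclass(frozen=True)
class CWECase:
    label: str

    def __post_init__(self) -> None:
        if self.label not in CWE_CASES:
            raise ValueError(f"unknown CWE case {self.label!r}")


def classify_case(i: int, j: int, n_paths: int) -> CWECase:
    """Engagement case of path j on layer i (both 1-based)."""
    if i < 1 or j < 1 or j > n_paths:
        raise ValueError("indices out of range")
    if i == 1:
        return CWECase(CWE_CASES[0] if j == 1 else CWE_CASES[1])
    if j == 1:
        return CWECase(CWE_CASES[2])
    return CWECase(CWE_CASES[4] if j == n_paths else CWE_CASES[3])


@dataclass(frozen=True)
class Stock:
    """Axis-aligned original stock box in WCS (mm)."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float))

    @classmethod
    def from_volume(cls, vol) -> "Stock":
        return cls(lo=vol.origin, hi=vol.origin + vol.size_mm)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return np.all((p >= self.lo - _TOL) & (p <= self.hi + _TOL), axis=-1)


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points (..., 3) to the segment [a, b]."""
    p = np.asarray(points, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(p - a, axis=-1)
    s = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + s[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


@dataclass
class MachinedState:
    """Removal history of a milling run.

    ``history`` is the set of completed (layer, path) pairs; it must be
    downward-closed in execution order (layer-major, path-minor). The
    geometric removal model is the union of ball-swept capsules around the
    recorded center segments (which may be the deviated, executed ones),
    plus the swept-so-far portion of the current path.
    """

    plan: object
    radius: float
    current: tuple[int, int]
    capsules: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    history: set[tuple[int, int]] = field(default_factory=set)

    @classmethod
    def nominal(cls, plan, spec, i: int, j: int) -> "MachinedState":
        """State just before nominal (plan-exact) execution of path (i, j)."""
        state = cls(plan=plan, radius=spec.radius_R, current=(i, j))
        for rec in plan.paths():
            if (rec.i, rec.j) < (i, j):
                state.add_pass(rec.i, rec.j,
                               rec.start + np.array([0.0, 0.0, spec.radius_R]),
                               rec.end + np.array([0.0, 0.0, spec.radius_R]))
        return state

    def add_pass(self, i: int, j: int, center_a: np.ndarray, center_b: np.ndarray) -> None:
        key = (i, j)
        if key in self.history:
            raise ValueError(f"pass {key} recorded twice")
        self.capsules.append((np.asarray(center_a, float), np.asarray(center_b, float)))
        self.history.add(key)

    def capsules_near(self, axis_a: np.ndarray, axis_b: np.ndarray,
                      reach: float) -> list[tuple[np.ndarray, np.ndarray]]:
        """Capsules whose axis comes within ``reach`` of the given segment.

        Conservative cull for querying points on a cutter sweeping the
        segment [axis_a, axis_b]: capsules farther than the reach from
        both endpoints and the midpoint of the query axis (paths here are
        near-parallel straight segments) cannot contain such points.
        """
        probes = np.stack([axis_a, 0.5 * (axis_a + axis_b), axis_b])
        keep = []
        for a, b in self.capsules:
            if point_segment_distance(probes, a, b).min() < reach:
                keep.append((a, b))
        return keep

    def removed(self, points: np.ndarray, current_sweep=None,
                capsules=None) -> np.ndarray:
        """True where a point lies strictly inside already-removed material.

        ``capsules`` optionally restricts the test to a pre-culled subset
        (see :meth:`capsules_near`); the result is identical when the cull
        is conservative.
        """
        p = np.asarray(points, dtype=float)
        out = np.zeros(p.shape[:-1], dtype=bool)
        for a, b in (self.capsules if capsules is None else capsules):
            out |= point_segment_distance(p, a, b) < self.radius - _TOL
        if current_sweep is not None:
            a, b = current_sweep
            out |= point_segment_distance(p, np.asarray(a, float), np.asarray(b, float)) \
                < self.radius - _TOL
        return out


def is_engaged(
    p_wcs: np.ndarray,
    state: MachinedState,
    stock: Stock,
    current_sweep=None,
) -> np.ndarray:
    """Whether points on the cutter sphere touch uncut stock material.

    True iff the point is inside the original stock and outside every
    swept capsule (completed passes plus the current partial sweep).
    Scalar or batched input.
    """
    p = np.asarray(p_wcs, dtype=float)
    mask = stock.contains(p) & ~state.removed(p, current_sweep=current_sweep)
    return mask if mask.ndim else bool(mask)


def engaged_edges(pose, edges, state: MachinedState, stock: Stock,
                  current_sweep=None, feed_dir_wcs=(1.0, 0.0, 0.0)):
    """Subset of micro-edges engaged at ``pose``.

    Engagement needs (a) the edge's WCS position inside uncut material and
    (b) positive undeformed chip thickness — the outward edge normal must
    have a positive component along the feed direction, i.e. the rake
    face is advancing into material. Returns the engaged list.
    """
    fd = np.asarray(feed_dir_wcs, dtype=float)
    fd = fd / np.linalg.norm(fd)
    out = []
    for e in edges:
        p_w = pose.transform(e.position_mccs)
        normal = (p_w - pose.translation) / state.radius
        if float(normal @ fd) <= 0:
            continue
        if is_engaged(p_w, state, stock, current_sweep=current_sweep):
            out.append(e)
    return out
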