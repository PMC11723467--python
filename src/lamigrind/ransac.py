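"""Robust refinement of the per-segment tip estimates.

Two hypothesize-and-verify stages:

1. fit a 3-D line to the matched landmark points of each milled path
   (2-point hypotheses, perpendicular-distance inliers, least-squares
   refit over the best consensus set), and
2. estimate the rigid workspace offsets (Delta_nr along y — the step
   direction — and Delta_nl along z — the depth direction) by comparing
   the fitted lines' y/z positions against the planned ones: each
   hypothesis averages the offsets of a random subset of paths and is
   scored by how many paths agree within a threshold.

Milling-depth estimate = planned layer depth + Delta_nl. Along-path (x)
deviation is unobservable from line geometry and is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FittedLine",
    "DeviationEstimate",
    "point_line_residual",
    "fit_path_line",
    "estimate_deviation",
    "estimate_deviation_censored",
]


@dataclass
class FittedLine:
    """3-D line (point + unit direction) with inlier bookkeeping."""

    point: np.ndarray
    direction: np.ndarray
    inlier_count: int
    inlier_indices: np.ndarray
    mean_residual: float

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("line direction must be nonzero")
        self.direction = d / n

    def yz_at_x(self, x: float) -> tuple[float, float]:
        """Intersection of the line with the plane of constant x.

        Falls back to the anchor point's y/z when the line is (nearly)
        perpendicular to x.
        """
        if abs(self.direction[0]) < 1e-9:
            return float(self.point[1]), float(self.point[2])
        s = (x - self.point[0]) / self.direction[0]
        p = self.point + s * self.direction
        return float(p[1]), float(p[2])


def point_line_residual(Pi, P0, v0) -> np.ndarray:
    """Perpendicular distance from point(s) Pi to the line (P0, v0).

    ``v0`` must be a unit vector; implemented as |(Pi - P0) x v0|, which
    is invariant to sliding P0 along the line.
    """
    Pi = np.asarray(Pi, dtype=float)
    P0 = np.asarray(P0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    d = np.linalg.norm(np.cross(Pi - P0, v0), axis=-1)
    return d if np.ndim(d) else float(d)


def _ls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: centroid + first PC."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[0]


def fit_path_line(
    points: np.ndarray,
    n1: int = 2,
    k1: int = 2000,
    t1: float = 1.0,
    seed: int | None = 0,
    refit: bool = True,
    axis: np.ndarray | None = None,
    max_axis_angle: float = 0.3,
) -> FittedLine:
    """RANSAC 3-D line fit to the matched points of one milled path.

    ``k1`` random 2-point hypotheses; a point is an inlier when its
    perpendicular distance is below ``t1`` mm. The best hypothesis (most
    inliers; ties by smaller mean inlier residual) is refit to its inlier
    set by total least squares. Deterministic for a fixed seed.

    When ``axis`` is given (the known feed direction of the path),
    hypotheses whose direction deviates from it by more than
    ``max_axis_angle`` rad are rejected: the executed path is a rigidly
    displaced copy of the planned one, so its direction stays within the
    small-angle deviation regime, while matched landmarks sit on a
    regular grid full of spurious collinear subsets along other axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (N, 3)")
    n = pts.shape[0]
    uniq = np.unique(pts, axis=0)
    if n < n1 or uniq.shape[0] < 2:
        raise ValueError("need at least two distinct points to fit a line")
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, n, size=k1)
    jj = rng.integers(0, n, size=k1)
    a, b = pts[ii], pts[jj]
    d = b - a
    lens = np.linalg.norm(d, axis=1)
    ok = lens > 1e-12          # coincident sample pairs are skipped
    if axis is not None and ok.any():
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        with np.errstate(invalid="ignore"):
            cosang = np.abs((d @ u) / np.where(lens > 0, lens, 1.0))
        ok &= cosang > np.cos(max_axis_angle)
    if not ok.any():
        # degenerate draw (e.g. many duplicate points): fall back to LS
        c, v = _ls_line(uniq)
        if axis is not None:
            v = np.asarray(axis, dtype=float) / np.linalg.norm(axis)
            c = uniq.mean(axis=0)
        res = point_line_residual(pts, c, v)
        inl = np.flatnonzero(res < t1)
        return FittedLine(c, v, len(inl), inl, float(res[inl].mean()) if len(inl) else np.inf)
    a, d = a[ok], d[ok] / lens[ok, None]
    # residuals of all points against all hypotheses: (K, N)
    diff = pts[None, :, :] - a[:, None, :]
    cr = np.cross(diff, d[:, None, :])
    res = np.linalg.norm(cr, axis=-1)
    inlier = res < t1
    counts = inlier.sum(axis=1)
    mean_res = np.where(counts > 0,
                        (res * inlier).sum(axis=1) / np.maximum(counts, 1),
                        np.inf)
    # most inliers; ties broken by smaller mean inlier residual
    order = np.lexsort((mean_res, -counts))
    best = order[0]
    inl = np.flatnonzero(inlier[best])
    def _constrain(c, v):
        # the refit must honor the axis constraint as well: a stack of
        # same-x landmarks would otherwise yield a transverse direction
        # whose yz_at_x extrapolation is meaningless
        if axis is None:
            return c, v
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        if abs(float(v @ u)) < np.cos(max_axis_angle):
            return c, u
        return c, v

    if refit and len(inl) >= 2 and np.unique(pts[inl], axis=0).shape[0] >= 2:
        c, v = _constrain(*_ls_line(pts[inl]))
        # trimmed second pass: chance outliers sitting just inside the
        # inlier band (large lever arm) would tilt a plain LS refit
        res = point_line_residual(pts, c, v)
        core = res < t1
        if core.sum() >= 2:
            gate = max(3.0 * float(np.median(res[core])), 1e-9)
            tight = res <= gate
            if tight.sum() >= 2 and np.unique(pts[tight], axis=0).shape[0] >= 2:
                c, v = _constrain(*_ls_line(pts[tight]))
    else:
        c, v = a[best], d[best]
    final_res = point_line_residual(pts, c, v)
    inl = np.flatnonzero(final_res < t1)
    mean_final = float(final_res[inl].mean()) if len(inl) else np.inf
    return FittedLine(c, v, len(inl), inl, mean_final)


@dataclass
class DeviationEstimate:
    """Workspace offsets along y (step) and z (depth) with inliers."""

    dnr: float                    # y-offset (mm)
    dnl: float                    # z-offset (mm)
    inlier_paths: np.ndarray      # indices into the supplied path list
    residuals: np.ndarray         # per-path planar residual (mm)
    depth_estimate: float | None = None  # planned layer depth + dnl

    def to_dict(self) -> dict:
        return {
            "dnr_mm": self.dnr,
            "dnl_mm": self.dnl,
            "inliers": [int(i) for i in self.inlier_paths],
            "per_path_residuals": [float(r) for r in self.residuals],
            "depth_estimate_mm": self.depth_estimate,
        }


def estimate_deviation(
    lines: list[FittedLine],
    planned_yz: np.ndarray,
    read_x: np.ndarray | float,
    n2: int = 30,
    k2: int = 2000,
    t2: float = 1.0,
    seed: int | None = 0,
    depth_d: float | None = None,
) -> DeviationEstimate:
    """RANSAC estimate of the workspace offsets (Delta_nr, Delta_nl).

    Parameters
    ----------
    lines
        Fitted line of every milled path, in plan execution order.
    planned_yz
        (P, 2) planned y/z of each path, read at the same x station.
    read_x
        x station(s) where each line's y/z are evaluated (the planned
        path midpoint by default convention).
    n2
        Minimum number of paths sampled per hypothesis (BestNum).

    Each of ``k2`` iterations samples ``n2`` paths without replacement,
    averages their (observed - planned) y and z offsets, and counts as
    inliers the paths whose residual sqrt((Ry - ry - dnr)^2 +
    (Lz - lz - dnl)^2) falls below ``t2``. The best model (most inliers)
    is re-estimated over its inlier set.
    """
    P = len(lines)
    if P < n2:
        raise ValueError(
            f"insufficient data: {P} fitted paths but BestNum n2 = {n2}")
    planned_yz = np.asarray(planned_yz, dtype=float)
    xs = np.broadcast_to(np.asarray(read_x, dtype=float), (P,))
    obs = np.array([line.yz_at_x(float(x)) for line, x in zip(lines, xs)])
    delta = obs - planned_yz          # (P, 2) per-path offsets
    rng = np.random.default_rng(seed)
    best_count = -1
    best_model = delta.mean(axis=0)
    for _ in range(k2):
        pick = rng.choice(P, size=n2, replace=False)
        model = delta[pick].mean(axis=0)
        res = np.linalg.norm(delta - model, axis=1)
        count = int((res < t2).sum())
        if count > best_count:
            best_count = count
            best_model = model
    res = np.linalg.norm(delta - best_model, axis=1)
    inl = np.flatnonzero(res < t2)
    final = delta[inl].mean(axis=0) if len(inl) else best_model
    res_final = np.linalg.norm(delta - final, axis=1)
    inl = np.flatnonzero(res_final < t2)
    return DeviationEstimate(
        dnr=float(final[0]),
        dnl=float(final[1]),
        inlier_paths=inl,
        residuals=res_final,
        depth_estimate=None if depth_d is None else float(depth_d + final[1]),
    )


def estimate_deviation_censored(
    lines: list[FittedLine],
    planned_yz: np.ndarray,
    read_x: np.ndarray | float,
    pitch_yz: tuple[float, float],
    n2: int = 30,
    t2: float = 1.0,
    seed: int | None = 0,
    depth_d: float | None = None,
) -> DeviationEstimate:
    """Workspace-offset estimate that accounts for plan-boundary censoring.

    The per-path offset observations are quantized to the planned
    lattice (path pitch along y, layer depth along z) and clamp at the
    plan boundary — a path whose true shifted position leaves the
    planned workspace cannot express its offset. Each candidate model
    ``m`` therefore predicts, for every path, the lattice point nearest
    to (planned + m) clipped into the planned range; a path is an
    inlier when its observed position lies within ``t2`` of that
    prediction, and all models share the same denominator (every path
    is scored). Candidates are each path's own observed offset plus the
    global mean, refined twice by the mean observed offset of the
    non-clamped inliers; the most inliers win (ties: smaller mean
    residual). Requires at least ``n2`` non-clamped paths, otherwise
    falls back to :func:`estimate_deviation`.
    """
    P = len(lines)
    if P < n2:
        raise ValueError(
            f"insufficient data: {P} fitted paths but BestNum n2 = {n2}")
    planned_yz = np.asarray(planned_yz, dtype=float)
    xs = np.broadcast_to(np.asarray(read_x, dtype=float), (P,))
    obs = np.array([line.yz_at_x(float(x)) for line, x in zip(lines, xs)])
    delta = obs - planned_yz
    wy, wz = pitch_yz
    y_lo, y_hi = planned_yz[:, 0].min(), planned_yz[:, 0].max()
    z_lo, z_hi = planned_yz[:, 1].min(), planned_yz[:, 1].max()

    def predict(m):
        """Expected observation per path: lattice-quantized, clamped."""
        sy = np.clip(planned_yz[:, 0] + m[0], y_lo, y_hi)
        sz = np.clip(planned_yz[:, 1] + m[1], z_lo, z_hi)
        py = y_lo + wy * np.round((sy - y_lo) / wy)
        pz = z_lo + wz * np.round((sz - z_lo) / wz)
        return np.stack([py, pz], axis=1)

    def unclamped(m):
        sy = planned_yz[:, 0] + m[0]
        sz = planned_yz[:, 1] + m[1]
        return ((sy >= y_lo - wy / 2) & (sy <= y_hi + wy / 2)
                & (sz >= z_lo - wz / 2) & (sz <= z_hi + wz / 2))

    null_pred_y = predict(np.zeros(2))[:, 0]

    cands = [np.zeros(2)] + list(delta) + [delta.mean(axis=0)]
    scored = []
    for m0 in cands:
        m = np.asarray(m0, dtype=float)
        for _ in range(2):
            res = np.linalg.norm(obs - predict(m), axis=1)
            inl = res < t2
            core = inl & unclamped(m)
            if core.sum() < 1:
                break
            m = delta[core].mean(axis=0)
        res = np.linalg.norm(obs - predict(m), axis=1)
        inl = res < t2
        core = inl & unclamped(m)
        if core.sum() < 1:
            continue
        pred = predict(m)
        y_shifted = bool(np.any(np.abs(pred[:, 0] - null_pred_y) > 1e-9))
        scored.append({"m": m, "inl": inl, "res": res, "pred": pred,
                       "y_shifted": y_shifted})
    if not scored:
        return estimate_deviation(lines, planned_yz, read_x, n2=n2, k2=2000,
                                  t2=t2, seed=seed, depth_d=depth_d)

    def rank(s):
        return (int(s["inl"].sum()), -float(s["res"][s["inl"]].mean()))

    # Reference = best model that does not shift the step-direction
    # lattice (its depth offset is still refined freely). A path that is
    # clamped or lattice-coincident agrees with every model predicting
    # the same value, so it cannot decide between models: a y-shifting
    # model is accepted only when, on the paths where its prediction
    # differs from the reference's, it explains at least two MORE paths
    # than the reference does.
    unshifted = [s for s in scored if not s["y_shifted"]]
    ref = max(unshifted, key=rank) if unshifted else None
    accepted = []
    for s in scored:
        if not s["y_shifted"]:
            continue
        if ref is not None:
            d_rows = np.linalg.norm(s["pred"] - ref["pred"], axis=1) > 1e-9
            disc = int(s["inl"][d_rows].sum()) - int(ref["inl"][d_rows].sum())
            if disc < 1:
                continue
        accepted.append(s)
    if accepted:
        best = max(accepted, key=rank)
    elif ref is not None:
        best = ref
    else:
        best = max(scored, key=rank)
    m, inl, res = best["m"], best["inl"], best["res"]
    if int(np.sum(unclamped(m))) < n2:
        return estimate_deviation(lines, planned_yz, read_x, n2=n2, k2=2000,
                                  t2=t2, seed=seed, depth_d=depth_d)
    return DeviationEstimate(
        dnr=float(m[0]),
        dnl=float(m[1]),
        inlier_paths=np.flatnonzero(inl),
        residuals=res,
        depth_estimate=None if depth_d is None else float(depth_d + m[1]),
    )
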