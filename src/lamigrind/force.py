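"""Grayscale-weighted mechanistic milling-force model.

Per micro-edge, the classic shear + edge (ploughing) decomposition gives
radial/axial/tangential force increments

    dF. = lambda^mu * (K.c * tn * db + K.e * ds)

where tn is the undeformed chip thickness (projection of the feed per
tooth on the outward sphere normal), db = R*dtheta the chip width, ds the
micro-edge arc length, and lambda the normalized CT gray value sampled at
the micro-edge position — the bone-strength weight that personalizes the
model to the imaged bone. Increments are rotated into the spin-following
tool frame (i-MCCS) and summed over the engaged edges into the four
channels (Fx, Fy, Fz, Mz); Mz is the moment of the tangential increments
about the tool axis with arm R*cos(theta).

Note on coefficient units: shear coefficients are N/mm^2 (force per chip
cross-section tn*db), edge coefficients N/mm (force per edge length ds).
The default values follow the published calibration table for bone
grinding; that table prints two "Kte" rows and no "Krc", which this
package resolves as Krc = -1203.1 N/mm^2 (shear), Kre = -75 and
Kte = -199.1 N/mm (edge) — the shear >> edge magnitude convention. All
six are configurable.

:func:`predict_bank` compiles the model into the prediction bank: one
fixed-length four-channel sequence plus one landmark position per grid of
the milling plan, simulated along the nominal (deviation-free) plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cutter import CutterSpec, edge_arrays, feed_per_tooth, incline_matrix, spin_rate
from .cwe import MachinedState, Stock
from .planning import GridIndex, MillingPlan
from .volume import CTVolume, NormalizationParams, normalize_gray

__all__ = [
    "ForceCoefficients",
    "Wrench",
    "PathTrace",
    "PredictionBank",
    "chip_geometry",
    "micro_force",
    "rotate_micro_force",
    "instantaneous_wrench",
    "trace_path_forces",
    "predict_bank",
]

_ZHAT = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class ForceCoefficients:
    """Shear (N/mm^2) and edge (N/mm) coefficients plus the density power."""

    Krc: float = -1203.1
    Kac: float = -105.2
    Ktc: float = 2142.1
    Kre: float = -75.0
    Kae: float = 22.4
    Kte: float = -199.1
    mu: float = 1.815

    def __post_init__(self) -> None:
        vals = [self.Krc, self.Kac, self.Ktc, self.Kre, self.Kae, self.Kte, self.mu]
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


@dataclass(frozen=True)
class Wrench:
    """Four-channel force/torque sample in the i-MCCS (N, N*mm)."""

    Fx: float
    Fy: float
    Fz: float
    Mz: float
    frame: str = "i-MCCS"

    def as_array(self) -> np.ndarray:
        return np.array([self.Fx, self.Fy, self.Fz, self.Mz])


def chip_geometry(theta_m, dtheta: float, spec: CutterSpec, vt_vector, pose=None):
    """Micro-edge chip geometry (db, ds, tn) in mm.

    db = R*dtheta; ds = R*sqrt(1 + cos^4(theta)*tan^2(beta))*dtheta;
    tn = positive part of the feed-per-tooth vector projected on the
    outward sphere normal n_t (|n_t| = R). ``vt_vector`` and the edge
    normal are both taken in the spin-following frame: the normal is
    (cos th cos ph, cos th sin ph, -sin th) with ph the instantaneous
    circumferential angle; pass the normal via pose=(phi_inst) — here the
    caller supplies ``vt_vector`` already resolved against the normal, or
    a 3-vector with the instantaneous angle in ``pose``.
    """
    theta_m = np.asarray(theta_m, dtype=float)
    R = spec.radius_R
    db = R * dtheta
    ds = R * np.sqrt(1.0 + np.cos(theta_m) ** 4 * np.tan(spec.helix_beta) ** 2) * dtheta
    vt = np.asarray(vt_vector, dtype=float)
    if pose is not None:  # instantaneous circumferential angle supplied
        phi = np.asarray(pose, dtype=float)
        normal = np.stack(
            [np.cos(theta_m) * np.cos(phi), np.cos(theta_m) * np.sin(phi),
             -np.sin(theta_m)], axis=-1)
        tn = np.maximum(0.0, (vt * normal).sum(axis=-1))
    else:
        nt = np.stack([np.cos(theta_m), np.zeros_like(theta_m),
                       -np.sin(theta_m)], axis=-1)
        tn = np.maximum(0.0, (vt * nt).sum(axis=-1))
    return db, ds, tn


def micro_force(tn, db, ds, lam, c: ForceCoefficients):
    """Radial/axial/tangential force increments, weighted by lambda^mu."""
    lam = np.asarray(lam, dtype=float)
    w = lam**c.mu
    dFr = w * (c.Krc * tn * db + c.Kre * ds)
    dFa = w * (c.Kac * tn * db + c.Kae * ds)
    dFt = w * (c.Ktc * tn * db + c.Kte * ds)
    return dFr, dFa, dFt


def rotation_rat_to_xyz(theta_m, phi_m) -> np.ndarray:
    """3x3 matrix mapping (dFr, dFa, dFt) to Cartesian components."""
    ct, st = np.cos(theta_m), np.sin(theta_m)
    cp, sp = np.cos(phi_m), np.sin(phi_m)
    return np.array([
        [-ct * cp, -st * cp, sp],
        [-ct * sp, -st * sp, -cp],
        [-st, ct, 0.0],
    ])


def rotate_micro_force(dFr, dFa, dFt, theta_m, phi_m):
    """Resolve (dFr, dFa, dFt) onto the tool-frame Cartesian axes.

    The matrix is orthonormal for any angle pair, so force magnitude is
    preserved. Broadcasts over arrays of angles/forces.
    """
    ct, st = np.cos(theta_m), np.sin(theta_m)
    cp, sp = np.cos(phi_m), np.sin(phi_m)
    dFx = -ct * cp * dFr - st * cp * dFa + sp * dFt
    dFy = -ct * sp * dFr - st * sp * dFa - cp * dFt
    dFz = -st * dFr + ct * dFa
    return dFx, dFy, dFz


def instantaneous_wrench(
    pose,
    edges_engaged,
    vol: CTVolume,
    norm: NormalizationParams,
    c: ForceCoefficients,
    spec: CutterSpec,
    vt_mag: float,
    feed_dir_wcs=(1.0, 0.0, 0.0),
) -> Wrench:
    """Sum weighted micro-forces of the engaged edges into an i-MCCS wrench.

    Each engaged micro-edge is weighted by lambda from the voxel nearest
    its WCS position (outside the volume counts as air, lambda = 0). The
    instantaneous circumferential angle (flute angle plus spin phase)
    resolves the increments in the non-spinning tool frame.
    """
    if not edges_engaged:
        return Wrench(0.0, 0.0, 0.0, 0.0)
    fd = np.asarray(feed_dir_wcs, dtype=float)
    fd /= np.linalg.norm(fd)
    R = spec.radius_R
    F = np.zeros(3)
    Mz = 0.0
    for e in edges_engaged:
        p_w = pose.transform(e.position_mccs)
        lam = normalize_gray(vol.sample_nearest(p_w), norm)
        phi_inst = e.phi_m + pose.spin_phase
        normal_w = (p_w - pose.translation) / R
        tn = max(0.0, vt_mag * float(normal_w @ fd))
        db, ds, _ = chip_geometry(e.theta_m, spec.axial_step_dtheta, spec, (0, 0, 0))
        dFr, dFa, dFt = micro_force(tn, db, ds, lam, c)
        dFx, dFy, dFz = rotate_micro_force(dFr, dFa, dFt, e.theta_m, phi_inst)
        F += (dFx, dFy, dFz)
        Mz += R * np.cos(e.theta_m) * dFt
    return Wrench(float(F[0]), float(F[1]), float(F[2]), float(Mz))


# ---------------------------------------------------------------------------
# fast vectorized per-path trace (shared by the bank and the simulator)
# ---------------------------------------------------------------------------


@dataclass
class PathTrace:
    """Force/ground-truth trace of one path traversal."""

    i: int
    j: int
    t: np.ndarray          # (T,) seconds from path start
    forces: np.ndarray     # (T, 4): Fx, Fy, Fz, Mz in the i-MCCS
    gray_mean: np.ndarray  # (T,) mean raw gray over engaged edges
    tip: np.ndarray        # (T, 3) executed tip position, WCS mm
    center_a: np.ndarray   # executed ball-center segment of the full pass
    center_b: np.ndarray


DEFAULT_SUBSTEPS = 10


def trace_path_forces(
    vol: CTVolume,
    plan: MillingPlan,
    spec: CutterSpec,
    coeffs: ForceCoefficients,
    norm: NormalizationParams,
    rec,
    state: MachinedState,
    stock: Stock,
    phi_rand: float = 0.0,
    deviation=None,
    feed_profile=None,
    n_substeps: int = DEFAULT_SUBSTEPS,
) -> PathTrace:
    """Simulate the four-channel force trace of one path traversal.

    ``rec`` is the nominal path record; ``state`` holds the capsules of
    previously executed passes (already in executed coordinates when a
    deviation applies). ``deviation`` is an optional rigid transform
    object with a ``matrix()`` method (applied about the workspace
    origin). ``feed_profile`` maps path-local times to (along-path
    displacement mm, instantaneous feed rate mm/s); None means nominal
    uniform feed.

    Sensor model: a 20 Hz force/torque channel does not capture the
    53 Hz tooth-passing ripple instantaneously — it integrates. Each
    reported sample is therefore the boxcar average of the wrench over
    its 1/fs interval, evaluated at ``n_substeps`` equally spaced
    sub-instants (this attenuates the spin-phase-dependent ripple by
    roughly an order of magnitude while keeping the density envelope).
    """
    T = plan.samples_per_path
    q = (np.arange(n_substeps) + 0.5) / n_substeps
    t_sub = ((np.arange(T)[:, None] + q[None, :]) / plan.fs).ravel()  # (T*S,)
    if feed_profile is None:
        feed_offsets = plan.feed_vd * t_sub
        feed_rates = np.full(t_sub.size, plan.feed_vd)
    else:
        feed_offsets, feed_rates = feed_profile(t_sub)

    theta, phi, _ = edge_arrays(spec)       # (E,)
    R = spec.radius_R
    dtheta = spec.axial_step_dtheta
    omega = spin_rate(plan.spin_N)
    tanb = np.tan(spec.helix_beta)

    alpha = omega * t_sub + phi_rand          # (T*S,)
    phi_inst = phi[None, :] + alpha[:, None]  # (T*S, E)
    ct, st = np.cos(theta), np.sin(theta)     # (E,)
    cp, sp = np.cos(phi_inst), np.sin(phi_inst)

    # spin-following (i-MCCS) edge positions
    p_i = np.stack([R * ct * cp, R * ct * sp,
                    np.broadcast_to(-R * st, cp.shape)], axis=-1)  # (T*S, E, 3)
    Tl = incline_matrix(np.deg2rad(plan.incline_deg))
    p_l = p_i @ Tl.T

    center0 = rec.start + R * _ZHAT
    centers = center0[None, :] + feed_offsets[:, None] * rec.direction[None, :]
    p_nom = centers[:, None, :] + p_l

    if deviation is not None:
        M = deviation.matrix()
        Rd, td = M[:3, :3], M[:3, 3]
        p_w = p_nom @ Rd.T + td
        centers_w = centers @ Rd.T + td
        axis_a = center0 @ Rd.T + td
        axis_u = Rd @ rec.direction
    else:
        p_w = p_nom
        centers_w = centers
        axis_a = center0
        axis_u = rec.direction

    # engagement: inside stock, outside every swept capsule, chip > 0
    engaged = stock.contains(p_w)
    near = state.capsules_near(axis_a, axis_a + float(feed_offsets[-1]) * axis_u,
                               reach=2.0 * R + 0.5)
    engaged &= ~state.removed(p_w, capsules=near)
    # current pass swept so far: segment [axis_a, axis_a + s_k * u]
    rel = p_w - axis_a
    proj = rel @ axis_u
    proj_c = np.clip(proj, 0.0, feed_offsets[:, None])
    d_axis = np.linalg.norm(rel - proj_c[..., None] * axis_u, axis=-1)
    engaged &= ~(d_axis < R - 1e-6)
    # undeformed chip thickness: feed-per-tooth projected on the normal
    vt_mag = feed_per_tooth(1.0, spec.n_flutes, plan.spin_N) * feed_rates  # (T*S,)
    tn = vt_mag[:, None] * ct[None, :] * cp   # normal . feed direction (x)
    engaged &= tn > 0
    tn = np.where(engaged, tn, 0.0)

    gray = vol.sample_nearest(p_w, outside=0.0)
    lam = normalize_gray(gray, norm)
    w = np.where(engaged, lam**coeffs.mu, 0.0)

    db = R * dtheta
    ds = R * np.sqrt(1.0 + ct**4 * tanb**2) * dtheta  # (E,)
    dFr = w * (coeffs.Krc * tn * db + coeffs.Kre * ds)
    dFa = w * (coeffs.Kac * tn * db + coeffs.Kae * ds)
    dFt = w * (coeffs.Ktc * tn * db + coeffs.Kte * ds)

    Fx = (-ct * cp * dFr - st * cp * dFa + sp * dFt).sum(axis=1)
    Fy = (-ct * sp * dFr - st * sp * dFa - cp * dFt).sum(axis=1)
    Fz = (-st * dFr + ct * dFa).sum(axis=1)
    Mz = (R * ct * dFt).sum(axis=1)

    n_eng = engaged.sum(axis=1)
    gmean_sub = np.where(n_eng > 0,
                         (gray * engaged).sum(axis=1) / np.maximum(n_eng, 1), 0.0)

    # boxcar-average substeps into the reported samples
    F_sub = np.stack([Fx, Fy, Fz, Mz], axis=-1)
    forces = F_sub.reshape(T, n_substeps, 4).mean(axis=1)
    gmean = gmean_sub.reshape(T, n_substeps).mean(axis=1)
    tips = (centers_w - R * _ZHAT).reshape(T, n_substeps, 3).mean(axis=1)

    return PathTrace(
        i=rec.i, j=rec.j, t=np.arange(T) / plan.fs,
        forces=forces, gray_mean=gmean, tip=tips,
        center_a=axis_a, center_b=axis_a + float(feed_offsets[-1]) * axis_u,
    )


# ---------------------------------------------------------------------------
# prediction bank
# ---------------------------------------------------------------------------


@dataclass
class PredictionBank:
    """Predicted per-grid force sequences and landmark positions.

    ``sequences`` has shape (Nl, Ntraj, Ngrids, ns, 4) and ``landmarks``
    (Nl, Ntraj, Ngrids, 3); every grid's landmark is the tip-level
    midpoint of its centerline on the planned path.
    """

    plan: MillingPlan
    sequences: np.ndarray
    landmarks: np.ndarray
    fs: float
    phase_seed: int | None = None

    @property
    def ns(self) -> int:
        return self.sequences.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sequences.shape[:3]

    def entry(self, idx: GridIndex) -> tuple[np.ndarray, np.ndarray]:
        self.plan.check_index(idx)
        return (self.sequences[idx.i - 1, idx.j - 1, idx.k - 1],
                self.landmarks[idx.i - 1, idx.j - 1, idx.k - 1])

    def flat_sequences(self) -> np.ndarray:
        """(B, ns, 4) view; B enumerates (i, j, k) in C order."""
        nl, np_, ng = self.shape
        return self.sequences.reshape(nl * np_ * ng, self.ns, 4)

    def flat_index(self, b: int) -> GridIndex:
        nl, np_, ng = self.shape
        i, rem = divmod(b, np_ * ng)
        j, k = divmod(rem, ng)
        return GridIndex(i + 1, j + 1, k + 1)

    # -- serialization: bank.json (landmarks) + one CSV per path ----------

    def save(self, directory: str | Path) -> None:
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nl, np_, ng = self.shape
        index = {}
        for i in range(1, nl + 1):
            for j in range(1, np_ + 1):
                seqs = self.sequences[i - 1, j - 1].reshape(ng * self.ns, 4)
                tcol = np.arange(seqs.shape[0]) / self.fs
                df = pd.DataFrame(
                    {"t": tcol, "Fx": seqs[:, 0], "Fy": seqs[:, 1],
                     "Fz": seqs[:, 2], "Mz": seqs[:, 3]})
                df.to_csv(directory / f"path_{i:02d}_{j:02d}.csv", index=False)
                for k in range(1, ng + 1):
                    index[f"{i},{j},{k}"] = list(self.landmarks[i - 1, j - 1, k - 1])
        meta = {
            "shape": list(self.shape), "ns": self.ns, "fs": self.fs,
            "landmarks": index,
        }
        (directory / "bank.json").write_text(json.dumps(meta, indent=1))


def predict_bank(
    vol: CTVolume,
    plan: MillingPlan,
    spec: CutterSpec,
    coeffs: ForceCoefficients,
    norm: NormalizationParams,
    ns: int | None = None,
    fs: float | None = None,
    phase_seed: int = 0,
) -> PredictionBank:
    """Simulate the nominal plan and compile the per-grid prediction bank.

    The initial spin phase of each path is drawn uniformly from [0, 2pi)
    with ``phase_seed`` (the phase a surgeon cannot control is random per
    pass, but the bank must be reproducible). Wrench samples at ``fs`` are
    sliced into consecutive length-``ns`` grid sequences; the trailing
    remainder of each path is dropped.
    """
    ns = plan.ns if ns is None else ns
    fs = plan.fs if fs is None else fs
    if ns != plan.ns or fs != plan.fs:
        raise ValueError("ns/fs must match the plan's segmentation parameters")
    ng = plan.grids_per_path
    if ng < 1:
        raise ValueError("plan/segmentation mismatch: path shorter than one grid")
    rng = np.random.default_rng(phase_seed)
    stock = Stock.from_volume(vol)
    nl, np_ = plan.n_layers, plan.n_paths_per_layer
    seqs = np.zeros((nl, np_, ng, ns, 4))
    lands = np.zeros((nl, np_, ng, 3))
    state = MachinedState(plan=plan, radius=spec.radius_R, current=(1, 1))
    for rec in plan.paths():
        state.current = (rec.i, rec.j)
        phi_rand = float(rng.uniform(0.0, 2.0 * np.pi))
        trace = trace_path_forces(vol, plan, spec, coeffs, norm, rec, state,
                                  stock, phi_rand=phi_rand)
        used = ng * ns
        seqs[rec.i - 1, rec.j - 1] = trace.forces[:used].reshape(ng, ns, 4)
        for k in range(1, ng + 1):
            lands[rec.i - 1, rec.j - 1, k - 1] = plan.landmark(
                GridIndex(rec.i, rec.j, k))
        state.add_pass(rec.i, rec.j, trace.center_a, trace.center_b)
    return PredictionBank(plan=plan, sequences=seqs, landmarks=lands, fs=fs,
                          phase_seed=phase_seed)
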