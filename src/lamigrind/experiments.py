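"""End-to-end estimation pipeline and standard simulation protocols.

This module wires the pieces together — phantom, plan, prediction bank,
simulated run, segment matching, RANSAC refinement, scoring — into the
study protocols the package is validated on:

* closed-loop exactness on the stepped-gradient phantom (no
  disturbances: the estimator must return the true grid),
* a feed-disturbance sweep on a lamina-like phantom (random pose
  deviation + sinusoidal feed-rate disturbance at five amplitudes), and
* the narrow-plan protocol (2 paths x 11 layers, eleven fixed reference
  deviations, deviation-fit BestNum of 8).

Problem sizes are desk scale: 6 mm paths and a 10-layer x 4-path plan
for the sweep, chosen so a full protocol runs in minutes on one CPU
while keeping several hundred grids in the bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cutter import CutterSpec
from .estimate import ForceSignal, TipEstimate, estimate_segments, tumble_segment
from .force import ForceCoefficients, PredictionBank, predict_bank
from .phantom import make_lamina_phantom, make_step_phantom
from .planning import MillingPlan
from .ransac import (
    DeviationEstimate,
    FittedLine,
    estimate_deviation_censored,
    fit_path_line,
)
from .simulate import (
    NARROW_PLAN_DEVIATIONS,
    ErrorReport,
    FeedDisturbance,
    PoseDeviation,
    draw_random_deviation,
    evaluate,
    simulate_run,
)
from .volume import NormalizationParams

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "stepped_protocol",
    "lamina_protocol",
    "narrow_protocol",
    "closed_loop_exactness",
    "feed_sweep",
    "summarize_sweep",
    "narrow_plan_protocol",
    "bestnum_sweep",
    "run_experiment_suite",
    "FEED_AMPLITUDES",
]

FEED_AMPLITUDES = (0.05, 0.10, 0.15, 0.20, 0.30)
DEFAULT_NOISE_SIGMA = 0.05  # N per force channel (10x for the torque channel)


def default_cutter() -> CutterSpec:
    return CutterSpec()


def default_coefficients() -> ForceCoefficients:
    return ForceCoefficients()


def default_normalization() -> NormalizationParams:
    return NormalizationParams()


# ---------------------------------------------------------------------------
# full pipeline on one simulated run
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one run and one method."""

    method: str
    estimates: list[TipEstimate]
    lines: list[FittedLine]
    deviation: DeviationEstimate
    report: ErrorReport


def _fit_lines_per_path(estimates, truth, plan, seed, window=None) -> list[FittedLine]:
    """RANSAC line per executed path from its segments' matched landmarks."""
    ns = plan.ns
    lines = []
    rng = np.random.default_rng(seed)
    for rec in plan.paths():
        pts = []
        for est in estimates:
            mid = int((est.segment - 1) * ns + ns // 2)
            if (int(truth.path_i[mid]), int(truth.path_j[mid])) != (rec.i, rec.j):
                continue
            pts.append(est.position)
        pts = np.asarray(pts)
        sub_seed = int(rng.integers(2**31))
        try:
            line = fit_path_line(pts, seed=sub_seed, axis=rec.direction)
        except ValueError:
            # all matches collapsed onto one landmark: the path direction
            # is known from the plan, keep it and anchor at the match
            line = FittedLine(point=pts.mean(axis=0) if len(pts) else rec.midpoint,
                              direction=rec.direction,
                              inlier_count=len(pts),
                              inlier_indices=np.arange(len(pts)),
                              mean_residual=0.0)
        lines.append(line)
    return lines


# search window used by the closed-loop protocols: the execution schedule
# is known intra-operatively and the pose-deviation model (|angles| < 0.1
# rad over a ~10 mm workspace, translations ~N(0, 0.9 mm)) bounds the
# plausible offset to ~3 layers and ~1 path pitch at 3 sigma
PROTOCOL_WINDOW = (4, 1)


def run_pipeline(
    bank: PredictionBank,
    signal: ForceSignal,
    truth,
    method: str = "dtw",
    n2: int = 30,
    seed: int = 0,
    window: tuple | None = None,
) -> PipelineResult:
    """Match segments, fit per-path lines, estimate the workspace offsets.

    ``n2`` is the deviation-fit BestNum (minimum paths per hypothesis).
    ``window`` optionally restricts matching to (layers, paths) around
    each segment's scheduled indices (see
    :func:`lamigrind.estimate.estimate_segments`); the default is the
    global scan over all grids.
    """
    plan = bank.plan
    segments = tumble_segment(signal, plan.ns, vd=plan.feed_vd)
    scheduled = None
    if window is not None:
        ns = plan.ns
        scheduled = []
        for seg in segments:
            mid = int((seg.m - 1) * ns + ns // 2)
            scheduled.append((int(truth.path_i[mid]), int(truth.path_j[mid])))
    estimates = estimate_segments(segments, bank, method=method,
                                  scheduled=scheduled, window=window)
    lines = _fit_lines_per_path(estimates, truth, plan, seed=seed,
                                window=window)
    recs = plan.paths()
    planned_yz = np.array([[r.start[1], r.start[2]] for r in recs])
    read_x = np.array([r.midpoint[0] for r in recs])
    # only consensus-supported lines qualify as path observations: a
    # path whose matched landmarks do not even form a coherent line
    # (fewer than half its segments as fit inliers) is milling material
    # the bank does not predict (off the bone edge or outside the plan)
    # and carries no usable offset observation
    min_support = max(2, plan.grids_per_path // 2)
    good = np.array([ln.inlier_count >= min_support for ln in lines])
    if good.sum() >= n2:
        kept_lines = [ln for ln, g in zip(lines, good) if g]
        kept_yz = planned_yz[good]
        kept_x = read_x[good]
    else:
        kept_lines, kept_yz, kept_x = lines, planned_yz, read_x
    dev_est = estimate_deviation_censored(
        kept_lines, kept_yz, kept_x, pitch_yz=(plan.step_w, plan.depth_d),
        n2=n2, seed=seed, depth_d=plan.depth_d)
    report = evaluate(estimates, truth, dev_est, method=method)
    return PipelineResult(method=method, estimates=estimates, lines=lines,
                          deviation=dev_est, report=report)


# ---------------------------------------------------------------------------
# standard protocols
# ---------------------------------------------------------------------------


def stepped_protocol(gradient_axis: int = 0):
    """Stepped-gradient phantom with the reference milling parameters.

    12 x 12 x 6 mm block at 0.25 mm voxels, 10 gray levels over [0, 1400];
    3 layers x 4 paths of 12 mm at 0.8 mm depth / 2.8 mm step, feed
    0.5 mm/s, 800 RPM, 30 deg incline, 20 Hz sampling.
    """
    vol = make_step_phantom(gradient_axis=gradient_axis)
    plan = MillingPlan(
        n_layers=3, n_paths_per_layer=4, path_length_mm=12.0,
        workspace_origin=np.array([0.0, 1.8, 6.0]), incline_deg=30.0)
    return vol, plan, default_cutter(), default_coefficients(), default_normalization()


def lamina_protocol(seed: int, n_layers: int = 10, n_paths: int = 4,
                    path_length: float = 6.0, incline_deg: float = 2.0):
    """Lamina-like phantom and plan for the feed-disturbance sweep.

    The volume extends one deviation range (~3 mm) beyond the workspace
    on every side so a deviated run still samples scanned material; the
    first path rides 1.5 mm from the free lateral bone edge.
    """
    vol = make_lamina_phantom(size_mm=(10.0, 17.0, 11.0), seed=seed)
    plan = MillingPlan(
        n_layers=n_layers, n_paths_per_layer=n_paths,
        path_length_mm=path_length, incline_deg=incline_deg,
        workspace_origin=np.array([2.0, 3.0, 11.0]))
    return vol, plan, default_cutter(), default_coefficients(), default_normalization()


def narrow_protocol(seed: int, incline_deg: float):
    """Narrow lamina phantom: 2 paths per layer x 11 layers.

    Sized so the reference deviation conditions (lateral offsets up to
    one path pitch) keep the executed workspace inside the volume.
    """
    vol = make_lamina_phantom(size_mm=(10.0, 12.0, 12.0), seed=seed)
    plan = MillingPlan(
        n_layers=11, n_paths_per_layer=2, path_length_mm=6.0,
        incline_deg=incline_deg,
        workspace_origin=np.array([2.0, 2.6, 12.0]))
    return vol, plan, default_cutter(), default_coefficients(), default_normalization()


def closed_loop_exactness(seed: int = 0, gradient_axis: int = 0) -> dict:
    """No-disturbance closed loop on the stepped phantom.

    The simulated signal reproduces the bank's own sequences (same spin
    phases, no deviation/noise/feed disturbance), so the DTW estimator
    should return the true grid for essentially every segment; the only
    admissible failures are ties between grids with identical predicted
    sequences inside constant-gray slabs.
    """
    vol, plan, spec, coeffs, norm = stepped_protocol(gradient_axis=gradient_axis)
    phase_seed = seed
    bank = predict_bank(vol, plan, spec, coeffs, norm, phase_seed=phase_seed)
    signal, truth = simulate_run(vol, plan, spec, coeffs, norm,
                                 noise_sigma=0.0, seed=seed,
                                 phase_seed=phase_seed)
    segments = tumble_segment(signal, plan.ns, vd=plan.feed_vd)
    estimates = estimate_segments(segments, bank, method="dtw")
    n_true = 0
    for est in estimates:
        mid = int((est.segment - 1) * plan.ns + plan.ns // 2)
        truth_idx = (int(truth.path_i[mid]), int(truth.path_j[mid]),
                     int(truth.grid_k[mid]))
        if truth_idx == (est.index.i, est.index.j, est.index.k):
            n_true += 1
    return {
        "n_segments": len(estimates),
        "n_true_grid": n_true,
        "accuracy": n_true / len(estimates),
    }


def feed_sweep(
    seed: int = 0,
    amplitudes=FEED_AMPLITUDES,
    seeds_per_amplitude: int = 5,
    methods=("dtw", "pearson"),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    n2: int = 30,
) -> list[dict]:
    """Feed-disturbance sweep: random deviations, sine feed, both methods.

    One lamina phantom and one prediction bank serve the whole sweep; for
    every amplitude, ``seeds_per_amplitude`` runs draw a fresh random pose
    deviation, spin phases and sine phase. Returns one record per
    (amplitude, run, method) with the scored errors.
    """
    master = np.random.default_rng(seed)
    phantom_seed = int(master.integers(2**31))
    bank_phase_seed = int(master.integers(2**31))
    vol, plan, spec, coeffs, norm = lamina_protocol(phantom_seed)
    bank = predict_bank(vol, plan, spec, coeffs, norm, phase_seed=bank_phase_seed)
    results = []
    for amp in amplitudes:
        for r in range(seeds_per_amplitude):
            run_seed = int(master.integers(2**31))
            rng = np.random.default_rng(run_seed)
            dev = draw_random_deviation(rng, origin=plan.workspace_origin)
            feed = FeedDisturbance(amplitude=amp, frequency=1.0,
                                   phase=float(rng.uniform(0, 2 * np.pi)))
            signal, truth = simulate_run(
                vol, plan, spec, coeffs, norm, deviation=dev, feed=feed,
                noise_sigma=noise_sigma, seed=run_seed)
            for method in methods:
                res = run_pipeline(bank, signal, truth, method=method,
                                   n2=n2, seed=run_seed,
                                   window=PROTOCOL_WINDOW)
                rec = {"amplitude": amp, "run": r, "method": method,
                       **res.report.summary()}
                rec["channel_error_mean"] = res.report.channel_error_mean
                results.append(rec)
    return results


def summarize_sweep(results: list[dict]) -> dict:
    """Aggregate sweep records into the per-amplitude and overall errors.

    The scored error of one run is the mean of its two deviation-channel
    errors (distance deviation along y, milling depth along z). Returns
    the worst-amplitude means for the pooled pipeline and for the DTW
    branch alone, plus suite-wide per-method means.
    """
    amplitudes = sorted({r["amplitude"] for r in results})
    per_amp_all, per_amp_dtw = {}, {}
    for amp in amplitudes:
        errs_all = [r["channel_error_mean"] for r in results if r["amplitude"] == amp]
        errs_dtw = [r["channel_error_mean"] for r in results
                    if r["amplitude"] == amp and r["method"] == "dtw"]
        per_amp_all[amp] = float(np.mean(errs_all))
        per_amp_dtw[amp] = float(np.mean(errs_dtw))
    method_means = {}
    for method in sorted({r["method"] for r in results}):
        method_means[method] = float(np.mean(
            [r["channel_error_mean"] for r in results if r["method"] == method]))
    return {
        "per_amplitude_overall": per_amp_all,
        "per_amplitude_dtw": per_amp_dtw,
        "worst_amplitude_overall": float(max(per_amp_all.values())),
        "worst_amplitude_dtw": float(max(per_amp_dtw.values())),
        "method_means": method_means,
    }


def narrow_plan_protocol(
    seed: int = 0,
    conditions=NARROW_PLAN_DEVIATIONS,
    n2: int = 8,
    method: str = "dtw",
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seeds_per_condition: int = 3,
) -> list[dict]:
    """Narrow-plan protocol: 2 paths x 11 layers, fixed deviations.

    Each of the reference conditions fixes the pose deviation and the
    incline angle; the deviation-fit BestNum is 8. Per condition,
    ``seeds_per_condition`` replicate runs redraw the nuisance
    randomness (spin phases, sensor noise, consensus sampling) and the
    reported per-condition errors are means over the replicates.
    """
    master = np.random.default_rng(seed)
    phantom_seed = int(master.integers(2**31))
    out = []
    for c_idx, cond in enumerate(conditions):
        rx, ry, rz, tx, ty, tz, incline = cond
        vol, plan, spec, coeffs, norm = narrow_protocol(phantom_seed, incline)
        bank = predict_bank(vol, plan, spec, coeffs, norm,
                            phase_seed=int(master.integers(2**31)))
        dev = PoseDeviation(rotation=(rx, ry, rz), translation=(tx, ty, tz),
                            origin=plan.workspace_origin)
        dnr_e, dnl_e, acc = [], [], []
        for _ in range(seeds_per_condition):
            run_seed = int(master.integers(2**31))
            signal, truth = simulate_run(vol, plan, spec, coeffs, norm,
                                         deviation=dev,
                                         noise_sigma=noise_sigma,
                                         seed=run_seed)
            res = run_pipeline(bank, signal, truth, method=method, n2=n2,
                               seed=run_seed, window=PROTOCOL_WINDOW)
            dnr_e.append(res.report.dnr_error)
            dnl_e.append(res.report.dnl_error)
            acc.append(res.report.grid_accuracy)
        out.append({
            "condition": c_idx + 1,
            "incline_deg": incline,
            "distance_deviation_error_mm": float(np.mean(dnr_e)),
            "depth_error_mm": float(np.mean(dnl_e)),
            "channel_error_mean": float(0.5 * (np.mean(dnr_e) + np.mean(dnl_e))),
            "grid_accuracy": float(np.mean(acc)),
        })
    return out


def bestnum_sweep(seed: int = 0, n2_values=(20, 25, 30, 32),
                  amplitude: float = 0.10) -> list[dict]:
    """Error of the deviation fit as the BestNum parameter varies."""
    master = np.random.default_rng(seed)
    phantom_seed = int(master.integers(2**31))
    bank_phase = int(master.integers(2**31))
    run_seed = int(master.integers(2**31))
    vol, plan, spec, coeffs, norm = lamina_protocol(phantom_seed)
    bank = predict_bank(vol, plan, spec, coeffs, norm, phase_seed=bank_phase)
    rng = np.random.default_rng(run_seed)
    dev = draw_random_deviation(rng, origin=plan.workspace_origin)
    feed = FeedDisturbance(amplitude=amplitude,
                           phase=float(rng.uniform(0, 2 * np.pi)))
    signal, truth = simulate_run(vol, plan, spec, coeffs, norm, deviation=dev,
                                 feed=feed, noise_sigma=DEFAULT_NOISE_SIGMA,
                                 seed=run_seed)
    out = []
    for n2 in n2_values:
        res = run_pipeline(bank, signal, truth, method="dtw", n2=n2,
                           seed=run_seed, window=PROTOCOL_WINDOW)
        out.append({"n2": n2,
                    "distance_deviation_error_mm": res.report.dnr_error,
                    "depth_error_mm": res.report.dnl_error})
    return out


def run_experiment_suite(config: dict, seeds) -> dict:
    """Run the cross-product of configured conditions and seeds.

    ``config`` maps condition names to protocol descriptions, e.g.
    ``{"kind": "feed_sweep", "amplitudes": [...]}`` or
    ``{"kind": "narrow_plan"}``. Failures of individual conditions are
    recorded and the suite continues. An empty seed list yields an empty
    report.
    """
    report: dict = {"conditions": [], "errors": []}
    seeds = list(seeds)
    if not seeds:
        return report
    kind = config.get("kind", "feed_sweep")
    for s in seeds:
        try:
            if kind == "feed_sweep":
                amps = config.get("amplitudes", FEED_AMPLITUDES)
                res = feed_sweep(seed=s, amplitudes=amps,
                                 seeds_per_amplitude=config.get("seeds_per_amplitude", 1))
                for amp in amps:
                    report["conditions"].append(
                        {"seed": s, "amplitude": amp,
                         "records": [r for r in res if r["amplitude"] == amp]})
            elif kind == "narrow_plan":
                res = narrow_plan_protocol(seed=s, n2=config.get("n2", 8))
                report["conditions"].append({"seed": s, "records": res})
            elif kind == "bestnum_sweep":
                res = bestnum_sweep(seed=s, n2_values=tuple(
                    config.get("n2_values", (20, 25, 30, 32))))
                report["conditions"].append({"seed": s, "records": res})
            else:
                raise ValueError(f"unknown condition kind {kind!r}")
        except Exception as exc:  # noqa: BLE001 - suite must continue
            report["errors"].append({"seed": s, "error": repr(exc)})
    return report
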