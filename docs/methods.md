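# Methods

This note records the models implemented in `lamigrind`, their
assumptions, the synthetic data they are validated on, and the design
choices made where the design was genuinely open.

## Coordinate conventions

The workpiece coordinate system (WCS) is right-handed with x along the
feed direction, y along the step direction, and z normal to the milling
layers pointing out of the bone; the original bone surface lies at
`z = z0` and the cutter tip on layer i runs at `z = z0 − i·d`. Voxels
are indexed 0-based with the voxel-center convention
`position = origin + (index + 0.5)·spacing`; gray lookup is
nearest-voxel (no interpolation), and positions outside the volume read
as air (gray 0). Four frames chain the cutter to the workpiece: the
cutter-fixed MCCS, the spin-following i-MCCS (x along feed, z along the
rod axis), the path-local frame reached by rotating the tool axis about
x by the incline angle δ_m, and the WCS.

## Cutter and force model

Cutting edges wind helically over the ball of radius R; a micro-edge at
axial position angle θ (0 at the equator, capped at `arccos(h/R)`
because edges end a distance h from the center in the bottom view) sits
at circumferential angle `φ0 − sinθ·tanβ_G`. Per engaged micro-edge the
shear/edge (Lee–Altintas) decomposition gives radial/axial/tangential
increments

    dF• = λ^μ · (K•c · tn · db  +  K•e · ds),      • ∈ {r, a, t}

with chip width `db = R·dθ`, edge arc length
`ds = R·sqrt(1 + cos⁴θ·tan²β_G)·dθ` (which reduces to `R·dθ` at
β_G = 0, as an arc length must), and undeformed chip thickness `tn` =
positive part of the feed-per-tooth vector (`60·v_d/(n·N)` along x)
projected on the outward sphere normal. λ is the piecewise-linear
normalization of the CT gray at the micro-edge position (0 below
`m_min = 80`, 1 above `m_max = 1400`), raised to `μ = 1.815`; it
multiplies both the shear and the edge term as printed in the source
calibration. Increments are resolved onto Cartesian axes with the
orthonormal matrix in (θ, φ_inst), φ_inst being the flute angle plus
the spin phase, so the summed wrench lives in the non-spinning i-MCCS.
The torque channel is defined as `Mz = Σ R·cosθ·dFt` (moment of the
tangential increments about the tool axis); the source material plots
this channel without printing a formula.

Coefficient units and values: shear in N/mm², edge in N/mm —
dimensional consistency of the model forces this split even though the
published table prints N/mm² for all six. The published table also
lists "Kte" twice and omits Krc; we assign Krc = −1203.1 (shear),
Kre = −75, Kte = −199.1 (edge), Kac = −105.2, Ktc = 2142.1, Kae = 22.4.
All six are configurable, and the absolute force scale is irrelevant to
the estimator (prediction and measurement share it).

## Engagement (CWE)

A micro-edge is engaged when its position lies inside the original
stock, outside every previously swept volume, and its chip thickness is
positive (rake face advancing). Because the tool tip is a ball, the
swept volume of a pass is exactly the capsule of radius R around the
ball-center segment, so the machined state is the union of capsules of
all completed passes plus the swept-so-far part of the current pass.
This reproduces slot floors, spherical end caps and the scallop ridges
left between adjacent paths, and cleanly generates the five qualitative
engagement cases of the layer-by-layer policy (first/other path on
top/lower layers). The analytic test is validated against an
independent brute-force voxel-removal oracle (0.1 mm occupancy grid,
spheres deleted along the executed passes) with ≥ 99% agreement
required over a 2-layer × 2-path run.

## Sensor model

At the reference parameters (800 RPM, 4 flutes, 20 Hz sampling) the
tooth-passing frequency is 53.3 Hz: an instantaneous 20 Hz sample of
the wrench is a stroboscopic snapshot whose ripple (comparable to the
mean force) depends on the uncontrollable initial spin phase of each
pass — with the spin phase advancing exactly 2/3 of a revolution per
sample, the aliased pattern repeats every 3 samples. A real low-rate
force/torque channel integrates instead, so each reported sample is the
boxcar average of the wrench over its 1/f_s interval (10 equally spaced
sub-instants). This attenuates the phase-dependent ripple by roughly an
order of magnitude while preserving the density envelope; the small
residual acts as a per-pass signature that breaks ties between
otherwise identical predictions. The matcher additionally conditions
both the segments and the bank sequences with a centered 3-sample
moving average, which cancels the residual 3-sample stroboscopic
pattern; matching therefore does not rely on knowing the executed spin
phases.

## Estimation pipeline

The signal is segmented by a tumbling window of `n_s = 15` samples
(grid length `l = v_d·n_s/f_s = 0.375` mm at the reference
parameters). Similarity of a segment to a bank grid is the equal-weight
sum over the four channels of the DTW distance (absolute-difference
local metric, accumulated first row/column), computed on the raw
(amplitude-preserving) conditioned channels; amplitudes carry the
density and engagement signature, which is what localizes the tip. A
Pearson-correlation baseline replaces the DTW distance for comparison.
Ties resolve to the smallest (layer, path, grid) lexicographically. By
default the whole bank is scanned; the closed-loop protocols instead
use the optional scheduled-index search window (±4 layers, ±1 path,
all grids) because the execution schedule is known intra-operatively
and the pose-deviation model bounds the plausible index offset (3σ of
the translations ≈ 2.7 mm ≈ 3.4 layers ≈ 1 path pitch).

Per milled path, a 3-D line is fitted to the matched landmarks by
RANSAC (2-point hypotheses, k1 = 2000, inlier band t1 = 1.0 mm, best
consensus refit by total least squares with a trimmed second pass at
3× the median inlier residual). Hypothesis directions are constrained
to within 0.3 rad of the known feed axis: the executed path is a
rigidly displaced copy of the planned one (small-angle regime), while
the landmark grid is full of spurious collinear subsets along the other
axes. The line's y/z are read at the planned path midpoint's x.

The workspace offsets (Δn_r, Δn_l) come from the per-path
(observed − planned) y/z offsets by a consensus that models how the
observations are actually generated. Only consensus-supported lines
qualify as observations: a path whose Algorithm-1 inlier count falls
below half its segments produced an incoherent match cloud — it milled
material the bank never predicted (off the bone edge or outside the
plan) — and is excluded when enough paths remain. The observations are
quantized to the planned lattice (path pitch along y, layer depth
along z) and clamp at the plan boundary, so each candidate offset
(every path's own observed offset plus the global mean, refined twice
by non-clamped inlier means, inlier threshold t2 = 1.0 mm) predicts
per path the clamped lattice point nearest to (planned + offset). A
clamped or lattice-coincident path agrees with every model that
predicts the same value, so it cannot decide between models: a
candidate that shifts the y-lattice is accepted only when it explains
at least two more paths than the best y-unshifted reference on exactly
the paths where their predictions differ; otherwise the parsimonious
reference (whose depth offset is still refined freely) wins. A plain
sampled-mean RANSAC (n2 = BestNum, k2 = 2000, per-path residual
threshold) implements the textbook algorithm and is the fallback
whenever the extended model runs out of usable paths. The
milling-depth estimate is the planned layer depth plus Δn_l;
along-path (x) offsets are unobservable from line geometry and out of
scope.

## Synthetic phantoms — what they emulate and what they do not

**Stepped block** (12×12×6 mm, 0.25 mm voxels): ten equal-width gray
slabs stepping 0 → 1400 along a chosen axis; probes the density
sensitivity of the force model (thrust grows monotonically along
gradient-aligned paths, stays flat across them) and gives the
no-disturbance closed loop an exactly reproducible target.

**Lamina slab** (seeded): a bone plate embedded in force-neutral soft
tissue (gray 40), with a 1.2 mm cortical shell (gray 1200) around a
cancellous core (gray 300) and a Gaussian random texture of 2 mm
correlation length and 150 gray RMS (trabecular density variation; the
RMS is referenced to the 2 mm correlation length and falls off as
smoothness^(−3/2)). Two anatomical features matter to the estimator
and are deliberately modeled: the **free lateral edge** (bone inset
1.5 mm from the volume on the x sides and the low-y side) and the
**attached medial side** (bone runs to the volume boundary at high y,
emulating the continuation into the spinous process). Edge paths
partially engaging the free boundary are the step-direction
localization signal; the asymmetry is what makes the sign of a lateral
offset observable. The phantoms do not emulate anisotropic trabecular
orientation, osteoporotic degradation, metal artifacts, partial-volume
blur, or patient-specific lamina curvature — passing tests show the
estimator works when the imaged density is a faithful strength proxy
with lamina-like structure, not that it survives arbitrary real scans.

## Simulation protocols (desk scale)

All closed-loop runs use the reference milling parameters (feed
0.5 mm/s, 800 RPM, depth 0.8 mm, step 2.8 mm, 20 Hz, n_s = 15) and
σ = 0.05 N sensor noise per force channel (0.5 N·mm on Mz).

* **Closed-loop exactness**: stepped phantom, 3 layers × 4 paths of
  12 mm, no disturbances, simulated with the bank's own spin phases;
  the DTW estimator must return the true grid for ≥ 95% of the 384
  segments.
* **Feed-disturbance sweep**: lamina phantom (10×17×11 mm), 10 layers
  × 4 paths of 6 mm (640-grid bank); per amplitude in
  {0.05, 0.10, 0.15, 0.20, 0.30} mm/s, seeded runs draw a random pose
  deviation (rotations N(0, 0.02 rad), translations N(0, 0.9 mm)
  truncated at 3σ — magnitudes representative of navigated-spine
  registration error), a random sine phase (1 Hz), and random cutter
  phases. The scored error of a run is the mean of the two
  deviation-channel errors |Δn̂_r − Δn_r| and |Δn̂_l − Δn_l|; the
  sweep reports per-amplitude means for the pooled pipeline and the
  DTW branch.
* **Narrow-plan protocol**: narrow lamina phantom (10×12×12 mm), 2
  paths × 11 layers, BestNum 8, the eleven fixed reference deviation
  conditions (rotations up to 0.069 rad, translations up to one path
  pitch) each replicated 3 times over nuisance randomness.

Problem sizes (6 mm paths, 5–10 seeds per amplitude, 3 replicates per
narrow condition) were chosen so each full protocol completes in
minutes on a single CPU while keeping several hundred grids in the
bank.

## Numerical choices and degenerate inputs

DTW uses float64 and an exact O(n²) dynamic program (numba-accelerated
all-pairs kernel, numpy fallback, verified identical). Constant
sequences under Pearson score 0 (logged). Segment remainders shorter
than n_s are dropped; a signal shorter than one window yields an empty
segmentation with a warning. Line fits require two distinct points;
fully collapsed match sets fall back to the known path direction
anchored at the matched landmark. Capsule membership uses a strict
interior test with a 10⁻⁶ mm margin so points on the current sphere
surface count as uncut. Phantom generators are pure functions of their
arguments and seed; every stochastic stage (phases, deviations, noise,
RANSAC sampling) derives from explicit integer seeds.

## Known limitations

* The estimator's lateral resolution is bounded by the path pitch and
  its depth resolution by the layer depth; sub-pitch offsets are
  recovered only through the consensus over many paths and remain the
  dominant error term.
* A workspace offset near one full path pitch in a 2-path plan leaves
  half the paths censored at the plan boundary; the censoring-aware
  consensus handles the printed conditions but a plan this narrow is
  near the identifiability limit.
* Cutter runout, tool wear, structural deflection, thermal effects and
  chip evacuation are not modeled; bi-directional (serpentine) milling
  is supported in planning but the validated protocols are
  unidirectional.
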