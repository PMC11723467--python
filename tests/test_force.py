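import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamigrind import (
    ForceCoefficients,
    GridIndex,
    MillingPlan,
    chip_geometry,
    instantaneous_wrench,
    micro_force,
    predict_bank,
    rotate_micro_force,
)
from lamigrind.cutter import edge_points, pose_at
from lamigrind.cwe import MachinedState, Stock, engaged_edges
from lamigrind.force import rotation_rat_to_xyz, trace_path_forces


class TestChipGeometry:
    def test_chip_width_reference(self, spec):
        db, _, _ = chip_geometry(0.5, spec.axial_step_dtheta, spec, (0, 0, 0))
        assert db == pytest.approx(2.0 * np.deg2rad(4.0))  # 0.1396 mm

    def test_edge_length_reduces_at_equatorial_angle(self, spec):
        # at theta = pi/2 the helix term vanishes: ds = R * dtheta
        _, ds, _ = chip_geometry(np.pi / 2, spec.axial_step_dtheta, spec, (0, 0, 0))
        assert ds == pytest.approx(2.0 * np.deg2rad(4.0))

    def test_edge_length_reduces_without_helix(self):
        from lamigrind import CutterSpec

        straight = CutterSpec(helix_beta=0.0)
        _, ds, _ = chip_geometry(0.3, straight.axial_step_dtheta, straight, (0, 0, 0))
        assert ds == pytest.approx(straight.radius_R * straight.axial_step_dtheta)

    def test_chip_thickness_zero_when_normal_orthogonal_to_feed(self, spec):
        # edge normal at phi = 90 deg is orthogonal to the +x feed
        _, _, tn = chip_geometry(0.0, spec.axial_step_dtheta, spec,
                                 (0.009, 0.0, 0.0), pose=np.pi / 2)
        assert tn == pytest.approx(0.0, abs=1e-12)

    def test_chip_thickness_clamped_nonnegative(self, spec):
        _, _, tn = chip_geometry(0.0, spec.axial_step_dtheta, spec,
                                 (0.009, 0.0, 0.0), pose=np.pi)
        assert tn == 0.0


class TestMicroForce:
    def test_air_limit(self, coeffs):
        assert micro_force(0.01, 0.1, 0.1, 0.0, coeffs) == (0.0, 0.0, 0.0)

    def test_full_density_recovers_unweighted_model(self, coeffs):
        tn, db, ds = 0.009, 0.14, 0.16
        dFr, dFa, dFt = micro_force(tn, db, ds, 1.0, coeffs)
        assert dFr == pytest.approx(coeffs.Krc * tn * db + coeffs.Kre * ds)
        assert dFa == pytest.approx(coeffs.Kac * tn * db + coeffs.Kae * ds)
        assert dFt == pytest.approx(coeffs.Ktc * tn * db + coeffs.Kte * ds)

    def test_power_law_weighting(self, coeffs):
        f1 = np.array(micro_force(0.009, 0.14, 0.16, 1.0, coeffs))
        fh = np.array(micro_force(0.009, 0.14, 0.16, 0.5, coeffs))
        assert np.allclose(fh, f1 * 0.5**1.815)
        assert 0.5**1.815 == pytest.approx(0.2842, abs=2e-4)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_density(self, lam1, lam2):
        c = ForceCoefficients()
        lo, hi = sorted((lam1, lam2))
        f_lo = np.array(micro_force(0.009, 0.14, 0.16, lo, c))
        f_hi = np.array(micro_force(0.009, 0.14, 0.16, hi, c))
        assert np.all(np.abs(f_hi) >= np.abs(f_lo) - 1e-12)


class TestRotation:
    @given(st.floats(-np.pi, np.pi), st.floats(-2 * np.pi, 2 * np.pi))
    @settings(max_examples=50, deadline=None)
    def test_matrix_orthonormal(self, theta, phi):
        M = rotation_rat_to_xyz(theta, phi)
        assert np.max(np.abs(M @ M.T - np.eye(3))) < 1e-12

    def test_radial_force_at_zero_angles(self):
        assert rotate_micro_force(1.0, 0.0, 0.0, 0.0, 0.0) == (-1.0, -0.0, -0.0)

    @given(st.floats(-np.pi, np.pi), st.floats(-2 * np.pi, 2 * np.pi),
           st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_norm_preserved(self, theta, phi, fr, fa, ft):
        out = np.array(rotate_micro_force(fr, fa, ft, theta, phi))
        assert np.linalg.norm(out) == pytest.approx(
            np.linalg.norm([fr, fa, ft]), abs=1e-9)


class TestInstantaneousWrench:
    def test_no_engagement_gives_zero(self, step_vol, norm, coeffs, spec):
        plan = MillingPlan(workspace_origin=np.array([0.0, 1.8, 6.0]))
        pose = pose_at(0.0, plan, plan.path_record(1, 1), spec=spec)
        w = instantaneous_wrench(pose, [], step_vol, norm, coeffs, spec, 0.009)
        assert w.as_array().tolist() == [0.0, 0.0, 0.0, 0.0]
        assert w.frame == "i-MCCS"

    def test_matches_vectorized_trace(self, step_vol, norm, coeffs, spec):
        """The readable per-edge sum and the fast trace agree sample-wise."""
        plan = MillingPlan(workspace_origin=np.array([0.0, 1.8, 6.0]))
        rec = plan.path_record(1, 1)
        stock = Stock.from_volume(step_vol)
        state = MachinedState.nominal(plan, spec, 1, 1)
        trace = trace_path_forces(step_vol, plan, spec, coeffs, norm, rec,
                                  state, stock, phi_rand=0.3, n_substeps=1)
        k = 200
        # substep centering puts the sample instant at (k + 0.5) / fs
        t_k = (k + 0.5) / plan.fs
        pose = pose_at(t_k, plan, rec, spec=spec, phi0=0.3)
        sweep = (rec.start + [0, 0, spec.radius_R],
                 pose.translation)
        eng = engaged_edges(pose, edge_points(spec), state, stock,
                            current_sweep=sweep)
        w = instantaneous_wrench(pose, eng, step_vol, norm, coeffs, spec,
                                 vt_mag=0.009375)
        assert np.allclose(w.as_array(), trace.forces[k], rtol=1e-9, atol=1e-9)

    def test_deterministic(self, step_vol, norm, coeffs, spec):
        plan = MillingPlan(workspace_origin=np.array([0.0, 1.8, 6.0]))
        rec = plan.path_record(1, 1)
        stock = Stock.from_volume(step_vol)
        state = MachinedState.nominal(plan, spec, 1, 1)
        t1 = trace_path_forces(step_vol, plan, spec, coeffs, norm, rec,
                               state, stock, phi_rand=1.0)
        state2 = MachinedState.nominal(plan, spec, 1, 1)
        t2 = trace_path_forces(step_vol, plan, spec, coeffs, norm, rec,
                               state2, stock, phi_rand=1.0)
        assert np.array_equal(t1.forces, t2.forces)


@pytest.fixture(scope="module")
def bank(step_vol, table_plan, spec, coeffs, norm):
    return predict_bank(step_vol, table_plan, spec, coeffs, norm, phase_seed=3)


class TestPredictBank:

    def test_bookkeeping(self, bank, table_plan):
        assert bank.shape == (3, 4, 32)
        assert bank.flat_sequences().shape == (384, 15, 4)
        seq, land = bank.entry(GridIndex(2, 3, 5))
        assert seq.shape == (15, 4)
        assert np.allclose(land, table_plan.landmark(GridIndex(2, 3, 5)))

    def test_gradient_aligned_thrust_trend(self, bank):
        """Milling along the density gradient: |Fz| grows along the path
        wherever the full contact patch lies inside the block (the last
        few grids overhang the volume end and taper into air)."""
        mean_fz = np.abs(bank.sequences[1, 1, :, :, 2]).mean(axis=1)
        interior = mean_fz[:-5]
        drops = np.diff(interior)
        assert np.all(drops > -0.05 * np.abs(interior[:-1] + 1e-9))
        assert interior[-1] > 10 * max(interior[0], 1e-6)

    def test_perpendicular_paths_flat_profiles(self, spec, coeffs, norm):
        """Milling across the gradient: constant density along each path."""
        from lamigrind import make_step_phantom

        vol = make_step_phantom(gradient_axis=1)
        plan = MillingPlan(workspace_origin=np.array([0.0, 1.8, 6.0]))
        bank = predict_bank(vol, plan, spec, coeffs, norm, phase_seed=3)
        # interior grids of a mid-gray path (skip entry/exit transients)
        mean_fz = np.abs(bank.sequences[0, 2, 6:-6, :, 2]).mean(axis=1)
        assert np.ptp(mean_fz) <= 0.05 * np.abs(mean_fz).mean()

    def test_flat_index_round_trip(self, bank):
        for b in [0, 17, 383]:
            idx = bank.flat_index(b)
            seq, _ = bank.entry(idx)
            assert np.array_equal(seq, bank.flat_sequences()[b])
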