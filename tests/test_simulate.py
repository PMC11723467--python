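import numpy as np
import pytest

from lamigrind import FeedDisturbance, PoseDeviation, correlation_matrix, predict_bank, simulate_run
from lamigrind.experiments import (
    bestnum_sweep,
    lamina_protocol,
    run_experiment_suite,
    stepped_protocol,
)
from lamigrind.simulate import SimulationError, draw_random_deviation, independent_pairs


class TestPoseDeviation:
    def test_identity(self):
        dev = PoseDeviation()
        assert dev.is_identity
        pts = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(dev.apply(pts), pts)

    def test_rotation_about_origin_then_translation(self):
        dev = PoseDeviation(rotation=(0.0, 0.0, 0.05), translation=(1.0, 0.0, 0.0),
                            origin=(2.0, 2.0, 0.0))
        p = dev.apply(np.array([2.0, 2.0, 0.0]))  # the origin only translates
        assert np.allclose(p, [3.0, 2.0, 0.0])

    def test_small_angle_invariant_enforced(self):
        with pytest.raises(ValueError):
            PoseDeviation(rotation=(0.2, 0.0, 0.0))

    def test_random_draw_respects_bounds(self, rng):
        for _ in range(50):
            dev = draw_random_deviation(rng, origin=np.zeros(3))
            assert np.all(np.abs(dev.rotation) < 0.1)


class TestFeedDisturbance:
    def test_rates_and_offsets_consistent(self):
        feed = FeedDisturbance(amplitude=0.2, frequency=1.0, phase=0.3)
        t = np.linspace(0, 10, 2001)
        offs = feed.offsets(0.5, t)
        # numerical integral of the rate matches the closed form
        num = np.concatenate([[0.0], np.cumsum(
            (feed.rates(0.5, t)[1:] + feed.rates(0.5, t)[:-1]) / 2 * np.diff(t))])
        assert np.max(np.abs(offs - num)) < 1e-4

    def test_zero_amplitude_is_nominal(self):
        feed = FeedDisturbance(amplitude=0.0)
        t = np.linspace(0, 5, 11)
        assert np.allclose(feed.offsets(0.5, t), 0.5 * t)

    def test_nonpositive_feed_rejected(self):
        feed = FeedDisturbance(amplitude=0.7)
        with pytest.raises(ValueError):
            feed.rates(0.5, np.linspace(0, 2, 50))


@pytest.fixture(scope="module")
def protocol():
    return stepped_protocol()


class TestSimulateRun:

    def test_deterministic_given_seed(self, protocol):
        vol, plan, spec, coeffs, norm = protocol
        a, _ = simulate_run(vol, plan, spec, coeffs, norm, noise_sigma=0.05, seed=9)
        b, _ = simulate_run(vol, plan, spec, coeffs, norm, noise_sigma=0.05, seed=9)
        assert np.array_equal(a.data, b.data)
        c, _ = simulate_run(vol, plan, spec, coeffs, norm, noise_sigma=0.05, seed=10)
        assert not np.array_equal(a.data, c.data)

    def test_nominal_run_reproduces_bank_exactly(self, protocol):
        """Zero deviation/noise/disturbance with the bank's phases: the
        signal equals the concatenated bank sequences sample for sample."""
        vol, plan, spec, coeffs, norm = protocol
        bank = predict_bank(vol, plan, spec, coeffs, norm, phase_seed=5)
        sig, _ = simulate_run(vol, plan, spec, coeffs, norm, noise_sigma=0.0,
                              seed=1, phase_seed=5)
        expected = bank.sequences.reshape(-1, 4)
        assert np.array_equal(sig.data, expected)

    def test_ground_truth_records_deviation(self, protocol):
        vol, plan, spec, coeffs, norm = protocol
        dev = PoseDeviation(translation=(0.0, 0.4, -0.2),
                            origin=plan.workspace_origin)
        _, truth = simulate_run(vol, plan, spec, coeffs, norm, deviation=dev,
                                seed=2)
        dnr, dnl = truth.true_offsets()
        assert dnr == pytest.approx(0.4, abs=1e-9)
        assert dnl == pytest.approx(-0.2, abs=1e-9)

    def test_runaway_deviation_aborts(self, protocol):
        vol, plan, spec, coeffs, norm = protocol
        dev = PoseDeviation(translation=(0.0, 50.0, 0.0),
                            origin=plan.workspace_origin)
        with pytest.raises(SimulationError):
            simulate_run(vol, plan, spec, coeffs, norm, deviation=dev, seed=0)

    def test_printed_narrow_condition_runs(self):
        """The large reference deviation (condition 8) completes on a
        lamina phantom with margins."""
        from lamigrind.simulate import NARROW_PLAN_DEVIATIONS

        rx, ry, rz, tx, ty, tz, incline = NARROW_PLAN_DEVIATIONS[7]
        vol, plan, spec, coeffs, norm = lamina_protocol(3, n_layers=2,
                                                        incline_deg=incline)
        dev = PoseDeviation(rotation=(rx, ry, rz), translation=(tx, ty, tz),
                            origin=plan.workspace_origin)
        sig, truth = simulate_run(vol, plan, spec, coeffs, norm, deviation=dev,
                                  noise_sigma=0.05, seed=4)
        assert len(sig) == plan.n_paths_total * plan.samples_per_path
        assert np.all(np.isfinite(truth.tip))


class TestCorrelationMatrix:
    def test_diagonal_is_one(self, rng):
        R = correlation_matrix(rng.normal(size=(5, 40)))
        assert np.allclose(np.diag(R), 1.0)

    def test_affine_invariance(self, rng):
        s = rng.normal(size=40)
        R = correlation_matrix(np.stack([s, 2 * s + 3]))
        assert R[0, 1] == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        s = rng.normal(size=40)
        R = correlation_matrix(np.stack([s, -s]))
        assert R[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_row_scored_zero(self, rng):
        s = rng.normal(size=40)
        R = correlation_matrix(np.stack([s, np.full(40, 2.0)]))
        assert R[0, 1] == 0.0 and R[1, 1] == 1.0

    def test_independence_flagging(self):
        R = np.array([[1.0, 0.2, 0.8], [0.2, 1.0, -0.3], [0.8, -0.3, 1.0]])
        assert independent_pairs(R) == [(0, 1), (1, 2)]


class TestExperimentSuite:
    def test_empty_seed_list_gives_empty_report(self):
        rep = run_experiment_suite({"kind": "feed_sweep"}, seeds=[])
        assert rep == {"conditions": [], "errors": []}

    def test_amplitude_sweep_enumerates_five_conditions(self):
        rep = run_experiment_suite(
            {"kind": "feed_sweep", "amplitudes": (0.05, 0.10, 0.15, 0.20, 0.30),
             "seeds_per_amplitude": 0}, seeds=[1])
        assert len(rep["conditions"]) == 5

    def test_unknown_kind_recorded_not_raised(self):
        rep = run_experiment_suite({"kind": "bogus"}, seeds=[1])
        assert rep["conditions"] == []
        assert len(rep["errors"]) == 1

    def test_bestnum_sweep_runs_all_settings(self):
        res = bestnum_sweep(seed=5, n2_values=(20, 25, 30, 32))
        assert [r["n2"] for r in res] == [20, 25, 30, 32]
        assert all(np.isfinite(r["distance_deviation_error_mm"]) for r in res)
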