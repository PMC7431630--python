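"""Time-domain driver: steady-state detection, determinism, instability
flagging, perturbation response."""

import numpy as np
import pytest

import spinectrl as sc


class TestSteadyStateDetector:
    def test_constant_history_converges_after_ramp_plus_window(self):
        t = np.arange(1, 3001) * 1e-3
        ok, tc = sc.detect_steady_state(t, np.zeros_like(t), np.zeros_like(t),
                                        0.2, 1.0, window=1.0, ramp_time=0.2)
        assert ok
        assert tc == pytest.approx(0.2 + 1.0, abs=2e-3)

    def test_persistent_oscillation_never_converges(self):
        t = np.arange(1, 3001) * 1e-3
        err = 0.5 + 0.5 * np.sin(20 * t)     # exceeds tol forever
        ok, tc = sc.detect_steady_state(t, err, np.zeros_like(t), 0.2, 1.0, 1.0)
        assert not ok and np.isnan(tc)

    def test_window_must_hold_continuously(self):
        t = np.arange(1, 5001) * 1e-3
        err = np.zeros_like(t)
        err[599] = 1.0                       # spike before the first full
        ok, tc = sc.detect_steady_state(t, err, np.zeros_like(t), 0.2, 1.0, 1.0)
        assert ok                            # window restarts after it
        assert tc == pytest.approx(0.6 + 1.0, abs=2e-3)


class TestLoadingCases:
    def test_builtin_cases_match_reference_loads(self):
        assert sc.STUDY_CASES[1].P == (635, 0, 0, 0, 0)
        assert sc.STUDY_CASES[2].P == (350, 50, 50, 50, 50)
        for c in (3, 4, 5):
            assert sc.STUDY_CASES[c].P == (110,) * 5
        assert [sc.STUDY_CASES[c].D_mm for c in (1, 2, 3, 4, 5)] == \
            [50.0, 50.0, 50.0, 25.0, 75.0]
        assert all(sc.STUDY_CASES[c].ramp_time == 0.2 for c in range(1, 6))

    def test_invalid_cases_rejected(self):
        with pytest.raises(ValueError):
            sc.LoadingCase((-10, 0, 0, 0, 0), 50.0)
        with pytest.raises(ValueError):
            sc.LoadingCase((100, 0, 0, 0, 0), 0.0)


class TestRunCase:
    def test_without_controller_every_case_is_flagged_unstable(self):
        """The bare column is far above its buckling load under every
        loading case; the uncontrolled run must be aborted and flagged,
        never silently continued."""
        cfg = sc.SimulationConfig(t_end=15.0, controller=False)
        for c in range(1, 6):
            res = sc.run_case(c, cfg)
            assert res.unstable, f"case {c} not flagged unstable"

    def test_uncontrolled_static_equilibrium_is_far_from_target(self):
        """Even the post-buckled static equilibrium without muscles lies
        tens of millimetres from the reference posture."""
        from spinectrl.beam import BeamModel
        g = sc.build_geometry()
        model = BeamModel(g)
        f = np.zeros(model.ndof)
        for k, p in enumerate(sc.STUDY_CASES[1].P):
            f[3 * g.lumbar_nodes[4 - k]] -= p
        u = model.solve_static(f)
        assert np.abs(u[1::3]).max() * 1e3 > 50.0

    def test_zero_load_converges_with_idle_muscles(self):
        cfg = sc.SimulationConfig(t_end=2.0)
        res = sc.run_case(sc.LoadingCase((0, 0, 0, 0, 0), 50.0), cfg)
        assert res.converged and not res.unstable
        assert res.steady_alphas().max() == pytest.approx(0.0, abs=1e-6)
        assert res.max_tracking_error_mm < 1e-6

    def test_identical_configurations_are_bit_identical(self):
        cfg = sc.SimulationConfig(t_end=1.0)
        r1 = sc.run_case(2, cfg)
        r2 = sc.run_case(2, cfg)
        assert np.array_equal(r1.z_lumbar_mm, r2.z_lumbar_mm)
        assert np.array_equal(r1.muscle_forces, r2.muscle_forces)
        assert np.array_equal(r1.alphas, r2.alphas)


class TestPerturbation:
    def test_pulse_validation(self):
        cfg = sc.SimulationConfig(t_end=2.0)
        with pytest.raises(ValueError):
            sc.run_perturbation(1, [(1.0, 0.5, 100.0)], cfg)
        with pytest.raises(ValueError):
            sc.run_perturbation(1, [(1.0, 3.0, 100.0)], cfg)

    def test_zero_amplitude_pulse_equals_plain_run(self):
        cfg = sc.SimulationConfig(t_end=1.0)
        plain = sc.run_case(1, cfg)
        pulsed = sc.run_perturbation(1, [(0.3, 0.6, 0.0)], cfg)
        assert np.array_equal(plain.z_lumbar_mm, pulsed.z_lumbar_mm)
        assert np.array_equal(plain.muscle_forces, pulsed.muscle_forces)

    def test_muscle_force_tracks_load_pulses(self):
        """-100 N / +100 N pulses at L1 make the top-level muscle force
        fall / rise relative to the unperturbed run, and the tracking
        error returns toward zero afterwards."""
        cfg = sc.SimulationConfig(t_end=4.0)
        pulses = [(0.5, 1.0, -100.0), (1.5, 2.0, 100.0)]
        plain = sc.run_case(1, cfg)
        pulsed = sc.run_perturbation(1, pulses, cfg)
        assert not pulsed.unstable
        t = pulsed.time
        # total force of the L1 pair, compared at matched times
        pair = pulsed.muscle_forces[:, 8:10].sum(axis=1)
        ref = plain.muscle_forces[:, 8:10].sum(axis=1)

        def mean(x, t0, t1):
            m = (t >= t0) & (t < t1)
            return x[m].mean()

        assert mean(pair, 0.6, 1.0) < mean(ref, 0.6, 1.0)   # -100 N
        assert mean(pair, 1.6, 2.0) > mean(ref, 1.6, 2.0)   # +100 N
        assert pulsed.pos_err_mm[-1] < 0.2


class TestMeshRefinement:
    def test_section_loads_stable_under_element_splitting(self):
        """Splitting every beam element in two changes the quasi-steady
        section loads by <2% (matched horizons)."""
        cfg = sc.SimulationConfig(t_end=8.0)
        coarse = sc.run_case(3, cfg)
        fine = sc.run_case(3, cfg, geometry=sc.build_geometry().refine(2))
        assert not fine.unstable
        ca = np.array([s.compression for s in coarse.section_loads])
        cb = np.array([s.compression for s in fine.section_loads])
        assert np.abs(ca - cb).max() / ca.max() < 0.02


class TestLoadSweep:
    def test_sweep_input_validation(self):
        with pytest.raises(ValueError):
            sc.run_load_sweep(2, [150.0, 1500.0])

    def test_single_point_sweep_is_degenerate_but_reports_forces(self):
        cfg = sc.SimulationConfig(t_end=1.5)
        table = sc.run_load_sweep(2, [150.0], cfg)
        assert table["forces"].shape[0] == 1
        assert np.isfinite(table["forces"]).all()
        assert all(f["degenerate"] for f in table["fits"])
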