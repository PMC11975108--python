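"""Scaling of human gait traces to mouse commands, waveforms and timelines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitloop as gl
from gaitloop.protocol import (InvalidArchitectureError,
                               map_excitation_to_voltage)


def make_trace(fiber_length, time=None, excitation=None, force=None):
    fiber_length = np.asarray(fiber_length, float)
    n = len(fiber_length)
    return gl.HumanGaitTrace(
        np.linspace(0, 1.1, n) if time is None else time,
        fiber_length,
        np.zeros(n) if excitation is None else excitation,
        np.zeros(n) if force is None else force,
    )


class TestNormalizeLength:
    def test_identity_at_optimal_length(self, soleus_arch):
        tr = make_trace(np.full(50, soleus_arch.lo_human_mm))
        out = gl.normalize_length(tr, soleus_arch)
        np.testing.assert_allclose(out.value, 1.0)
        np.testing.assert_array_equal(out.time_s, tr.time_s)

    def test_linear_scaling(self, soleus_arch):
        tr = make_trace(np.full(10, 1.2 * soleus_arch.lo_human_mm))
        np.testing.assert_allclose(gl.normalize_length(tr, soleus_arch).value, 1.2)

    def test_rejects_bad_architecture(self):
        with pytest.raises((InvalidArchitectureError, ValueError)):
            gl.MuscleArchitecture("soleus", 12.0, -44.0, 2800.0)

    def test_gait_cycle_starts_below_optimal(self, soleus_trace, soleus_arch):
        out = gl.normalize_length(soleus_trace, soleus_arch)
        assert out.value[0] < 1.0


class TestScaleToMouse:
    def test_zero_delta_at_optimal(self, soleus_arch):
        norm = gl.NormalizedTrace(np.linspace(0, 1, 40), np.ones(40))
        cmd = gl.scale_to_mouse(norm, soleus_arch)
        np.testing.assert_allclose(cmd.delta_length_mm, 0.0, atol=1e-12)
        np.testing.assert_allclose(cmd.voltage_v, 0.0)

    def test_affine_range_mapping(self, soleus_arch):
        t = np.linspace(0, 1, 60)
        value = 0.9 + 0.4 * (0.5 - 0.5 * np.cos(2 * np.pi * t))  # [0.9, 1.3]
        cmd = gl.scale_to_mouse(gl.NormalizedTrace(t, value), soleus_arch)
        lo = soleus_arch.lo_mouse_mm
        assert cmd.delta_length_mm.min() >= 0.9 * lo - lo - 1e-9
        assert cmd.delta_length_mm.max() <= 1.3 * lo - lo + 1e-9

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_composition_matches_affine_oracle(self, seed):
        """normalize + rescale equals (L/Lo_h - 1) * Lo_m at every sample."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 60))
        t = np.sort(rng.uniform(0, 1.2, n))
        t[0], t[-1] = 0.0, 1.2
        t = np.unique(t)
        length = rng.uniform(20.0, 60.0, len(t))
        arch = gl.MuscleArchitecture("soleus",
                                     lo_mouse_mm=float(rng.uniform(5, 20)),
                                     lo_human_mm=float(rng.uniform(30, 60)),
                                     fmax_human_n=1000.0)
        tr = make_trace(length, time=t)
        # oracle on the source grid (before resampling)
        oracle = (length / arch.lo_human_mm - 1.0) * arch.lo_mouse_mm
        norm = gl.normalize_length(tr, arch)
        direct = norm.value * arch.lo_mouse_mm - arch.lo_mouse_mm
        np.testing.assert_allclose(direct, oracle, rtol=1e-12)

    def test_resampling_preserves_extrema_within_interpolation_error(
            self, soleus_trace, soleus_arch):
        norm = gl.normalize_length(soleus_trace, soleus_arch)
        cmd = gl.scale_to_mouse(norm, soleus_arch, sample_rate_hz=222.0)
        src_delta = norm.value * soleus_arch.lo_mouse_mm - soleus_arch.lo_mouse_mm
        # PCHIP does not overshoot; extrema match within one sample's slew
        dt = 1.0 / 222.0
        max_slew = np.max(np.abs(np.diff(src_delta))) / np.min(
            np.diff(soleus_trace.time_s)) * dt
        assert abs(cmd.delta_length_mm.max() - src_delta.max()) <= max_slew
        assert abs(cmd.delta_length_mm.min() - src_delta.min()) <= max_slew
        assert cmd.delta_length_mm.max() <= src_delta.max() + 1e-9  # no overshoot
        assert cmd.delta_length_mm.min() >= src_delta.min() - 1e-9


class TestNormalizeForce:
    def test_basic_arithmetic(self):
        out = gl.normalize_force([10.0, 25.0], 50.0)
        np.testing.assert_allclose(out.value, [0.2, 0.5])
        np.testing.assert_allclose(gl.normalize_force([50.0], 50.0).value, 1.0)
        np.testing.assert_allclose(gl.normalize_force([0.0], 50.0).value, 0.0)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            gl.normalize_force([1.0], 0.0)


class TestEccentricCommand:
    @pytest.mark.parametrize("strain,ramp_ms", [(0.10, 200), (0.20, 400),
                                                (0.30, 600)])
    def test_ramp_duration_and_final_displacement(self, soleus_arch, strain,
                                                  ramp_ms):
        spec = gl.EccentricSpec(strain=strain)
        cmd = gl.build_eccentric_command(spec, soleus_arch)
        assert cmd.meta["realized_ramp_s"] * 1000 == pytest.approx(ramp_ms)
        assert cmd.delta_length_mm[-1] == pytest.approx(
            strain * soleus_arch.lo_mouse_mm)
        # isometric hold commands no displacement
        hold = cmd.time_s < spec.isometric_hold_s
        np.testing.assert_allclose(cmd.delta_length_mm[hold][:-1], 0.0)

    def test_zero_strain_is_pure_isometric(self, soleus_arch):
        cmd = gl.build_eccentric_command(gl.EccentricSpec(strain=0.0),
                                         soleus_arch)
        np.testing.assert_allclose(cmd.delta_length_mm, 0.0)
        assert np.all(cmd.voltage_v > 0)

    def test_hand_arithmetic_endpoint(self):
        arch = gl.MuscleArchitecture("EDL", lo_mouse_mm=12.0, lo_human_mm=69.0,
                                     fmax_human_n=350.0)
        cmd = gl.build_eccentric_command(gl.EccentricSpec(strain=0.30), arch)
        assert cmd.delta_length_mm[-1] == pytest.approx(3.6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.01, 0.5), st.floats(100.0, 2000.0))
    def test_endpoint_exact_for_random_strains(self, strain, fs):
        arch = gl.MuscleArchitecture("soleus", 12.0, 44.0, 2800.0)
        cmd = gl.build_eccentric_command(gl.EccentricSpec(strain=strain), arch,
                                         sample_rate_hz=fs)
        assert cmd.delta_length_mm[-1] == pytest.approx(12.0 * strain, rel=1e-12)


class TestGaitCycleCommand:
    def test_one_second_cycle_has_222_samples(self, soleus_trace, soleus_arch):
        cmd = gl.build_gait_cycle_command(soleus_trace, soleus_arch)
        assert cmd.n_samples == 222
        assert cmd.sample_rate_hz == 222.0

    def test_zero_voltage_scale(self, soleus_trace, soleus_arch):
        cmd = gl.build_gait_cycle_command(soleus_trace, soleus_arch,
                                          voltage_scale=0.0)
        np.testing.assert_allclose(cmd.voltage_v, 0.0)

    def test_full_excitation_maps_to_range_top(self):
        v = map_excitation_to_voltage(np.ones(5), 1.0, (0.0, 20.0))
        np.testing.assert_allclose(v, 20.0)

    def test_cycle_starts_below_optimal_length(self, soleus_trace, soleus_arch):
        cmd = gl.build_gait_cycle_command(soleus_trace, soleus_arch)
        assert cmd.delta_length_mm[0] < 0

    def test_concatenated_cycles_keep_uniform_grid(self, soleus_trace,
                                                   soleus_arch):
        cmd = gl.build_gait_cycle_command(soleus_trace, soleus_arch, n_cycles=3)
        assert cmd.n_samples == 3 * 222
        np.testing.assert_allclose(np.diff(cmd.time_s), 1 / 222.0, rtol=1e-9)


class TestTimelines:
    def test_cycling200_event_counts(self):
        tl = gl.build_timeline("cycling200")
        assert tl.count(gl.EventKind.GAIT_CYCLE) == 200
        assert tl.count(gl.EventKind.REST, between_sets=True) == 7
        # viability tetani: mid-protocol after cycle 100 and post-protocol
        assert tl.count(gl.EventKind.TETANUS, phase="mid_protocol") == 1
        assert tl.count(gl.EventKind.TETANUS, phase="post_protocol") == 1
        assert tl.count(gl.EventKind.FORCE_FREQUENCY_STEP, phase="pre") == 10
        assert tl.count(gl.EventKind.FORCE_FREQUENCY_STEP, phase="post") == 10
        assert tl.total_span_s <= 5400.0

    def test_cycling25_has_single_set(self):
        tl = gl.build_timeline("cycling25")
        assert tl.count(gl.EventKind.GAIT_CYCLE) == 25
        assert tl.count(gl.EventKind.REST, between_sets=True) == 0
        assert tl.total_span_s <= 5400.0

    def test_eccentric_reps_and_quiescence(self):
        spec = gl.EccentricSpec(strain=0.2)
        tl = gl.build_timeline("eccentric", spec=spec)
        reps = [e for e in tl.events if e.kind is gl.EventKind.ECCENTRIC_REP]
        assert len(reps) == 5
        gaps = [b.start_s - a.end_s for a, b in zip(reps, reps[1:])]
        np.testing.assert_allclose(gaps, 240.0)
        recov = [e for e in tl.events
                 if e.kind is gl.EventKind.TETANUS
                 and e.attrs.get("phase") == "recovery"]
        assert [e.attrs["recovery_min"] for e in recov] == [5.0, 10.0, 15.0, 30.0]
        final_stretch_end = reps[-1].end_s
        np.testing.assert_allclose(
            [e.start_s - final_stretch_end for e in recov],
            [300.0, 600.0, 900.0, 1800.0])

    @pytest.mark.parametrize("kind", ["eccentric", "cycling25", "cycling200"])
    def test_events_never_overlap(self, kind):
        spec = gl.EccentricSpec(strain=0.1) if kind == "eccentric" else None
        tl = gl.build_timeline(kind, spec=spec)
        for a, b in zip(tl.events, tl.events[1:]):
            assert b.start_s >= a.end_s - 1e-9

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            gl.build_timeline("cycling50")
        with pytest.raises(ValueError):
            gl.build_timeline("eccentric")  # missing spec


class TestValidation:
    def test_trace_invariants(self):
        with pytest.raises(ValueError):
            make_trace([44.0, 44.0], excitation=np.array([0.0, 1.5]))
        with pytest.raises(ValueError):
            make_trace([44.0, 44.0], time=np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            make_trace([44.0, 44.0], force=np.array([-1.0, 0.0]))

    def test_command_grid_must_be_uniform(self):
        with pytest.raises(ValueError):
            gl.CommandWaveform(np.array([0.0, 0.1, 0.3]), np.zeros(3),
                               np.zeros(3), 10.0)
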