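"""Ground-truth behavior of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from nfvisco import (
    FrameGenSpec,
    ParameterError,
    PronyModel,
    RelaxationGenSpec,
    TensileGenSpec,
    generate_frames,
    generate_relaxation_trace,
    generate_tensile_curve,
    group_stress,
    voronoi_volumes,
)
from nfvisco.synthetic import tensile_mean_stress


class TestRelaxationTraceGenerator:
    def test_sample_count_and_noiseless_expectation(self, three_param_model):
        spec = RelaxationGenSpec(model=three_param_model, duration=1000.0, dt=1.0, noise_sd=0.0)
        trace = generate_relaxation_trace(spec)
        assert len(trace) == 1001
        assert trace.modulus[0] == pytest.approx(0.930)
        np.testing.assert_allclose(trace.modulus, three_param_model.evaluate(trace.time))

    def test_long_time_value_reaches_long_term_modulus(self, three_param_model):
        spec = RelaxationGenSpec(model=three_param_model, duration=880.0, dt=878.66, noise_sd=0.0)
        trace = generate_relaxation_trace(spec)  # second sample sits at 10*tau
        assert trace.modulus[-1] == pytest.approx(0.103, abs=1e-4)

    def test_seeded_generation_is_bit_identical(self, three_param_model):
        spec = RelaxationGenSpec(model=three_param_model, noise_sd=0.05, seed=7)
        a = generate_relaxation_trace(spec)
        b = generate_relaxation_trace(spec)
        assert np.array_equal(a.modulus, b.modulus) and np.array_equal(a.time, b.time)

    def test_noiseless_trace_is_non_increasing(self, three_param_model, two_param_model):
        for model in (three_param_model, two_param_model):
            trace = generate_relaxation_trace(RelaxationGenSpec(model=model, noise_sd=0.0))
            assert np.all(np.diff(trace.modulus) <= 0)

    def test_mean_of_noisy_traces_converges_to_noiseless(self, three_param_model):
        # Monte-Carlo mean converges at ~1/sqrt(N), checked at N=1000.  The
        # per-point bound uses 4 sigma so the family-wise false-alarm rate
        # over the 51 simultaneous points stays below 0.2%; the RMS check is
        # the sensitive one (any systematic bias inflates it immediately).
        n, sd = 1000, 0.05
        clean = generate_relaxation_trace(
            RelaxationGenSpec(model=three_param_model, duration=50.0, dt=1.0, noise_sd=0.0)
        )
        acc = np.zeros_like(clean.modulus)
        for seed in range(n):
            acc += generate_relaxation_trace(
                RelaxationGenSpec(model=three_param_model, duration=50.0, dt=1.0,
                                  noise_sd=sd, seed=seed)
            ).modulus
        dev = acc / n - clean.modulus
        se = sd / np.sqrt(n)
        assert np.max(np.abs(dev)) <= 4 * se
        assert np.sqrt(np.mean(dev**2)) == pytest.approx(se, rel=0.25)

    @pytest.mark.parametrize("bad", [
        dict(duration=0.0), dict(dt=0.0), dict(dt=-1.0), dict(noise_sd=-0.1),
        dict(duration=1.0, dt=2.0),
    ])
    def test_invalid_spec_rejected(self, three_param_model, bad):
        with pytest.raises(ParameterError):
            RelaxationGenSpec(model=three_param_model, **bad)


class TestTensileCurveGenerator:
    def test_noiseless_piecewise_linear_values(self):
        spec = TensileGenSpec(unfold_slope=0.05, stretch_slope=0.5,
                              unfold_end_strain=1.5, max_strain=2.0, fluctuation_sd=0.0)
        assert tensile_mean_stress(spec, 2.0) == pytest.approx(0.325)
        assert tensile_mean_stress(spec, 0.0) == 0.0
        # continuity at the breakpoint
        eps = 1e-9
        assert tensile_mean_stress(spec, 1.5 - eps) == pytest.approx(
            tensile_mean_stress(spec, 1.5 + eps), abs=1e-6)

    def test_curve_endpoints_and_determinism(self):
        spec = TensileGenSpec(fluctuation_sd=0.02, seed=5)
        a = generate_tensile_curve(spec)
        b = generate_tensile_curve(spec)
        assert np.array_equal(a.stress, b.stress)
        assert a.strain[0] == 0.0 and a.strain[-1] == pytest.approx(spec.max_strain)

    def test_least_squares_recovers_stretch_slope_from_noisy_curve(self):
        spec = TensileGenSpec(unfold_slope=0.05, stretch_slope=0.5, unfold_end_strain=1.5,
                              max_strain=2.2, fluctuation_sd=0.02, n_points=500, seed=1)
        curve = generate_tensile_curve(spec)
        mask = curve.strain >= 1.5
        slope = stats.linregress(curve.strain[mask], curve.stress[mask]).slope
        assert slope == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("bad", [
        dict(max_strain=0.0), dict(unfold_end_strain=3.0),
        dict(unfold_slope=0.6), dict(fluctuation_sd=-1.0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ParameterError):
            TensileGenSpec(**bad)


class TestFrameGenerator:
    def _recover(self, frame):
        vols = voronoi_volumes(frame)
        return group_stress(frame, frame.ids, vols)

    def test_uniform_isotropic_prescription_recovered(self):
        target = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        frames = generate_frames(FrameGenSpec(n_atoms=8, box_edge=20.0,
                                              stress_history=(target,), seed=0))
        np.testing.assert_allclose(self._recover(frames[0]), target, atol=1e-9)

    def test_zero_prescription_recovered(self):
        frames = generate_frames(FrameGenSpec(n_atoms=8, box_edge=20.0,
                                              stress_history=(np.zeros(6),), seed=0))
        np.testing.assert_allclose(self._recover(frames[0]), 0.0, atol=1e-9)

    def test_random_partition_volume_weighted_sum_matches_prescription(self):
        history = tuple(np.array([0.9, -0.2, 0.4, 0.1, -0.3, 0.05]) * k
                        for k in (1.0, 0.5, 0.25))
        frames = generate_frames(FrameGenSpec(n_atoms=50, box_edge=50.0,
                                              stress_history=history, seed=3))
        assert len(frames) == 3
        for frame, target in zip(frames, history):
            recovered = self._recover(frame)
            np.testing.assert_allclose(recovered, target, rtol=1e-9, atol=1e-12)

    def test_atoms_lie_inside_box(self):
        frames = generate_frames(FrameGenSpec(n_atoms=20, box_edge=30.0,
                                              stress_history=(np.zeros(6),), seed=2))
        f = frames[0]
        assert np.all(f.coords >= f.box_bounds[:, 0]) and np.all(f.coords <= f.box_bounds[:, 1])

    def test_empty_history_rejected(self):
        with pytest.raises(ParameterError):
            FrameGenSpec(n_atoms=8, box_edge=20.0, stress_history=())
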