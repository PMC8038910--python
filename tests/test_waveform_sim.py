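"""Generator correctness: rendered templates, ground truth, cohorts."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tmpulse import (
    ManeuverSchedule,
    PulseMorphology,
    SimulationConfig,
    default_state_params,
    render_pulse,
    simulate_cohort,
    simulate_recording,
    triangular_slope_ratio,
)

from conftest import quiet_config, single_state_config


def secant_sr(cycle: np.ndarray) -> float:
    """Independent secant slope-ratio oracle for a rendered cycle.

    Foot at sample 0; the next foot is the (excluded) endpoint at value 0.
    """
    n = cycle.shape[0]
    peak = int(np.argmax(cycle))
    up = (cycle[peak] - cycle[0]) / peak
    down = (0.0 - cycle[peak]) / (n - peak)
    return down / up


def bare_envelope(rise: float, amplitude: float = 1.0) -> PulseMorphology:
    return PulseMorphology(
        peak_latencies=(0.2, 0.4, 0.6),
        peak_amplitudes=(0.0, 0.0, 0.0),
        peak_widths=(0.05, 0.05, 0.05),
        rise_fraction=rise,
        envelope_amplitude=amplitude,
    )


class TestRenderPulse:
    def test_symmetric_single_peak_has_sr_minus_one(self):
        # one bump at midcycle on a symmetric envelope: |up| == |down|
        morph = PulseMorphology(
            peak_latencies=(0.5, 0.6, 0.7),
            peak_amplitudes=(0.4, 0.0, 0.0),
            peak_widths=(0.06, 0.05, 0.05),
            rise_fraction=0.5,
        )
        cycle = render_pulse(morph, 1.0, 100.0)
        assert int(np.argmax(cycle)) == 50
        assert secant_sr(cycle) == pytest.approx(-1.0, abs=1e-12)

    def test_triangular_rise_098_gives_minus_49(self):
        cycle = render_pulse(bare_envelope(0.98), 1.0, 100.0)
        assert secant_sr(cycle) == pytest.approx(-49.0, abs=1e-9)

    @pytest.mark.parametrize("rise", [0.2, 0.4, 0.5, 0.6, 0.75, 0.9, 0.95])
    def test_triangular_matches_closed_form(self, rise):
        # sample the peak exactly: rise * n integer for n = 200
        cycle = render_pulse(bare_envelope(rise), 1.0, 200.0)
        assert secant_sr(cycle) == pytest.approx(
            triangular_slope_ratio(rise), rel=1e-9
        )

    def test_dominant_peak_tracks_largest_bump(self):
        base = dict(
            peak_latencies=(0.15, 0.35, 0.55),
            peak_widths=(0.05, 0.05, 0.05),
            rise_fraction=0.9,
        )
        p1 = render_pulse(
            PulseMorphology(peak_amplitudes=(1.0, 0.6, 0.3), **base), 1.0, 200.0
        )
        p2 = render_pulse(
            PulseMorphology(peak_amplitudes=(0.6, 1.0, 0.3), **base), 1.0, 200.0
        )
        # P1-dominant pulse peaks at l1; P2-dominant shifts the peak rightward
        assert abs(np.argmax(p1) - 0.15 * 200) <= 2
        assert abs(np.argmax(p2) - 0.35 * 200) <= 2
        assert np.argmax(p2) > np.argmax(p1)

    def test_envelope_peak_lands_at_rise_fraction_within_one_sample(self):
        for rise in (0.6, 0.85):
            cycle = render_pulse(bare_envelope(rise), 0.857, 200.0)
            assert abs(int(np.argmax(cycle)) - rise * cycle.shape[0]) <= 1

    def test_all_zero_amplitudes_render_flat_cycle(self):
        morph = bare_envelope(0.5, amplitude=0.0)
        cycle = render_pulse(morph, 1.0, 100.0)
        assert np.all(cycle == 0.0)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(rise_fraction=1.5), "rise_fraction"),
            (dict(peak_latencies=(0.4, 0.3, 0.6)), "peak_latencies"),
            (dict(peak_amplitudes=(-0.1, 0.2, 0.1)), "peak_amplitudes"),
            (dict(peak_widths=(0.05, 0.0, 0.05)), "peak_widths"),
        ],
    )
    def test_invalid_fractions_rejected_naming_field(self, kwargs, field):
        params = dict(
            peak_latencies=(0.2, 0.4, 0.6),
            peak_amplitudes=(0.1, 0.1, 0.1),
            peak_widths=(0.05, 0.05, 0.05),
            rise_fraction=0.6,
        )
        params.update(kwargs)
        with pytest.raises(ValueError, match=field):
            PulseMorphology(**params)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            render_pulse(bare_envelope(0.5), 0.05, 100.0)

    @given(
        r1=st.floats(min_value=0.15, max_value=0.9),
        dr=st.floats(min_value=0.02, max_value=0.09),
    )
    def test_template_sr_strictly_decreasing_in_rise_fraction(self, r1, dr):
        sr1 = triangular_slope_ratio(r1)
        sr2 = triangular_slope_ratio(r1 + dr)
        assert sr2 < sr1


class TestSimulateRecording:
    def test_exact_pulse_count_without_jitter(self, quiet_minute_trace):
        trace, truth = quiet_minute_trace
        assert truth.n_pulses == 60
        assert trace.n_samples == 60 * 200

    def test_default_schedule_length_is_330_seconds(self):
        config = SimulationConfig(seed=3)
        trace, truth = simulate_recording(config)
        assert trace.n_samples == 66_000
        assert trace.duration_s == pytest.approx(330.0)
        assert [s.label for s in trace.segments] == [
            "upright_baseline",
            "head_down_tilt",
            "hyperventilation",
            "recovery",
        ]

    def test_bit_identical_under_same_seed(self):
        config = single_state_config(duration=30.0, seed=11)
        t1, g1 = simulate_recording(config)
        t2, g2 = simulate_recording(config)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(g1.peak_samples, g2.peak_samples)
        assert np.array_equal(g1.template_sr, g2.template_sr)

    def test_fiducials_are_cycle_extrema_at_zero_noise(self):
        config = quiet_config(duration=30.0, cycle_jitter_cv=0.02)
        trace, truth = simulate_recording(config, rng=np.random.default_rng(2))
        x = trace.samples
        for f, p, e in zip(
            truth.foot_samples, truth.peak_samples, truth.end_samples
        ):
            span = x[f:e]
            assert f + int(np.argmin(span)) == f  # foot is the cycle minimum
            assert f + int(np.argmax(span)) == p  # peak is the cycle maximum

    def test_state_direction_and_reversal_of_template_sr(self):
        config = SimulationConfig(seed=4)
        _, truth = simulate_recording(config)
        mean_sr = {
            s: truth.template_sr[truth.states == s].mean()
            for s in np.unique(truth.states)
        }
        # elevated ICP (tilt) decreases SR; hyperventilation reverses it
        assert mean_sr["head_down_tilt"] < mean_sr["upright_baseline"]
        assert mean_sr["hyperventilation"] > mean_sr["head_down_tilt"]
        separation = mean_sr["upright_baseline"] - mean_sr["head_down_tilt"]
        assert abs(mean_sr["recovery"] - mean_sr["upright_baseline"]) < 0.1 * abs(
            separation
        )

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            ManeuverSchedule(())

    def test_ground_truth_indices_strictly_increasing(self, noisy_two_minutes):
        _, truth = noisy_two_minutes
        assert np.all(np.diff(truth.foot_samples) > 0)
        assert np.all(truth.foot_samples < truth.peak_samples)
        assert np.all(truth.peak_samples < truth.end_samples)


class TestSimulateCohort:
    def test_training_cohort_counts(self):
        recs = simulate_cohort(3, 2, SimulationConfig(seed=1), seed=1)
        counted = [r for r in recs if r.counted]
        assert len(counted) == 18
        assert sum(r.truth_class == "elevated" for r in counted) == 6

    def test_heldout_cohort_counts(self):
        recs = simulate_cohort(14, 1, SimulationConfig(seed=1), seed=1)
        counted = [r for r in recs if r.counted]
        assert len(counted) == 42
        assert sum(r.truth_class == "elevated" for r in counted) == 14

    def test_single_subject_single_state(self):
        recs = simulate_cohort(
            1,
            1,
            SimulationConfig(seed=2),
            seed=2,
            counted_states=("upright_baseline",),
            states=("upright_baseline",),
        )
        assert len(recs) == 1
        assert recs[0].truth_class == "normal"

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            simulate_cohort(0, 1, SimulationConfig(seed=0), seed=0)

    def test_subject_physiology_shared_across_rounds(self):
        recs = simulate_cohort(
            1,
            2,
            SimulationConfig(seed=9),
            seed=9,
            states=("upright_baseline",),
            counted_states=("upright_baseline",),
        )
        # same subject, both rounds: identical heart rate means identical
        # median beat interval (jitter differs per recording)
        def median_interval(rec):
            return np.median(np.diff(rec.ground_truth.peak_samples))

        assert abs(median_interval(recs[0]) - median_interval(recs[1])) < 6

    def test_recording_streams_are_order_independent(self):
        full = simulate_cohort(2, 1, SimulationConfig(seed=5), seed=5)
        sub = simulate_cohort(
            2,
            1,
            SimulationConfig(seed=5),
            seed=5,
            states=("head_down_tilt",),
            counted_states=("head_down_tilt",),
        )
        full_tilt = {
            r.recording_id: r for r in full if r.state == "head_down_tilt"
        }
        for r in sub:
            assert np.array_equal(
                r.trace.samples, full_tilt[r.recording_id].trace.samples
            )
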