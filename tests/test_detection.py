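"""Synthetic video, ROI integration, burst detection, window cropping."""

import numpy as np
import pytest

import liftgate as lg
from liftgate.detection import (
    FluorescenceTrace,
    OpticsConfig,
    SyntheticVideoSpec,
    crop_windows,
    detect_events,
    generate_video,
    integrate_roi,
    match_events,
)


def quiet_spec(**kw):
    defaults = dict(duration_s=0.25, n_particles=0, noise_model="none",
                    background_level=2.0, rng_seed=0)
    defaults.update(kw)
    return SyntheticVideoSpec(**defaults)


class TestGenerateVideo:
    def test_no_particles_no_noise_is_flat_background(self):
        frames, truth = generate_video(quiet_spec())
        assert truth == []
        assert np.all(frames == 2.0)

    def test_single_particle_peaks_at_its_transit_frame(self):
        t0 = 0.123
        frames, _ = generate_video(
            quiet_spec(n_particles=1, transit_times_s=(t0,))
        )
        trace = integrate_roi(frames)
        assert abs(trace.t_s[int(np.argmax(trace.intensity))] - t0) <= 1 / 2000.0

    def test_same_seed_is_bitwise_reproducible(self):
        spec = SyntheticVideoSpec(duration_s=0.25, n_particles=5, rng_seed=11)
        a, ta = generate_video(spec)
        b, tb = generate_video(spec)
        assert np.array_equal(a, b) and ta == tb

    def test_window_longer_than_acquisition_is_infeasible(self):
        with pytest.raises(ValueError, match="window"):
            generate_video(quiet_spec(duration_s=0.004))

    def test_transit_times_must_fit_duration(self):
        with pytest.raises(ValueError):
            SyntheticVideoSpec(duration_s=0.25, n_particles=1,
                               transit_times_s=(0.9,))


class TestIntegrateRoi:
    def test_ones_frame_sums_to_roi_area(self):
        frames = np.ones((3, 32, 32))
        optics = OpticsConfig(roi=(4, 6, 10, 10))
        trace = integrate_roi(frames, optics)
        assert np.all(trace.intensity == 100.0)

    def test_zero_frames_give_zero_trace(self):
        trace = integrate_roi(np.zeros((5, 16, 16)), OpticsConfig(roi=(0, 0, 16, 16)))
        assert np.all(trace.intensity == 0.0)

    def test_matches_naive_double_loop_sum(self, rng):
        frames = rng.uniform(0, 100, size=(7, 20, 24))
        optics = OpticsConfig(roi=(3, 5, 9, 11))
        trace = integrate_roi(frames, optics)
        x, y, w, h = optics.roi
        for i in range(7):
            total = 0.0
            for r in range(y, y + h):
                for c in range(x, x + w):
                    total += frames[i, r, c]
            assert trace.intensity[i] == pytest.approx(total, rel=1e-12)

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            integrate_roi(np.zeros((2, 8, 8)), OpticsConfig(roi=(0, 0, 16, 16)))

    def test_linearity_in_the_frames(self, rng):
        f1 = rng.uniform(0, 10, size=(6, 32, 32))
        f2 = rng.uniform(0, 10, size=(6, 32, 32))
        optics = OpticsConfig()
        combined = integrate_roi(2.0 * f1 + 3.0 * f2, optics).intensity
        separate = 2.0 * integrate_roi(f1, optics).intensity + 3.0 * integrate_roi(f2, optics).intensity
        assert combined == pytest.approx(separate, rel=1e-12)

    def test_text_round_trip(self):
        trace = integrate_roi(np.ones((4, 8, 8)), OpticsConfig(roi=(0, 0, 8, 8)))
        again = FluorescenceTrace.from_text(trace.to_text())
        assert again.intensity == pytest.approx(trace.intensity)
        assert again.frame_rate_hz == pytest.approx(trace.frame_rate_hz)


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        trace = FluorescenceTrace(np.arange(100) / 2000.0, np.zeros(100), 2000.0)
        assert detect_events(trace) == []

    def test_single_injected_peak_is_found_at_its_frame(self, rng):
        y = rng.normal(100.0, 1.0, size=500)
        y[250] += 50.0
        trace = FluorescenceTrace(np.arange(500) / 2000.0, y, 2000.0)
        events = detect_events(trace, threshold_k=5.0)
        assert [e.frame_index for e in events] == [250]
        assert events[0].snr > 5.0

    def test_offset_invariance(self, rng):
        y = rng.normal(0.0, 1.0, size=1000)
        y[[200, 600]] += 30.0
        t = np.arange(1000) / 2000.0
        base = detect_events(FluorescenceTrace(t, y, 2000.0))
        shifted = detect_events(FluorescenceTrace(t, y + 5000.0, 2000.0))
        assert [e.frame_index for e in base] == [e.frame_index for e in shifted]

    def test_event_count_monotone_in_threshold(self, benchmark_video):
        frames, _, optics = benchmark_video
        trace = integrate_roi(frames, optics)
        counts = [len(detect_events(trace, k, optics=optics))
                  for k in (2.0, 3.5, 5.0, 8.0, 12.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_high_snr_benchmark_recall_and_precision(self, benchmark_video):
        """100 particles at >=10x noise amplitude: essentially every event
        is recovered and no spurious ones are called."""
        frames, truth, optics = benchmark_video
        trace = integrate_roi(frames, optics)
        events = detect_events(trace, threshold_k=5.0, optics=optics)
        window_s = optics.event_window_ms / 1000.0
        matched, fp, missed = match_events(events, truth, tolerance_s=window_s)
        assert matched / len(truth) >= 0.95          # recall
        assert matched / len(events) >= 0.95         # precision

    def test_trace_shorter_than_window_rejected(self):
        trace = FluorescenceTrace(np.arange(4) / 2000.0, np.zeros(4), 2000.0)
        with pytest.raises(ValueError, match="window"):
            detect_events(trace)


class TestCropWindows:
    def test_window_spans_window_frames(self):
        optics = OpticsConfig(frame_rate_hz=2000.0, event_window_ms=5.0)
        assert optics.window_frames == 10
        y = np.zeros(200)
        y[100] = 100.0
        trace = FluorescenceTrace(np.arange(200) / 2000.0, y, 2000.0)
        events = detect_events(trace, optics=optics)
        (segment,) = crop_windows(trace, events, optics)
        assert len(segment) == 10
        assert segment.t_s[0] == pytest.approx(trace.t_s[95])

    def test_event_at_trace_edge_is_truncated_and_flagged(self):
        y = np.zeros(50)
        y[1] = 100.0
        trace = FluorescenceTrace(np.arange(50) / 2000.0, y, 2000.0)
        (event,) = detect_events(trace)
        assert event.window.truncated
        (segment,) = crop_windows(trace, [event])
        assert len(segment) < OpticsConfig().window_frames

    def test_default_window_is_five_milliseconds(self):
        assert OpticsConfig().event_window_ms == 5.0
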