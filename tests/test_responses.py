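"""Response-analysis pipeline: ROI extraction, dF/F0, photobleach correction
and excitatory-response calling."""

import numpy as np
import pytest

from olfact import (
    GlomerulusROI,
    MovieStack,
    Odor,
    StimulusEvent,
    analyze_movie,
    bleach_correct,
    compute_dff,
    count_responsive,
    detect_response,
    extract_traces,
    generate_movie,
    segment_dff,
)
from olfact.exceptions import ValidationError
from olfact.simulate import GlomerulusGT, make_schedule

FIELD = (96, 96)


def glom(gid, x, y, amplitudes=None, baseline=100.0):
    return GlomerulusGT(id=gid, center_um=(x, y), baseline=baseline,
                        amplitudes=amplitudes or {})


def small_movie(layout, **kwargs):
    defaults = dict(noise_sd=0.0, bleach_rate=0.0, n_trials=2,
                    field_shape=FIELD, seed=0)
    defaults.update(kwargs)
    return generate_movie(layout, **defaults)


class TestExtractTraces:
    def test_uniform_frames_give_constant_traces(self):
        stimuli, total = make_schedule(n_trials=1)
        frames = np.full((total, 64, 64), 7.0, dtype=np.float64)
        movie = MovieStack(frames=frames, frame_rate=2.0, pixel_size_um=5.0,
                           stimuli=stimuli)
        traces = extract_traces(movie, [GlomerulusROI("r0", (160, 160))])
        assert np.all(traces.raw == 7.0)

    def test_trace_equals_forward_model_roi_mean(self):
        g = glom("g0", 240, 240, {Odor.TNT_MIX: 0.3})
        movie = small_movie([g])
        traces = extract_traces(movie, [GlomerulusROI("g0", (240, 240))])
        # the ROI footprint coincides with the glomerulus, so the mean over the
        # ROI is exactly the planted per-pixel time course
        from olfact.simulate import circle_mask

        mask = circle_mask(FIELD, (48, 48), 10)
        expected = movie.frames[:, mask].mean(axis=1)
        np.testing.assert_allclose(traces.raw[0], expected, atol=1e-9)

    def test_roi_outside_frame_names_roi(self):
        movie = small_movie([glom("g0", 240, 240)])
        with pytest.raises(ValidationError, match="edge"):
            extract_traces(movie, [GlomerulusROI("edge", (20, 240))])

    def test_overlapping_rois_warn(self):
        movie = small_movie([glom("g0", 240, 240)])
        rois = [GlomerulusROI("a", (240, 240)), GlomerulusROI("b", (290, 240))]
        with pytest.warns(UserWarning, match="overlap"):
            extract_traces(movie, rois)


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        ev = StimulusEvent(Odor.TNT_MIX, 30, 20, 0)
        dff, f0 = compute_dff(np.full(80, 5.0), ev)
        assert f0 == 5.0
        assert np.all(dff == 0.0)

    def test_fifty_percent_step(self):
        ev = StimulusEvent(Odor.TNT_MIX, 30, 20, 0)
        trace = np.full(80, 2.0)
        trace[30:50] = 3.0
        dff, _ = compute_dff(trace, ev)
        assert np.all(dff[30:50] == pytest.approx(0.5))

    def test_nonpositive_f0_rejected(self):
        ev = StimulusEvent(Odor.TNT_MIX, 30, 20, 0)
        with pytest.raises(ValidationError, match="F0"):
            compute_dff(np.zeros(80), ev)

    def test_baseline_window_must_fit(self):
        ev = StimulusEvent(Odor.TNT_MIX, 10, 20, 0)
        with pytest.raises(ValidationError, match="baseline"):
            compute_dff(np.ones(80), ev)

    def test_gain_invariance(self):
        """dF/F of an affine-gain-rescaled movie is unchanged."""
        g = glom("g0", 240, 240, {Odor.IVO: 0.4})
        movie = small_movie([g], bleach_rate=0.002)
        roi = [GlomerulusROI("g0", (240, 240))]
        t1 = segment_dff(extract_traces(movie, roi), movie.stimuli)
        movie.frames = movie.frames * 3.7
        t2 = segment_dff(extract_traces(movie, roi), movie.stimuli)
        for odor in t1.segments:
            np.testing.assert_allclose(t1.segments[odor], t2.segments[odor],
                                       atol=1e-12)


class TestDetectResponse:
    def test_no_change_is_nonresponsive_with_unit_p(self):
        trials = np.zeros((5, 40))
        call = detect_response(trials)
        assert call.p_value == 1.0
        assert not call.responsive

    def test_strong_planted_response_detected(self):
        rng = np.random.default_rng(0)
        trials = rng.normal(0, 0.02, size=(5, 40))
        trials[:, 20:] += 0.5
        call = detect_response(trials)
        assert call.responsive and call.p_value < 1e-4
        assert call.magnitude == pytest.approx(0.5, abs=0.05)

    def test_decrease_never_called(self):
        rng = np.random.default_rng(1)
        trials = rng.normal(0, 0.02, size=(5, 40))
        trials[:, 20:] -= 0.5  # inhibition: one-sided test must not fire
        assert not detect_response(trials).responsive

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValidationError, match="2 trials"):
            detect_response(np.zeros((1, 40)))

    def test_type_one_error_near_alpha_under_null(self):
        rng = np.random.default_rng(123)
        n_rois, alpha = 1000, 0.05
        hits = sum(
            detect_response(rng.normal(0, 0.05, size=(5, 40)), alpha=alpha).responsive
            for _ in range(n_rois)
        )
        assert abs(hits / n_rois - alpha) <= 0.02

    def test_wilcoxon_flag(self):
        rng = np.random.default_rng(3)
        trials = rng.normal(0, 0.02, size=(6, 40))
        trials[:, 20:] += 0.5
        assert detect_response(trials, use_wilcoxon=True).responsive


class TestBleachCorrect:
    def test_pure_bleach_residual_small(self):
        layout = [glom(f"g{i}", 100 + 125 * (i % 3), 100 + 125 * (i // 3))
                  for i in range(6)]
        movie = small_movie(layout, bleach_rate=0.01, noise_sd=0.5, seed=7)
        rois = [GlomerulusROI(g.id, g.center_um) for g in layout]
        traces = segment_dff(extract_traces(movie, rois), movie.stimuli)
        corrected, reference = bleach_correct(traces)
        assert set(reference) == {g.id for g in layout}
        for segs in corrected.segments.values():
            window_means = segs.mean(axis=2)
            assert np.all(np.abs(window_means) < 0.01)

    def test_responder_amplitude_preserved(self):
        amp = 0.5
        layout = [glom("resp", 100, 100, {Odor.TNT_MIX: amp})] + [
            glom(f"g{i}", 100 + 125 * ((i + 1) % 3), 100 + 125 * ((i + 1) // 3))
            for i in range(5)
        ]
        movie = small_movie(layout, bleach_rate=0.002, n_trials=3)
        rois = [GlomerulusROI(g.id, g.center_um) for g in layout]
        calls, traces = analyze_movie(movie, rois)
        resp = next(c for c in calls
                    if c.roi_id == "resp" and c.odor is Odor.TNT_MIX)
        assert resp.responsive
        assert resp.magnitude == pytest.approx(amp, rel=0.02)
        assert "resp" not in traces.reference_rois

    def test_no_bleach_correction_changes_little(self):
        layout = [glom("r0", 100, 100, {Odor.IVO: 0.4})] + [
            glom(f"g{i}", 350, 100 + 125 * i) for i in range(3)
        ]
        movie = small_movie(layout, noise_sd=0.5, seed=2, n_trials=3)
        rois = [GlomerulusROI(g.id, g.center_um) for g in layout]
        raw = segment_dff(extract_traces(movie, rois), movie.stimuli)
        corrected, _ = bleach_correct(raw)
        for odor in raw.segments:
            diff = np.abs(corrected.segments[odor] - raw.segments[odor])
            assert diff.max() < 0.05  # noise / sqrt(n_reference) scale

    def test_all_responders_skips_with_warning(self):
        layout = [glom("a", 100, 100, {Odor.TNT_MIX: 0.5, Odor.IVO: 0.5}),
                  glom("b", 250, 100, {Odor.TNT_MIX: 0.5, Odor.IVO: 0.5})]
        movie = small_movie(layout)
        rois = [GlomerulusROI(g.id, g.center_um) for g in layout]
        traces = segment_dff(extract_traces(movie, rois), movie.stimuli)
        with pytest.warns(UserWarning, match="skipped"):
            corrected, reference = bleach_correct(traces)
        assert reference == ()


class TestEndToEnd:
    def test_noiseless_pipeline_exact_detection_and_amplitudes(self):
        planted = {
            "t0": {Odor.TNT_MIX: 0.3}, "t1": {Odor.TNT_MIX: 0.6},
            "i0": {Odor.IVO: 0.5}, "b0": {}, "b1": {},
        }
        layout = [glom(gid, 100 + 125 * (k % 3), 100 + 125 * (k // 3), amps)
                  for k, (gid, amps) in enumerate(planted.items())]
        # mild bleaching (~12% over a 10-min session); the subtractive
        # correction's second-order residual amp*rate*dt stays below 1e-3
        movie = small_movie(layout, bleach_rate=2e-4, n_trials=5)
        rois = [GlomerulusROI(g.id, g.center_um) for g in layout]
        calls, _ = analyze_movie(movie, rois)
        detected = {(c.roi_id, c.odor) for c in calls if c.responsive}
        expected = {(gid, o) for gid, amps in planted.items() for o in amps}
        assert detected == expected
        for c in calls:
            if (c.roi_id, c.odor) in expected:
                assert c.magnitude == pytest.approx(
                    planted[c.roi_id][c.odor], abs=1e-3
                )

    def test_count_responsive_conservation(self):
        layout = [glom("a", 100, 100, {Odor.TNT_MIX: 0.4}),
                  glom("b", 250, 100, {Odor.IVO: 0.4}),
                  glom("c", 400, 100)]
        movie = small_movie(layout, n_trials=3)
        rois = [GlomerulusROI(g.id, g.center_um) for g in layout]
        calls, _ = analyze_movie(movie, rois)
        counts, magnitudes = count_responsive(calls)
        assert counts == {Odor.TNT_MIX: 1, Odor.IVO: 1}
        assert sum(counts.values()) == sum(
            1 for c in calls if c.responsive
        )
        assert len(magnitudes[Odor.TNT_MIX]) == 1

    def test_zero_calls_zero_counts(self):
        counts, magnitudes = count_responsive([])
        assert counts == {} and magnitudes == {}
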