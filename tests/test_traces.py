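"""Trace pipeline: dF/F, smoothing, detection, permutation, sharpening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from obcode.synth import SynthConfig, generate_session_pair
from obcode.traces import (
    ImagingSession,
    baseline_shift,
    classify_pairs,
    compare_before_after,
    compute_dff,
    detect_response,
    estimate_sharpening,
    permutation_pvalues,
    response_magnitude,
    session_tuning,
    smooth_trace,
    tuning_summary,
)


def _session_from_raw(raw, frame_rate=7.0, onset=42, background=None):
    return ImagingSession(raw, frame_rate, onset, background=background)


def _flat_session(value=10.0, n_frames=112):
    raw = np.full((1, 1, 1, n_frames), value)
    return _session_from_raw(raw)


class TestDff:
    def test_constant_trace_gives_zero(self):
        dff = compute_dff(_flat_session())
        np.testing.assert_array_equal(dff, 0.0)

    def test_direct_arithmetic(self):
        raw = np.full((1, 1, 1, 112), 10.0)
        raw[0, 0, 0, 60] = 15.0
        dff = compute_dff(_session_from_raw(raw))
        assert dff[0, 0, 0, 60] == pytest.approx(0.5)

    def test_generator_round_trip(self, noiseless_pair):
        cfg, before, _, truth = noiseless_pair
        dff = compute_dff(before)
        expected = (truth.sign * truth.amp_before)[:, :, None, None] * truth.kernel
        np.testing.assert_allclose(dff, np.broadcast_to(expected, dff.shape), atol=1e-9)

    def test_scale_invariance(self, noiseless_pair):
        _, before, _, _ = noiseless_pair
        scaled = ImagingSession(
            before.fluorescence * 3.7, before.frame_rate, before.onset_frame
        )
        np.testing.assert_allclose(compute_dff(scaled), compute_dff(before), atol=1e-12)

    def test_nonpositive_f0_names_offender(self):
        raw = np.full((2, 1, 1, 112), 10.0)
        raw[1, 0, 0, :40] = -5.0
        with pytest.raises(ValueError, match="cell001"):
            compute_dff(_session_from_raw(raw))


class TestSmooth:
    def test_constant_fixed_point(self):
        x = np.full(20, 3.3)
        np.testing.assert_allclose(smooth_trace(x), x)

    def test_impulse_shrinking_windows(self):
        x = np.zeros(9)
        x[4] = 1.0  # index 5, 1-based
        expected = [0, 0, 0.2, 0.2, 0.2, 0.2, 0.2, 0, 0]
        np.testing.assert_allclose(smooth_trace(x, span=5), expected)

    def test_linear_ramp_unchanged(self):
        x = np.linspace(-2, 5, 30)
        np.testing.assert_allclose(smooth_trace(x), x, atol=1e-12)

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(5), span=4)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mean_preserved_and_length(self, vals):
        x = np.array(vals)
        y = smooth_trace(x)
        assert len(y) == len(x)
        assert np.isfinite(y).all()


class TestDetect:
    def test_flat_zero_trace(self):
        trace = np.zeros(112)
        call = detect_response(trace, 7.0, 42)
        assert call.effect_size == 0.0 and call.sign == "none"
        assert not call.significant

    def test_effect_size_formula_threshold(self):
        # response sample mean 5 sd 1, baseline sample mean 1 sd 1 -> ES 4
        resp = np.array([5 - 1.2, 5, 5 + 1.2, 5, 5 - 1.2, 5, 5 + 1.2])
        base = resp - 4.0
        sd = resp.std(ddof=1)
        es = (resp.mean() - base.mean()) / (0.5 * (sd + sd))
        assert es == pytest.approx(4.0 / sd)
        # zero variance in both samples -> degenerate infinite effect size
        trace = np.zeros(112)
        trace[30:] = 0.1  # plateau spans the whole extremum neighborhood
        call = detect_response(trace, 7.0, 42)
        assert call.degenerate and math.isinf(call.effect_size)

    def test_noiseless_excited_pair_detected(self):
        cfg = SynthConfig(n_cells=2, n_odors=2, seed=5, noise_sd=0.002,
                          p_excited=1.0, p_suppressed=0.0)
        before, _, truth = generate_session_pair(cfg)
        from obcode.traces import analyze_session

        calls = analyze_session(before)
        on = before.onset_frame
        for row in calls:
            for call in row:
                assert call.significant and call.sign == "excited"
                assert on <= call.extremum_frame < on + int(4 * cfg.frame_rate)

    def test_affine_invariance_of_effect_size(self, noiseless_pair):
        cfg, before, _, _ = noiseless_pair
        from obcode.traces import compute_dff, mean_smoothed_trace

        trace = mean_smoothed_trace(compute_dff(before))[0, 0]
        base = detect_response(trace, cfg.frame_rate, before.onset_frame)
        shifted = detect_response(trace + 0.7, cfg.frame_rate, before.onset_frame)
        scaled = detect_response(trace * 4.2, cfg.frame_rate, before.onset_frame)
        assert shifted.effect_size == pytest.approx(base.effect_size, rel=1e-9)
        assert scaled.effect_size == pytest.approx(base.effect_size, rel=1e-9)

    def test_suppressed_mirror_has_negative_magnitude(self):
        trace = np.zeros(112)
        trace[42:77] = 0.3
        pos = response_magnitude(trace, 7.0, 42)
        neg = response_magnitude(-trace, 7.0, 42)
        assert pos == pytest.approx(2.5 * 0.3 / 0.5)  # 0.3 over 5 s
        assert neg == -pos


class TestMagnitude:
    def test_rectangle_area(self):
        trace = np.zeros(112)
        trace[42: 42 + 35] = 0.5
        assert response_magnitude(trace, 7.0, 42) == pytest.approx(2.5)

    def test_zero_trace(self):
        assert response_magnitude(np.zeros(112), 7.0, 42) == 0.0


class TestPermutation:
    def test_identical_samples_p_one(self):
        assert compare_before_after([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_fully_separated_samples(self):
        p = compare_before_after([0, 0, 0, 0, 0], [1, 1, 1, 1, 1])
        assert p == pytest.approx(2 / 252)

    def test_symmetry_in_samples(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert compare_before_after(a, b) == compare_before_after(b, a)

    def test_pvalues_are_multiples_of_1_over_252(self, rng):
        for _ in range(20):
            p = compare_before_after(rng.normal(size=5), rng.normal(size=5))
            assert (p * 252) == pytest.approx(round(p * 252), abs=1e-9)

    def test_null_calibration(self, rng):
        """Exchangeable data rejects at <= 7% at alpha = 0.05 (10k pairs)."""
        before = rng.normal(size=(10000, 5))
        after = rng.normal(size=(10000, 5))
        pvals = permutation_pvalues(before, after)
        assert (pvals < 0.05).mean() <= 0.07

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            compare_before_after([1.0], [1, 2, 3, 4, 5])


class TestClassifyPairs:
    def test_null_pair_pools_stable(self, null_pair):
        cfg, before, after, _ = null_pair
        paired, pools = classify_pairs(before, after)
        for pr in pools["excited"] + pools["suppressed"]:
            assert pr.call_before.significant or pr.call_after.significant
        with_p = [pr for pr in paired if pr.perm_p is not None]
        assert with_p, "null session should still contain significant responses"
        changed = np.mean([pr.changed for pr in with_p])
        assert changed <= 0.07

    def test_quench_shifts_magnitudes_toward_zero(self, noiseless_pair):
        cfg, before, after, _ = noiseless_pair
        _, pools = classify_pairs(before, after)
        exc = [pr.delta_magnitude for pr in pools["excited"]]
        sup = [pr.delta_magnitude for pr in pools["suppressed"]]
        assert np.mean(exc) < 0
        assert np.mean(sup) > 0

    def test_responsiveness_partition(self, null_pair):
        from obcode.traces import analyze_session, responsiveness

        cfg, before, _, _ = null_pair
        counts = responsiveness(analyze_session(before))
        assert len(counts) == cfg.n_cells
        assert np.all((0 <= counts) & (counts <= cfg.n_odors))

    def test_mismatched_sessions_rejected(self, null_pair):
        _, before, _, _ = null_pair
        other = SynthConfig(n_cells=3, n_odors=5, seed=1)
        b2, _, _ = generate_session_pair(other)
        with pytest.raises(ValueError):
            classify_pairs(before, b2)


class TestSharpening:
    def test_identity(self, null_pair):
        _, before, _, _ = null_pair
        s = session_tuning(before)
        est = estimate_sharpening(s, s)
        assert est.sharpening == 1.0
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_quench_recovers_inverse_factor(self, noiseless_pair):
        cfg, before, after, _ = noiseless_pair
        est = estimate_sharpening(session_tuning(before), session_tuning(after))
        assert est.sharpening == pytest.approx(1 / cfg.quench_factor, rel=1e-9)
        assert est.ci_low <= est.sharpening <= est.ci_high

    def test_zero_sem_degenerate_bounds(self):
        mags = np.tile([1.0, 2.0, 3.0], (4, 1))  # identical cells -> SEM 0
        s = tuning_summary(mags)
        est = estimate_sharpening(s, s)
        assert est.ci_low == est.ci_high == est.sharpening == 1.0

    def test_ranked_curves_non_increasing(self, noiseless_pair):
        _, before, _, _ = noiseless_pair
        s = session_tuning(before)
        assert (np.diff(s.ranked, axis=1) <= 1e-12).all()


class TestBaselineShift:
    def test_identical_sessions_zero_shift(self, null_pair):
        _, before, _, _ = null_pair
        shift, flagged = baseline_shift(before, before)
        np.testing.assert_allclose(shift, 0.0)

    def test_generator_round_trip(self):
        cfg = SynthConfig(n_cells=6, n_odors=3, seed=4, noise_sd=0.0,
                          baseline_shift=0.05)
        before, after, truth = generate_session_pair(cfg)
        shift, _ = baseline_shift(before, after)
        expected = 0.05 * truth.f0 / truth.background_level
        np.testing.assert_allclose(shift, expected, atol=1e-6)

    def test_null_shift_not_significant(self):
        """Shuffled-condition baselines should rarely look shifted."""
        from scipy import stats

        hits = 0
        for seed in range(100):
            cfg = SynthConfig(n_cells=10, n_odors=3, n_trials=2, seed=seed,
                              noise_sd=0.05, quench_factor=1.0)
            before, after, _ = generate_session_pair(cfg)
            shift, _ = baseline_shift(before, after)
            if stats.ttest_1samp(shift, 0.0).pvalue < 0.05:
                hits += 1
        assert hits <= 7
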