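"""Smoothing, velocity estimation, noise calibration and segmentation."""

from dataclasses import replace

import numpy as np
import pytest

from ribostall import (NoiseEstimate, Trace, analyze_trace,
                       estimate_sigma_pause, instantaneous_velocity, segment,
                       simulate_trace, smooth, summarize_trace, true_velocity)
from ribostall.signal import Segment, _sg_apply


def sg_coeffs_normal_equations(span: int, polyorder: int, deriv: int = 0,
                               delta: float = 1.0) -> np.ndarray:
    """SG coefficients from first principles (least-squares normal equations)."""
    m = span // 2
    i = np.arange(-m, m + 1)
    a = np.vander(i, polyorder + 1, increasing=True)
    pinv = np.linalg.solve(a.T @ a, a.T)
    from math import factorial
    return pinv[deriv] * factorial(deriv) / delta ** deriv


def make_trace(extension, force=4.0, baseline_end=1.0, rate=1000.0):
    times = np.arange(len(extension)) / rate
    return Trace(times=times, extension=np.asarray(extension, float),
                 force=force, baseline_end=baseline_end)


class TestSmooth:
    def test_constant_preserved(self):
        tr = make_trace(np.full(5000, 7.5))
        out = smooth(tr, span=401)
        assert np.allclose(out[200:-200], 7.5)

    def test_linear_ramp_preserved(self):
        tr = make_trace(3.0 - 0.5 * np.arange(5000) / 1000.0)
        out = smooth(tr, span=401)
        np.testing.assert_allclose(out[200:-200], tr.extension[200:-200],
                                   atol=1e-10)

    def test_matches_direct_convolution_oracle(self):
        """FFT-applied SG equals brute-force convolution with coefficients
        computed from the least-squares normal equations."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        tr = make_trace(100 + np.cumsum(x) * 0.01)
        for deriv in (0, 1):
            coeffs = sg_coeffs_normal_equations(601, 2, deriv, 1e-3)
            direct = np.convolve(tr.extension, coeffs[::-1], mode="same")
            mine = _sg_apply(tr.extension, 601, 2, deriv, 1e-3)
            np.testing.assert_allclose(mine[300:-300], direct[300:-300],
                                       rtol=1e-9, atol=1e-9)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20_000)
        tr = make_trace(x)
        coeffs = sg_coeffs_normal_equations(401, 2)
        expected_sd = np.sqrt(np.sum(coeffs ** 2))
        out = smooth(tr, span=401)
        assert np.std(out[200:-200]) == pytest.approx(expected_sd, rel=0.1)

    def test_span_longer_than_series_rejected(self):
        tr = make_trace(np.zeros(100), baseline_end=0.01)
        with pytest.raises(ValueError, match="span"):
            smooth(tr, span=401)

    def test_even_span_widened_to_odd(self):
        tr = make_trace(np.arange(2000.0))
        assert np.isnan(smooth(tr, span=400)[:200]).all()


class TestInstantaneousVelocity:
    def test_ramp_gives_one_codon_per_second(self, model):
        force = 6.0
        slope = model.extension_per_codon(force)  # nm/s for 1 codon/s
        tr = make_trace(500 - slope * np.arange(20_000) / 1000.0, force=force)
        vel = instantaneous_velocity(tr, model, span=2001)
        assert np.allclose(vel.velocity, 1.0, atol=1e-8)

    def test_constant_extension_zero_velocity(self, model):
        tr = make_trace(np.full(20_000, 50.0))
        vel = instantaneous_velocity(tr, model, span=2001)
        assert np.allclose(vel.velocity, 0.0, atol=1e-9)

    def test_sign_convention_translation_positive(self, model):
        tr = make_trace(100 - 0.3 * np.arange(10_000) / 1000.0)
        vel = instantaneous_velocity(tr, model, span=1001)
        assert np.all(vel.velocity > 0)

    def test_noiseless_trace_matches_truth_rate(self, model, params):
        p = replace(params, k_pause_in=0.0, noise_sd=0.0,
                    baseline_duration=10.0, mrna_codons=1000)
        trace, truth = simulate_trace(p, 4.0, 3)
        vel = instantaneous_velocity(trace, model)
        sel = vel.times > p.baseline_duration
        measured = np.mean(vel.velocity[sel])
        t_lo, t_hi = vel.times[sel][0], vel.times[sel][-1]
        realized = np.sum((truth.step_times > t_lo)
                          & (truth.step_times <= t_hi)) / (t_hi - t_lo)
        assert measured == pytest.approx(realized, rel=0.02)

    def test_tiny_window_rejected(self, model):
        tr = make_trace(np.zeros(1000), baseline_end=0.01)
        with pytest.raises(ValueError):
            instantaneous_velocity(tr, model, span=1)


class TestSigmaPause:
    def test_matches_recomputed_velocity_sd(self, model, fast_params):
        trace, _ = simulate_trace(replace(fast_params, v0=0.0), 4.0, 9)
        vel = instantaneous_velocity(trace, model)
        est = estimate_sigma_pause(vel, trace)
        coeffs = sg_coeffs_normal_equations(4001, 2, 1, trace.dt)
        dxdt = np.convolve(trace.extension, coeffs[::-1], mode="same")
        v = -dxdt / model.extension_per_codon(trace.force)
        guard = 2000
        mask = trace.times <= trace.baseline_end - guard * trace.dt
        mask[:guard] = False
        assert est.sigma_pause == pytest.approx(np.std(v[mask], ddof=1),
                                                rel=1e-6)

    def test_scales_with_noise_sd(self, model, fast_params):
        sigmas = []
        for sd in (1.0, 2.0):
            trace, _ = simulate_trace(replace(fast_params, noise_sd=sd),
                                      4.0, 21)
            vel = instantaneous_velocity(trace, model)
            sigmas.append(estimate_sigma_pause(vel, trace).sigma_pause)
        assert sigmas[1] / sigmas[0] == pytest.approx(2.0, rel=0.15)

    def test_zero_noise_baseline_degenerate(self, model, fast_params):
        trace, _ = simulate_trace(replace(fast_params, noise_sd=0.0), 4.0, 2)
        vel = instantaneous_velocity(trace, model)
        with pytest.raises(ValueError, match="supply"):
            estimate_sigma_pause(vel, trace)

    def test_short_baseline_rejected(self, model, fast_params):
        p = replace(fast_params, baseline_duration=3.0)
        trace, _ = simulate_trace(p, 4.0, 2)
        vel = instantaneous_velocity(trace, model)
        with pytest.raises(ValueError):
            estimate_sigma_pause(vel, trace)


class TestSegmentation:
    def _chain(self, trace, model, sigma=None, **kw):
        sm = smooth(trace, span=kw.get("span", 4000))
        vel = instantaneous_velocity(trace, model, span=kw.get("span", 4000))
        noise = (NoiseEstimate(sigma, 0) if sigma is not None
                 else estimate_sigma_pause(vel, trace))
        return segment(vel, noise, sm, trace, model,
                       multiplier=kw.get("multiplier", 2.5),
                       min_segment=kw.get("min_segment", 0.5))

    def test_flat_trace_single_pause(self, model):
        tr = make_trace(np.full(30_000, 80.0), baseline_end=5.0)
        segs = self._chain(tr, model, sigma=0.05)
        assert len(segs) == 1
        assert segs[0].label == "pause"
        assert segs[0].censored

    def test_steady_ramp_single_burst(self, model):
        slope = model.extension_per_codon(4.0)  # 1 codon/s
        tr = make_trace(300 - slope * np.arange(60_000) / 1000.0,
                        baseline_end=5.0)
        segs = self._chain(tr, model, sigma=0.05)
        assert len(segs) == 1
        assert segs[0].label == "burst"
        assert segs[0].mean_velocity == pytest.approx(1.0, rel=1e-6)

    def test_partition_is_exact(self, model, params):
        trace, _ = simulate_trace(params, 4.0, 17)
        sm = smooth(trace)
        vel = instantaneous_velocity(trace, model)
        noise = estimate_sigma_pause(vel, trace)
        segs = segment(vel, noise, sm, trace, model)
        total = sum(s.duration for s in segs)
        region = vel.times[vel.times > trace.baseline_end]
        assert total == pytest.approx((len(region) - 1) * trace.dt, abs=1e-9)
        labels = [s.label for s in segs]
        assert all(a != b for a, b in zip(labels, labels[1:]))  # alternation

    def test_distance_conservation(self, model, params):
        trace, _ = simulate_trace(params, 4.0, 17)
        segs = self._chain(trace, model)
        total = sum(s.distance for s in segs)
        ends = (segs[0].start, segs[-1].end)
        sm = smooth(trace)
        i0 = int(round(ends[0] / trace.dt))
        i1 = min(int(round(ends[1] / trace.dt)), len(sm) - 2001)
        expect = (sm[i0] - sm[i1]) / model.extension_per_codon(trace.force)
        assert total == pytest.approx(expect, abs=1e-6)

    def test_offset_invariance(self, model, params):
        trace, _ = simulate_trace(params, 4.0, 29)
        shifted = Trace(times=trace.times, extension=trace.extension + 123.4,
                        force=trace.force, baseline_end=trace.baseline_end)
        a = self._chain(trace, model)
        b = self._chain(shifted, model)
        assert [(s.label, s.start, s.end) for s in a] == \
            [(s.label, s.start, s.end) for s in b]

    def test_detected_pause_count_near_truth(self, model, params):
        """At 4 pN defaults the detected pause count tracks the number of
        true pauses longer than min_segment (tolerance +/-2: threshold
        crossings near the boundaries can split or merge borderline pauses)."""
        trace, truth = simulate_trace(params, 4.0, 1)
        segs = self._chain(trace, model)
        detected = sum(1 for s in segs if s.label == "pause")
        true_long = sum(1 for a, b in truth.pause_intervals if b - a > 0.5)
        assert abs(detected - true_long) <= 2

    def test_min_segment_merging(self, model):
        # 1 codon/s ramp with a 2.9 s stall: the short detected pause run
        # must be merged into the surrounding burst at min_segment = 3 s
        # and survive as its own pause at min_segment = 0.5 s.
        slope = model.extension_per_codon(4.0)
        t = np.arange(60_000) / 1000.0
        moving = np.clip(t, None, 30.0) + np.clip(t - 32.9, 0.0, None)
        x = 300 - slope * moving
        tr = make_trace(x, baseline_end=5.0)
        merged = self._chain(tr, model, sigma=0.05, min_segment=3.0)
        assert len(merged) == 1 and merged[0].label == "burst"
        kept = self._chain(tr, model, sigma=0.05, min_segment=0.5)
        assert sum(1 for s in kept if s.label == "pause") == 1


class TestSummarize:
    def test_arithmetic(self):
        tr = make_trace(np.zeros(10_000))
        segs = [Segment("burst", 1.0, 6.0, 10.0, 2.0, False),
                Segment("pause", 6.0, 9.0, 0.0, 0.0, False)]
        res = summarize_trace(tr, segs)
        assert res.pause_free_velocity == pytest.approx(2.0)
        assert res.total_distance == pytest.approx(10.0)
        assert res.burst_durations == [5.0]
        assert res.pause_durations == [3.0]

    def test_all_pause_flagged_undefined(self):
        tr = make_trace(np.zeros(10_000))
        segs = [Segment("pause", 1.0, 9.0, 0.0, 0.0, True)]
        res = summarize_trace(tr, segs)
        assert not res.velocity_defined

    def test_censored_excluded_from_durations(self):
        tr = make_trace(np.zeros(10_000))
        segs = [Segment("burst", 0.0, 2.0, 4.0, 2.0, True),
                Segment("pause", 2.0, 5.0, 0.0, 0.0, False),
                Segment("burst", 5.0, 9.0, 8.0, 2.0, True)]
        res = summarize_trace(tr, segs)
        assert res.burst_durations == []
        assert res.pause_durations == [3.0]
        # censored bursts still contribute distance and velocity
        assert res.total_distance == pytest.approx(12.0)

    def test_full_chain_deterministic(self, model, params):
        trace, _ = simulate_trace(params, 4.0, 8)
        r1, s1 = analyze_trace(trace, model)
        r2, s2 = analyze_trace(trace, model)
        assert r1 == r2
        assert s1 == s2
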