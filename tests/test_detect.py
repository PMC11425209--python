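"""Detrending, noise estimation, event detection and rectangle fitting."""

import numpy as np
import pytest

from wgmdyn.config import KineticScheme
from wgmdyn.detect import (
    DetectionResult,
    Event,
    analyze_trace,
    detect_events,
    detrend,
    dwell_times,
    estimate_noise_sigma,
    fit_rectangle,
    match_events,
)
from wgmdyn.simulate import simulate_trace
from wgmdyn.trace import TimeTrace

FS = 50.0


def make_trace(dlambda, fwhm=None):
    n = len(dlambda)
    if fwhm is None:
        fwhm = np.full(n, 1e-13)
    return TimeTrace(t=np.arange(n) / FS, dlambda=np.asarray(dlambda, float), fwhm=fwhm)


class TestDetrend:
    def test_constant_trace_detrends_to_zero(self):
        out = detrend(make_trace(np.full(500, 2e-15)), window=101)
        np.testing.assert_allclose(out.dlambda, 0.0, atol=1e-28)

    def test_linear_ramp_is_removed(self):
        ramp = np.linspace(0, 1e-12, 500)
        out = detrend(make_trace(ramp), window=101)
        np.testing.assert_allclose(out.dlambda, 0.0, atol=1e-24)

    def test_short_rectangle_survives_on_a_ramp(self):
        # tau (10 samples) much shorter than the window (101 samples)
        ramp = np.linspace(0, 1e-12, 1000)
        y = ramp.copy()
        y[500:510] += 5e-15
        out = detrend(make_trace(y), window=101)
        recovered = out.dlambda[500:510].mean()
        assert recovered == pytest.approx(5e-15, rel=0.10)

    @pytest.mark.parametrize("window", [4, 2001])
    def test_rejects_bad_window(self, window):
        with pytest.raises(ValueError):
            detrend(make_trace(np.zeros(100)), window=window)

    def test_fwhm_channel_passes_through(self):
        f = np.linspace(1e-13, 2e-13, 200)
        out = detrend(make_trace(np.zeros(200), fwhm=f), window=51)
        np.testing.assert_array_equal(out.fwhm, f)


class TestNoiseSigma:
    def test_all_zeros(self):
        assert estimate_noise_sigma(make_trace(np.zeros(100))) == 0.0

    def test_gaussian_noise_recovered(self, rng):
        x = rng.normal(0, 0.5e-15, 100_000)
        assert estimate_noise_sigma(make_trace(x)) == pytest.approx(0.5e-15, rel=0.02)

    def test_robust_to_gross_outliers(self, rng):
        # 1% outliers of 20x the noise scale barely move the MAD estimate,
        # while the plain standard deviation (the non-robust oracle) blows up
        x = rng.normal(0, 1.0, 50_000)
        idx = rng.choice(x.size, x.size // 100, replace=False)
        x[idx] += 20.0
        assert estimate_noise_sigma(make_trace(x)) == pytest.approx(1.0, rel=0.05)
        assert np.std(x) > 1.5

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.zeros(5))


class TestFitRectangle:
    def test_noiseless_rectangle_exact(self):
        y = np.zeros(40)
        y[10:20] = 4e-15
        amp, tau, onset = fit_rectangle(make_trace(y))
        assert amp == pytest.approx(4e-15)
        assert tau == pytest.approx(10 / FS)
        assert onset == pytest.approx(10 / FS)

    def test_all_zero_segment_is_an_error(self):
        with pytest.raises(ValueError):
            fit_rectangle(make_trace(np.zeros(20)))

    def test_minimal_two_sample_segment(self):
        amp, tau, onset = fit_rectangle(
            TimeTrace(t=[0.0, 0.02], dlambda=[0.0, 1.0], fwhm=[0.0, 0.0])
        )
        assert amp == pytest.approx(1.0)
        assert tau == pytest.approx(0.02)
        assert onset == pytest.approx(0.02)

    def test_amplitude_unbiased_under_noise(self, rng):
        # A = 5 sigma, 20 in-event samples: the amplitude estimate averages
        # 20 noisy samples, so its error should be ~ sigma/sqrt(20)
        sigma, A, reps = 1.0, 5.0, 400
        errs = []
        for _ in range(reps):
            y = rng.normal(0, sigma, 60)
            y[20:40] += A
            amp, _, _ = fit_rectangle(make_trace(y))
            errs.append(amp - A)
        assert abs(np.mean(errs)) < 2 * sigma / np.sqrt(20) / np.sqrt(reps) * 3

    def test_equals_brute_force_grid_search(self, rng):
        # independent oracle: direct SSE minimisation over all (onset, width)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            y = rng.normal(0, 1.0, n)
            i0, j0 = sorted(rng.choice(n + 1, 2, replace=False))
            if j0 - i0 >= 1:
                y[i0:j0] += 4.0
            best_sse, best = np.inf, None
            for i in range(n):
                for j in range(i + 1, n + 1):
                    a = y[i:j].mean()
                    model = np.zeros(n)
                    model[i:j] = a
                    sse = float(np.sum((y - model) ** 2))
                    if sse < best_sse - 1e-12:
                        best_sse, best = sse, (a, (j - i) / FS, i / FS)
            amp, tau, onset = fit_rectangle(make_trace(y))
            assert amp == pytest.approx(best[0])
            assert tau == pytest.approx(best[1])
            assert onset == pytest.approx(best[2])


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        res = detect_events(make_trace(np.zeros(1000)), sigma=1e-16)
        assert res.events == []

    def test_single_rectangle_detected_and_fitted(self, rng):
        sigma = 1.0
        y = rng.normal(0, sigma, 2000)
        y[1000:1010] += 10 * sigma  # tau = 0.2 s at 50 Hz
        res = detect_events(make_trace(y), sigma=sigma)
        spikes = [e for e in res.events if e.kind == "spike"]
        assert len(spikes) == 1
        assert spikes[0].amplitude == pytest.approx(10 * sigma, rel=0.15)
        assert spikes[0].duration == pytest.approx(0.2, abs=3 / FS)

    def test_fwhm_excursion_vetoes_event(self):
        y = np.zeros(1000)
        y[500:510] = 1e-14
        f = np.full(1000, 1e-13) + np.sin(np.arange(1000)) * 1e-16  # noise floor
        f[500:510] += 5e-14  # linewidth excursion coincident with the shift
        res = detect_events(make_trace(y, fwhm=f), sigma=1e-15)
        assert res.events == []
        assert res.n_rejected_fwhm == 1

    def test_sustained_shift_classified_as_step(self):
        y = np.zeros(1000)
        y[500:] = 5e-15  # never returns to baseline
        res = detect_events(make_trace(y), sigma=0.5e-15)
        assert len(res.events) == 1
        assert res.events[0].kind == "step"

    def test_two_maxima_classified_as_double_peak(self, rng):
        y = rng.normal(0, 0.1, 600)
        y[300:304] += 6.0
        y[304] += 3.5  # dip between the peaks, still above threshold
        y[305:309] += 6.0
        res = detect_events(make_trace(y), sigma=1.0)
        assert len(res.events) == 1
        assert res.events[0].kind == "double_peak"

    def test_frequency_shift_consistent_with_amplitude(self):
        y = np.zeros(100)
        y[50:60] = 3e-15
        res = detect_events(make_trace(y), sigma=1e-16, lambda0=780e-9)
        e = res.events[0]
        c = 299792458.0
        assert e.dnu == pytest.approx(-c * e.amplitude / 780e-9**2)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            detect_events(make_trace(np.zeros(100)), sigma=0.0)


class TestDwellTimes:
    @staticmethod
    def _evt(onset, duration, dwell=None):
        return Event(onset=onset, duration=duration, amplitude=1e-15, dnu=0.0, dwell=dwell)

    def test_arithmetic(self):
        res = DetectionResult(events=[self._evt(1.0, 0.5), self._evt(3.0, 0.5)])
        assert dwell_times(res) == [pytest.approx(1.5)]

    def test_single_event_gives_empty(self):
        res = DetectionResult(events=[self._evt(1.0, 0.5)])
        assert dwell_times(res) == []

    def test_overlap_is_an_error(self):
        res = DetectionResult(events=[self._evt(1.0, 2.0), self._evt(2.0, 0.5)])
        res.events.sort(key=lambda e: e.onset)
        with pytest.raises(ValueError):
            dwell_times(res)

    def test_renewal_trace_recovers_dwell_rate(self, sensor):
        sch = KineticScheme(
            event_rate=0.5, mean_duration=0.2, amp_mean=5e-15, amp_sd=0.5e-15,
            noise_sd=0.5e-15,
        )
        trace, _ = simulate_trace(sensor, sch, duration=3000.0, seed=11)
        res = analyze_trace(trace)
        dts = dwell_times(res)
        assert len(dts) > 300
        mean_dt = np.mean(dts)
        se = np.std(dts) / np.sqrt(len(dts))
        assert abs(mean_dt - 1.0 / sch.event_rate) < 4 * se


class TestPipelineRecovery:
    def test_recall_of_strong_events(self, sensor):
        """Injected events with A >= 5 sigma and tau >= 3 samples are found."""
        found = total = 0
        for seed in range(20):
            sch = KineticScheme(
                amp_mean=2.5e-15, amp_sd=1e-22, event_rate=0.5,
                mean_duration=0.3, noise_sd=0.5e-15,
            )
            trace, truth = simulate_trace(sensor, sch, duration=100.0, seed=seed)
            res = analyze_trace(trace)
            eligible = [e for e in truth.events if e[1] >= 3 / FS]
            pairs = match_events(res.events, eligible, tol=0.1)
            found += len(pairs)
            total += len(eligible)
        assert total > 100
        assert found / total >= 0.90

    def test_amplitudes_recovered_without_systematic_bias(self, sensor, scheme):
        trace, truth = simulate_trace(sensor, scheme, duration=315.0, seed=3)
        res = analyze_trace(trace)
        pairs = match_events(res.events, truth.events, tol=0.1)
        ratios = [res.events[i].amplitude / truth.events[k][2] for k, i in pairs]
        assert len(ratios) > 50
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.03)
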