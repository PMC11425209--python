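"""Synthetic WGM sensor traces and transmission spectra with ground truth.

The generator emulates the experimental signature of single-enzyme turnover
on a plasmon-enhanced WGM sensor: a renewal process of rectangular Δλ
excursions (exponential dwell times, exponential durations,
truncated-normal positive amplitudes of a few femtometres), optional
permanent binding steps, slow baseline drift (sinusoid + Gaussian random
walk) and white Gaussian noise on both the Δλ and δλ channels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import KineticScheme, SensorConfig
from .trace import GroundTruth, TimeTrace, TransmissionSpectrum


def _draw_amplitude(rng: np.random.Generator, scheme: KineticScheme, size: int) -> np.ndarray:
    """Truncated-normal amplitudes, strictly positive."""
    if scheme.amp_sd == 0:
        return np.full(size, scheme.amp_mean)
    a = (0.0 - scheme.amp_mean) / scheme.amp_sd  # truncate at zero
    return stats.truncnorm.rvs(
        a, np.inf, loc=scheme.amp_mean, scale=scheme.amp_sd, size=size, random_state=rng
    )


def simulate_trace(
    config: SensorConfig,
    scheme: KineticScheme,
    duration: float,
    seed: int,
) -> tuple[TimeTrace, GroundTruth]:
    """Simulate a Δλ/δλ trace of the given duration with known ground truth.

    The trace is drift + Σ rectangular events + Σ binding steps + Gaussian
    noise. Events form a renewal process — dwell ~ Exp(event_rate), width
    ~ Exp(mean_duration) — and are therefore sequential and non-overlapping
    by construction; an event that would extend past the end of the trace
    is discarded.

    Parameters
    ----------
    config : sensor operating point (sets the sampling rate and the δλ
        baseline).
    scheme : stochastic trace description.
    duration : trace length (s); should cover several mean dwell times.
    seed : seed for the underlying :class:`numpy.random.Generator`.

    Returns
    -------
    (TimeTrace, GroundTruth)
        The sampled trace and the exact injected events/steps.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * config.sample_rate))
    if n < 2:
        raise ValueError("duration too short for the configured sample rate")
    t = np.arange(n) / config.sample_rate

    # renewal sequence of (onset, width) pairs
    events: list[tuple[float, float, float]] = []
    clock = 0.0
    sign = 1.0 if scheme.positive_events else -1.0
    while True:
        clock += rng.exponential(1.0 / scheme.event_rate)
        width = rng.exponential(scheme.mean_duration)
        if clock + width >= duration:
            break
        amp = sign * float(_draw_amplitude(rng, scheme, 1)[0])
        events.append((clock, width, amp))
        clock += width

    dlam = np.zeros(n)
    for onset, width, amp in events:
        mask = (t >= onset) & (t < onset + width)
        dlam[mask] += amp

    steps: list[tuple[float, float]] = []
    for _ in range(scheme.n_binding_steps):
        t_step = float(rng.uniform(0.0, duration))
        steps.append((t_step, scheme.binding_step))
        dlam[t >= t_step] += scheme.binding_step
    steps.sort()

    if scheme.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        dlam += scheme.drift_amplitude * np.sin(2 * np.pi * t / scheme.drift_period + phase)
    if scheme.drift_walk_sd > 0:
        dlam += np.cumsum(rng.normal(0.0, scheme.drift_walk_sd, n))
    if scheme.noise_sd > 0:
        dlam += rng.normal(0.0, scheme.noise_sd, n)

    fwhm = np.full(n, config.dlambda_bar)
    if scheme.fwhm_noise_sd > 0:
        fwhm = fwhm + rng.normal(0.0, scheme.fwhm_noise_sd, n)

    trace = TimeTrace(t=t, dlambda=dlam, fwhm=fwhm)
    truth = GroundTruth(events=events, binding_steps=steps, seed=seed)
    return trace, truth


def simulate_spectrum(config: SensorConfig, n_points: int = 501) -> TransmissionSpectrum:
    """Simulate the cavity transmission dip around resonance.

    A Lorentzian dip of depth S̄ and FWHM δλ̄ centred on λ0, sampled over
    ±8 linewidths. The returned ``S_i`` and ``dlambda_i`` are recovered
    from the sampled grid itself (dip depth from the minimum; FWHM from
    linearly interpolated half-maximum crossings), mirroring how they are
    read off an experimental spectrum.
    """
    if n_points < 16:
        raise ValueError("n_points must be at least 16")
    if config.S_bar >= 1:
        raise ValueError("S_bar must be below 1 (under-coupled dip depth)")
    half = config.dlambda_bar / 2.0
    wl = config.lambda0 + np.linspace(-8, 8, n_points) * config.dlambda_bar
    trans = 1.0 - config.S_bar * half**2 / ((wl - config.lambda0) ** 2 + half**2)

    S_i = float(1.0 - trans.min())
    if S_i <= 0:
        return TransmissionSpectrum(wl, trans, S_i=0.0, dlambda_i=float("nan"))

    # FWHM of the dip: crossings of the half-depth level, left and right of min
    level = 1.0 - S_i / 2.0
    i_min = int(np.argmin(trans))
    below = trans < level

    def _crossing(i0: int, i1: int) -> float:
        w0, w1 = wl[i0], wl[i1]
        y0, y1 = trans[i0], trans[i1]
        return w0 + (level - y0) * (w1 - w0) / (y1 - y0)

    left_idx = np.flatnonzero(below[: i_min + 1])
    right_idx = i_min + np.flatnonzero(below[i_min:])
    wl_left = _crossing(left_idx[0] - 1, left_idx[0]) if left_idx[0] > 0 else wl[0]
    wl_right = (
        _crossing(right_idx[-1], right_idx[-1] + 1)
        if right_idx[-1] < n_points - 1
        else wl[-1]
    )
    return TransmissionSpectrum(wl, trans, S_i=S_i, dlambda_i=float(wl_right - wl_left))
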