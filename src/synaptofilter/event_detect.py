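"""Spontaneous-EPSC detection and event statistics.

Detection is threshold crossing on a smoothed, baseline-subtracted trace,
with the threshold scaled to a robust (median-absolute-deviation) noise
estimate.  Two shape criteria reject noise excursions: the 10-90% rise must
be fast (kernel-consistent), and the detection signal must stay above half
its peak for a minimum time on the decay side — real synaptic events decay
over several milliseconds regardless of amplitude, while smoothing-scale
noise bumps collapse within ~1-2 ms.  Events closer than the refractory
interval are merged and counted once (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core_io import AnalysisConfig, SweepRecord


@dataclass(frozen=True)
class EventTable:
    """Detected spontaneous events for one trace."""

    times: np.ndarray          # seconds, strictly increasing
    amplitudes: np.ndarray     # pA, positive magnitudes
    duration: float            # analyzed span, seconds
    unstable: bool = False     # True when duration < 10 s

    @property
    def ieis(self) -> np.ndarray:
        """Inter-event intervals, seconds (count = events - 1)."""
        return np.diff(self.times)

    @property
    def frequency(self) -> float:
        """Event rate, Hz."""
        return self.times.size / self.duration


def _block_median_baseline(x: np.ndarray, block: int) -> np.ndarray:
    """Slowly varying baseline: per-block medians, linearly interpolated."""
    n_blocks = max(x.size // block, 1)
    edges = np.linspace(0, x.size, n_blocks + 1, dtype=int)
    centers = (edges[:-1] + edges[1:]) / 2.0
    meds = np.array([np.median(x[a:b]) for a, b in zip(edges[:-1], edges[1:])])
    return np.interp(np.arange(x.size), centers, meds)


def detect_events(
    sweep: SweepRecord, config: AnalysisConfig | None = None
) -> EventTable:
    """Detect inward spontaneous events in a stimulus-free trace.

    The detection signal is the negated, Gaussian-smoothed residual after
    block-median baseline subtraction; candidate peaks must exceed
    ``k x MAD-scaled noise SD`` of that signal, be separated by the
    refractory interval, rise from 10% to 90% in under ``max_rise_ms``, and
    hold above half their peak for ``min_half_decay_ms`` on the decay side.
    Amplitude is the local raw-trace extremum minus a local pre-event median
    baseline.
    """
    config = config or AnalysisConfig()
    fs = sweep.sampling_rate
    x = sweep.samples
    block = max(int(round(config.detect_baseline_block_ms / 1e3 * fs)), 2)
    baseline = _block_median_baseline(x, block)
    resid = x - baseline
    sigma_samp = config.detect_smooth_ms / 1e3 * fs
    det = -gaussian_filter1d(resid, sigma_samp)

    mad = np.median(np.abs(det - np.median(det)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        noise_sd = 1e-12
    threshold = config.detect_k * noise_sd

    distance = max(int(round(config.refractory_ms / 1e3 * fs)), 1)
    peaks, _ = find_peaks(det, height=threshold, distance=distance)

    max_rise = int(round(config.max_rise_ms / 1e3 * fs))
    min_half = int(round(config.min_half_decay_ms / 1e3 * fs))
    half_amp_win = max(int(round(1e-3 * fs)), 1)  # +-1 ms raw-peak search
    pre_lo = int(round(5e-3 * fs))
    pre_hi = max(int(round(0.5e-3 * fs)), 1)

    times, amps = [], []
    for p in peaks:
        pk = det[p]
        # decay-side dwell above half peak
        decay = det[p : p + 4 * min_half + 1]
        below = np.nonzero(decay < pk / 2.0)[0]
        dwell = below[0] if below.size else decay.size
        if dwell < min_half:
            continue
        # 10-90% rise on the leading edge (indices absolute in the trace)
        s0 = max(p - 4 * max_rise, 0)
        lead = det[s0 : p + 1]
        under10 = np.nonzero(lead < 0.1 * pk)[0]
        under90 = np.nonzero(lead < 0.9 * pk)[0]
        if under10.size and under90.size:
            if under90[-1] - under10[-1] > max_rise:
                continue
        onset = s0 + (under10[-1] if under10.size else 0)
        # amplitude vs local pre-event baseline on the raw trace
        b0, b1 = max(onset - pre_lo, 0), max(onset - pre_hi, 1)
        local_base = float(np.median(x[b0:b1])) if b1 > b0 else baseline[p]
        j0, j1 = max(p - half_amp_win, 0), min(p + half_amp_win + 1, x.size)
        amp = local_base - float(x[j0:j1].min())
        if amp <= 0:
            continue
        times.append(onset / fs)
        amps.append(amp)

    return EventTable(
        times=np.asarray(times),
        amplitudes=np.asarray(amps),
        duration=sweep.duration,
        unstable=sweep.duration < 10.0,
    )


@dataclass(frozen=True)
class EventStatistics:
    """Summary of one event table."""

    frequency_hz: float
    n_events: int
    amp_mean_pa: float
    amp_median_pa: float
    iei_ecdf: tuple[np.ndarray, np.ndarray]
    amp_ecdf: tuple[np.ndarray, np.ndarray]


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support points and probabilities."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, v.size + 1) / max(v.size, 1)


def event_statistics(table: EventTable) -> EventStatistics:
    """Frequency, amplitude summary, and empirical IEI/amplitude CDFs."""
    amps = table.amplitudes
    return EventStatistics(
        frequency_hz=table.frequency,
        n_events=int(table.times.size),
        amp_mean_pa=float(amps.mean()) if amps.size else np.nan,
        amp_median_pa=float(np.median(amps)) if amps.size else np.nan,
        iei_ecdf=ecdf(table.ieis),
        amp_ecdf=ecdf(amps),
    )


def match_events(
    detected_times: np.ndarray,
    true_times: np.ndarray,
    tolerance_s: float = 0.003,
) -> tuple[float, float]:
    """(recall, precision) of detections against ground-truth event times.

    One-to-one greedy matching in time order within ``tolerance_s``.
    """
    det = np.sort(np.asarray(detected_times, dtype=float))
    tru = np.sort(np.asarray(true_times, dtype=float))
    i = j = hits = 0
    while i < det.size and j < tru.size:
        dt = det[i] - tru[j]
        if abs(dt) <= tolerance_s:
            hits += 1
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    recall = hits / tru.size if tru.size else 1.0
    precision = hits / det.size if det.size else 1.0
    return recall, precision
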