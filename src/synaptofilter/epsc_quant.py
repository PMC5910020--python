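"""Evoked-EPSC quantification.

Amplitude follows the published definition: the mean over a 1 ms window
around the EPSC peak, referenced to a 1 s window immediately before the
onset of the stimulation artefact.  For the second and later pulses in
paired/train stimulation the reference is a short local baseline immediately
before each stimulus, which removes the residual decay of the preceding
EPSC.  All reported amplitudes are positive magnitudes of the inward
deflection; traces are stored signed (inward negative at -70 mV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_io import AnalysisConfig, SweepRecord, ValidationError


class UndefinedRatioError(ValueError):
    """First-pulse amplitude below the noise floor; a ratio is meaningless."""


@dataclass(frozen=True)
class EpscMeasure:
    """Per-stimulus quantification result.

    ``amplitude`` is the positive magnitude (pA) of the inward deflection;
    ``baseline_level`` the signed reference current; ``below_noise`` flags
    amplitudes under the configured noise floor (returned, not raised).
    """

    amplitude: float
    peak_time: float
    baseline_level: float
    stim_index: int = 0
    decay_tau_ms: float | None = None
    below_noise: bool = False


def _window_mean(sweep: SweepRecord, t0: float, t1: float) -> float:
    i0 = max(sweep.index_of(t0), 0)
    i1 = min(sweep.index_of(t1), sweep.samples.size)
    if i1 <= i0:
        raise ValidationError(f"empty window [{t0}, {t1}) s")
    return float(sweep.samples[i0:i1].mean())


def measure_epsc(
    sweep: SweepRecord,
    stim_time: float,
    config: AnalysisConfig | None = None,
    baseline_level: float | None = None,
    stim_index: int = 0,
    search_end_s: float | None = None,
) -> EpscMeasure:
    """Quantify one evoked EPSC.

    Baseline is the mean over ``config.baseline_window_s`` (default 1 s)
    immediately before ``stim_time`` unless ``baseline_level`` is supplied
    (as it is for later pulses in a train).  The peak is the most negative
    deflection within the search window (default 2-50 ms post-stimulus, the
    first 2 ms blanked for the artefact); amplitude is the absolute
    difference between the 1 ms mean around the peak and the baseline.
    """
    config = config or AnalysisConfig()
    fs = sweep.sampling_rate
    if baseline_level is None:
        t0 = stim_time - config.baseline_window_s
        if t0 < 0:
            raise ValidationError(
                f"only {stim_time:.3f} s of pre-stimulus data; "
                f"{config.baseline_window_s} s required and no baseline supplied"
            )
        baseline_level = _window_mean(sweep, t0, stim_time)

    lo = stim_time + max(config.peak_search_ms[0], config.artefact_blank_ms) / 1e3
    hi = stim_time + config.peak_search_ms[1] / 1e3
    if search_end_s is not None:
        hi = min(hi, search_end_s)
    i_lo, i_hi = sweep.index_of(lo), min(sweep.index_of(hi), sweep.samples.size)
    if i_hi <= i_lo:
        raise ValidationError("peak search window is empty")
    seg = sweep.samples[i_lo:i_hi]
    i_peak = i_lo + int(np.argmin(seg))
    peak_time = i_peak / fs

    half = max(1, int(round(config.peak_average_ms / 2e3 * fs)))
    j0, j1 = max(i_peak - half, 0), min(i_peak + half + 1, sweep.samples.size)
    peak_level = float(sweep.samples[j0:j1].mean())
    amplitude = abs(peak_level - baseline_level)
    return EpscMeasure(
        amplitude=amplitude,
        peak_time=peak_time,
        baseline_level=float(baseline_level),
        stim_index=stim_index,
        below_noise=amplitude < config.noise_floor_pa,
    )


def measure_train(
    sweep: SweepRecord, config: AnalysisConfig | None = None
) -> list[EpscMeasure]:
    """Measure every pulse in a sweep.

    The first pulse uses the 1 s pre-stimulus baseline; later pulses use a
    local baseline (mean over ``config.local_baseline_ms`` immediately before
    each stimulus) to remove residual decay from the preceding response.
    """
    config = config or AnalysisConfig()
    if not sweep.stim_times:
        raise ValidationError("sweep has no stimuli")
    out: list[EpscMeasure] = []
    for k, t_stim in enumerate(sweep.stim_times):
        if k == 0:
            baseline = None
        else:
            baseline = _window_mean(
                sweep, t_stim - config.local_baseline_ms / 1e3, t_stim
            )
        end = sweep.stim_times[k + 1] if k + 1 < len(sweep.stim_times) else None
        out.append(
            measure_epsc(
                sweep, t_stim, config,
                baseline_level=baseline, stim_index=k, search_end_s=end,
            )
        )
    return out


def paired_pulse_ratio(
    sweep: SweepRecord, config: AnalysisConfig | None = None
) -> float:
    """Second/first EPSC amplitude ratio for a paired-stimulus sweep.

    Raises
    ------
    UndefinedRatioError
        If the first-pulse amplitude is below the configured noise floor.
    """
    config = config or AnalysisConfig()
    if len(sweep.stim_times) < 2:
        raise ValidationError("paired-pulse ratio requires >= 2 stimuli")
    m = measure_train(sweep, config)
    if m[0].amplitude < config.noise_floor_pa:
        raise UndefinedRatioError(
            f"first-pulse amplitude {m[0].amplitude:.2f} pA is below the "
            f"noise floor ({config.noise_floor_pa} pA)"
        )
    return m[1].amplitude / m[0].amplitude


def fit_decay(
    sweep: SweepRecord,
    measure: EpscMeasure,
    config: AnalysisConfig | None = None,
    window_end_s: float | None = None,
) -> float | None:
    """Single-exponential decay time constant (ms) of one EPSC.

    Fits ``A exp(-t/tau) + c`` from the peak onward, initialised with the
    observed time from the peak to 1/e of the peak deflection.  Returns
    ``None`` (flagged absent) on non-convergence or a time constant outside
    (0.1, 500) ms.
    """
    config = config or AnalysisConfig()
    fs = sweep.sampling_rate
    i_peak = sweep.index_of(measure.peak_time)
    peak_defl = sweep.samples[i_peak] - measure.baseline_level
    if abs(peak_defl) < config.noise_floor_pa:
        return None
    # rough tau: first crossing of 1/e of the peak deflection
    target = measure.baseline_level + peak_defl / np.e
    tail = sweep.samples[i_peak:]
    above = np.nonzero(tail > target)[0]
    rough_tau_s = (above[0] / fs) if above.size else 0.01
    rough_tau_s = min(max(rough_tau_s, 1e-4), 0.2)
    end = measure.peak_time + config.decay_fit_span_taus * rough_tau_s
    if window_end_s is not None:
        end = min(end, window_end_s)
    i_end = min(sweep.index_of(end), sweep.samples.size)
    if i_end - i_peak < 5:
        return None
    t = np.arange(i_end - i_peak) / fs
    y = sweep.samples[i_peak:i_end]

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    try:
        popt, _ = curve_fit(
            model, t, y,
            p0=(peak_defl, rough_tau_s, measure.baseline_level),
            maxfev=2000,
        )
    except RuntimeError:
        return None
    tau_ms = popt[1] * 1e3
    if not 0.1 < tau_ms < 500.0:
        return None
    return float(tau_ms)


def input_resistance(sweep: SweepRecord) -> float:
    """Input resistance (MΩ) from the hyperpolarizing test pulse.

    Steady state is the mean of the last 20 ms of the pulse, referenced to
    a 50 ms pre-pulse baseline; R = |ΔV| / |ΔI| by Ohm's law
    (mV / pA x 10^3 = MΩ).
    """
    tp = sweep.test_pulse
    if tp is None:
        raise ValidationError("sweep has no test-pulse metadata")
    pre_t0 = max(tp.onset_s - 0.05, 0.0)
    pre = _window_mean(sweep, pre_t0, tp.onset_s)
    t_end = tp.onset_s + tp.duration_s
    steady = _window_mean(sweep, t_end - 0.02, t_end)
    d_i = steady - pre
    if abs(d_i) < 1e-9:
        raise ValidationError("no measurable test-pulse deflection")
    return abs(tp.step_mv) / abs(d_i) * 1e3


def holding_current_change(
    sweeps: Sequence[SweepRecord],
    epoch_a: str,
    epoch_b: str,
    config: AnalysisConfig | None = None,
) -> float:
    """Change in pre-stimulus holding current (pA), epoch_b minus epoch_a."""
    config = config or AnalysisConfig()

    def epoch_mean(epoch: str) -> float:
        levels = []
        for sw in sweeps:
            if sw.epoch != epoch:
                continue
            if sw.stim_times:
                t1 = sw.stim_times[0]
                t0 = max(t1 - config.baseline_window_s, 0.0)
            else:
                t0, t1 = 0.0, sw.duration
            levels.append(_window_mean(sw, t0, t1))
        if not levels:
            raise ValidationError(f"no sweeps in epoch {epoch!r}")
        return float(np.mean(levels))

    return epoch_mean(epoch_b) - epoch_mean(epoch_a)


@dataclass(frozen=True)
class NormalizedSeries:
    """Per-sweep amplitudes expressed as % of the baseline-epoch mean."""

    table: pd.DataFrame  # columns: timestamp, epoch, amplitude, norm_pct
    baseline_epoch: str
    window_s: float
    baseline_mean_amp: float


def normalize_to_baseline(
    measures: pd.DataFrame,
    baseline_epoch: str = "baseline",
    window_s: float = 300.0,
) -> NormalizedSeries:
    """Normalize per-sweep amplitudes to the 5 min baseline mean.

    ``measures`` must have columns ``timestamp``, ``epoch``, ``amplitude``.
    The reference is the mean amplitude over baseline-epoch sweeps within
    the final ``window_s`` seconds of that epoch; by construction the mean
    of the normalized baseline window is 100%.
    """
    for col in ("timestamp", "epoch", "amplitude"):
        if col not in measures.columns:
            raise ValidationError(f"measures table missing column {col!r}")
    base = measures[measures["epoch"] == baseline_epoch]
    if len(base) < 2:
        raise ValidationError("need >= 2 baseline sweeps to normalize")
    t_end = base["timestamp"].max()
    in_window = base[base["timestamp"] >= t_end - window_s]
    ref = float(in_window["amplitude"].mean())
    if ref == 0:
        raise ValidationError("baseline mean amplitude is zero")
    out = measures.copy()
    out["norm_pct"] = out["amplitude"] / ref * 100.0
    return NormalizedSeries(
        table=out, baseline_epoch=baseline_epoch,
        window_s=window_s, baseline_mean_amp=ref,
    )


def epoch_mean_pct(series: NormalizedSeries, epoch: str) -> float:
    """Mean normalized amplitude (%) over one epoch — the per-cell summary."""
    rows = series.table[series.table["epoch"] == epoch]
    if rows.empty:
        raise ValidationError(f"no sweeps in epoch {epoch!r}")
    return float(rows["norm_pct"].mean())


def dose_response(
    per_cell_pct: Mapping[object, Sequence[float]]
) -> pd.DataFrame:
    """Assemble a dose-response summary table.

    ``per_cell_pct`` maps a concentration label to per-cell normalized
    drug-epoch means (%).  Returns a tidy table (concentration, n, mean_pct,
    sem_pct) ready for a Kruskal-Wallis + Dunn comparison; SEM is absent
    (NaN) for groups with n < 2.
    """
    if len(per_cell_pct) < 2:
        raise ValidationError("dose-response requires >= 2 groups")
    rows = []
    for label, values in per_cell_pct.items():
        v = np.asarray(list(values), dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else np.nan
        rows.append(
            {
                "concentration": label,
                "n": int(v.size),
                "mean_pct": float(v.mean()) if v.size else np.nan,
                "sem_pct": sem,
            }
        )
    return pd.DataFrame(rows)
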