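"""Short-term train metrics and long-term depression quantification.

The train ratio is the last/first evoked amplitude within a 10-pulse,
50 ms-ISI train, with per-pulse amplitudes measured against local pre-pulse
baselines.  LTD magnitude is the mean normalized first-pulse amplitude over
a 10 min window starting 10 min after the end of the induction period;
timestamps, not sweep indices, define the window, and induction-epoch sweeps
are excluded from the normalized time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from typing import Sequence

from .core_io import AnalysisConfig, SweepRecord, ValidationError
from .epsc_quant import (
    NormalizedSeries,
    UndefinedRatioError,
    measure_train,
    normalize_to_baseline,
    paired_pulse_ratio,
)


@dataclass(frozen=True)
class TrainResult:
    """Per-pulse amplitudes and the last/first ratio for one train sweep."""

    amplitudes: np.ndarray
    ratio: float  # last / first


def train_ratio(
    sweep: SweepRecord, config: AnalysisConfig | None = None
) -> TrainResult:
    """Ratio of the 10th (last) to the first EPSC amplitude in a train."""
    config = config or AnalysisConfig()
    if len(sweep.stim_times) < 2:
        raise ValidationError("train ratio requires a multi-stimulus sweep")
    measures = measure_train(sweep, config)
    amps = np.array([m.amplitude for m in measures])
    if amps[0] < config.noise_floor_pa:
        raise UndefinedRatioError(
            "first-pulse amplitude below the noise floor; ratio undefined"
        )
    return TrainResult(amplitudes=amps, ratio=float(amps[-1] / amps[0]))


def first_pulse_series(
    sweeps: Sequence[SweepRecord], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """First-pulse amplitude per sweep (the LTD time-course raw series).

    Induction-epoch sweeps are excluded.  Columns: timestamp, epoch,
    amplitude.
    """
    config = config or AnalysisConfig()
    rows = []
    for sw in sweeps:
        if sw.epoch == "induction" or not sw.stim_times:
            continue
        m = measure_train(sw, config)[0]
        rows.append(
            {"timestamp": sw.timestamp, "epoch": sw.epoch, "amplitude": m.amplitude}
        )
    return pd.DataFrame(rows)


def normalize_ltd_series(
    sweeps: Sequence[SweepRecord],
    config: AnalysisConfig | None = None,
    window_s: float = 300.0,
) -> NormalizedSeries:
    """Normalize the first-pulse time course to its 5 min baseline."""
    return normalize_to_baseline(
        first_pulse_series(sweeps, config), "baseline", window_s
    )


def ltd_magnitude(
    series: NormalizedSeries, induction_end_s: float
) -> float:
    """LTD magnitude: mean normalized amplitude, % of baseline.

    Averaged over sweeps with timestamps in
    ``[induction_end + 600 s, induction_end + 1200 s]``.
    """
    t = series.table["timestamp"]
    window = series.table[
        (t >= induction_end_s + 600.0) & (t <= induction_end_s + 1200.0)
    ]
    if window.empty:
        raise ValidationError(
            "no sweeps inside the magnitude window "
            "(10-20 min after induction end)"
        )
    return float(window["norm_pct"].mean())


def ppr_across_ltd(
    sweeps: Sequence[SweepRecord], config: AnalysisConfig | None = None
) -> tuple[float, float]:
    """Mean paired-pulse ratio before and after LTD induction.

    Returns ``(ppr_baseline, ppr_post)`` averaged over paired-stimulus
    sweeps in the ``baseline`` and ``post_induction`` epochs.
    """
    config = config or AnalysisConfig()

    def epoch_mean(epoch: str) -> float:
        ratios = [
            paired_pulse_ratio(sw, config)
            for sw in sweeps
            if sw.epoch == epoch and len(sw.stim_times) >= 2
        ]
        if not ratios:
            raise ValidationError(f"no paired-stimulus sweeps in epoch {epoch!r}")
        return float(np.mean(ratios))

    return epoch_mean("baseline"), epoch_mean("post_induction")
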