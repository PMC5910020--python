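import numpy as np
import pandas as pd
import pytest

import synaptofilter as sf
from synaptofilter.core_io import SweepRecord, TestPulse, ValidationError
from synaptofilter.epsc_quant import (
    UndefinedRatioError,
    dose_response,
    epoch_mean_pct,
    fit_decay,
    holding_current_change,
    input_resistance,
    measure_epsc,
    measure_train,
    normalize_to_baseline,
    paired_pulse_ratio,
)
from synaptofilter.synth_ephys import kernel_peak_time_s

from conftest import make_kernel_trace

FS = 10_000.0


class TestMeasureEpsc:
    def test_flat_trace_measures_zero(self):
        sw = SweepRecord(samples=np.zeros(30_000), sampling_rate=FS,
                         stim_times=(1.5,))
        m = measure_epsc(sw, 1.5)
        assert m.amplitude == pytest.approx(0.0)
        assert m.below_noise

    def test_noiseless_kernel_amplitude_and_peak_time(self):
        # 120 pA kernel on a -20 pA baseline: amplitude ~120, peak at the
        # analytic kernel maximum (1 ms averaging shaves ~1% off the peak)
        trace = make_kernel_trace(120.0, 1.5, baseline_pa=-20.0)
        sw = SweepRecord(samples=trace, sampling_rate=FS, stim_times=(1.5,))
        m = measure_epsc(sw, 1.5)
        assert m.baseline_level == pytest.approx(-20.0)
        assert m.amplitude == pytest.approx(120.0, rel=0.015)
        assert m.peak_time == pytest.approx(
            1.5 + kernel_peak_time_s(1.0, 8.0), abs=2e-4
        )

    def test_offset_invariance(self):
        trace = make_kernel_trace(90.0, 1.5)
        a = measure_epsc(
            SweepRecord(samples=trace, sampling_rate=FS, stim_times=(1.5,)), 1.5
        )
        b = measure_epsc(
            SweepRecord(samples=trace + 50.0, sampling_rate=FS,
                        stim_times=(1.5,)), 1.5
        )
        assert a.amplitude == pytest.approx(b.amplitude, abs=1e-9)

    def test_scale_equivariance(self):
        trace = make_kernel_trace(90.0, 1.5)
        a = measure_epsc(
            SweepRecord(samples=trace, sampling_rate=FS, stim_times=(1.5,)), 1.5
        )
        b = measure_epsc(
            SweepRecord(samples=trace * 3.0, sampling_rate=FS,
                        stim_times=(1.5,)), 1.5
        )
        assert b.amplitude == pytest.approx(3.0 * a.amplitude, rel=1e-9)

    def test_insufficient_baseline_raises(self):
        sw = SweepRecord(samples=np.zeros(10_000), sampling_rate=FS,
                         stim_times=(0.5,))
        with pytest.raises(ValidationError):
            measure_epsc(sw, 0.5)


class TestPairedPulseRatio:
    def test_definition_arithmetic(self):
        # A1 = 80, A2 = 136 -> ratio 1.7; non-overlapping kernels
        trace = (make_kernel_trace(80.0, 1.5)
                 + make_kernel_trace(136.0, 1.9) )
        sw = SweepRecord(samples=trace, sampling_rate=FS,
                         stim_times=(1.5, 1.9))
        assert paired_pulse_ratio(sw) == pytest.approx(1.7, rel=0.01)

    def test_identical_kernels_give_unity(self):
        trace = make_kernel_trace(100.0, 1.5) + make_kernel_trace(100.0, 1.9)
        sw = SweepRecord(samples=trace, sampling_rate=FS,
                         stim_times=(1.5, 1.9))
        assert paired_pulse_ratio(sw) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("isi_ms", [50, 80, 100])
    def test_unbiased_on_overlapping_pairs(self, isi_ms):
        # local-baseline correction removes the residual first-EPSC decay
        proto = sf.StimProtocol(kind="paired", isi_s=isi_ms / 1e3)
        params = sf.ReleaseModelParams(noise_sd=0.0, U=0.15)
        sw, gt = sf.simulate_sweep(proto, params, deterministic=True)
        want = gt.expected_amplitudes[1] / gt.expected_amplitudes[0]
        assert paired_pulse_ratio(sw) == pytest.approx(want, rel=0.02)

    def test_noise_floor_guard(self):
        sw = SweepRecord(samples=np.zeros(30_000), sampling_rate=FS,
                         stim_times=(1.5, 1.55))
        with pytest.raises(UndefinedRatioError):
            paired_pulse_ratio(sw)

    def test_q_scaling_preserves_ppr_but_u_scaling_changes_it(
        self, paired_protocol
    ):
        # the presynaptic-vs-postsynaptic signature the pipeline must resolve
        params = sf.ReleaseModelParams(noise_sd=0.0, U=0.2)
        base, _ = sf.simulate_sweep(paired_protocol, params,
                                    deterministic=True)
        q_scaled, _ = sf.simulate_sweep(paired_protocol, params, 0.5, "q",
                                        deterministic=True)
        u_scaled, _ = sf.simulate_sweep(paired_protocol, params, 0.5, "U",
                                        deterministic=True)
        ppr0 = paired_pulse_ratio(base)
        assert paired_pulse_ratio(q_scaled) == pytest.approx(ppr0, rel=0.02)
        assert paired_pulse_ratio(u_scaled) > ppr0 * 1.1


class TestDecayFit:
    def test_pure_exponential_recovered(self):
        t = np.arange(30_000) / FS
        tau = 0.010
        trace = np.where(t >= 1.5, -100.0 * np.exp(-(t - 1.5) / tau), 0.0)
        sw = SweepRecord(samples=trace, sampling_rate=FS, stim_times=(1.498,))
        m = measure_epsc(sw, 1.498)
        assert fit_decay(sw, m) == pytest.approx(10.0, rel=0.02)

    def test_scale_invariance(self):
        trace = make_kernel_trace(100.0, 1.5)
        sw1 = SweepRecord(samples=trace, sampling_rate=FS, stim_times=(1.5,))
        sw2 = SweepRecord(samples=trace * 4, sampling_rate=FS,
                          stim_times=(1.5,))
        t1 = fit_decay(sw1, measure_epsc(sw1, 1.5))
        t2 = fit_decay(sw2, measure_epsc(sw2, 1.5))
        assert t1 == pytest.approx(t2, rel=1e-6)

    def test_noisy_recovery_within_five_percent_median(self):
        rng = np.random.default_rng(3)
        taus = []
        for _ in range(100):
            trace = make_kernel_trace(100.0, 1.5, tau_decay_ms=15.0)
            trace += rng.normal(0, 10.0, trace.size)  # SNR 10
            sw = SweepRecord(samples=trace, sampling_rate=FS,
                             stim_times=(1.5,))
            tau = fit_decay(sw, measure_epsc(sw, 1.5))
            if tau is not None:
                taus.append(tau)
        # the double-exponential kernel's tail is 15 ms; single-exp fit
        # from the peak recovers it within 5% at the median
        assert np.median(taus) == pytest.approx(15.0, rel=0.05)


class TestInputResistance:
    @pytest.mark.parametrize("delta_pa,expected", [(50.0, 100.0), (25.0, 200.0)])
    def test_ohms_law(self, delta_pa, expected):
        trace = np.zeros(10_000)
        i0, i1 = 2000, 3000  # 100 ms pulse
        trace[i0:i1] = -delta_pa
        sw = SweepRecord(samples=trace, sampling_rate=FS,
                         test_pulse=TestPulse(0.2))
        assert input_resistance(sw) == pytest.approx(expected)

    def test_rc_settling_recovered_within_one_percent(self):
        proto = sf.StimProtocol(kind="test_pulse_only")
        membrane = sf.MembraneParams(r_input_mohm=150.0, tau_m_ms=10.0)
        sw, _ = sf.simulate_sweep(
            proto, sf.ReleaseModelParams(noise_sd=0.0), membrane=membrane
        )
        assert input_resistance(sw) == pytest.approx(150.0, rel=0.01)

    def test_missing_test_pulse_raises(self):
        sw = SweepRecord(samples=np.zeros(1000), sampling_rate=FS)
        with pytest.raises(ValidationError):
            input_resistance(sw)


class TestHoldingCurrent:
    def _sweeps(self, offset_b=0.0, noise=0.0, n=5, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for epoch, off in (("baseline", 0.0), ("drug", offset_b)):
            for _ in range(n):
                trace = np.full(30_000, -20.0 + off)
                if noise:
                    trace += rng.normal(0, noise, trace.size)
                out.append(SweepRecord(samples=trace, sampling_rate=FS,
                                       stim_times=(1.5,), epoch=epoch))
        return out

    def test_identical_epochs_give_zero(self):
        assert holding_current_change(self._sweeps(), "baseline", "drug") == 0

    def test_injected_offset_recovered(self):
        got = holding_current_change(self._sweeps(offset_b=3.0),
                                     "baseline", "drug")
        assert got == pytest.approx(3.0, abs=1e-9)

    def test_noisy_offset_within_propagated_error(self):
        got = holding_current_change(
            self._sweeps(offset_b=3.0, noise=5.0, n=30, seed=1),
            "baseline", "drug",
        )
        assert got == pytest.approx(3.0, abs=2.0)

    def test_empty_epoch_raises(self):
        with pytest.raises(ValidationError):
            holding_current_change(self._sweeps(), "baseline",
                                   "post_induction")


class TestNormalization:
    def _measures(self, amps, epochs):
        return pd.DataFrame(
            {"timestamp": 30.0 * np.arange(len(amps)), "epoch": epochs,
             "amplitude": amps}
        )

    def test_constant_series_is_all_hundred(self):
        df = self._measures([50.0] * 6, ["baseline"] * 3 + ["drug"] * 3)
        series = normalize_to_baseline(df)
        assert (series.table["norm_pct"] == 100.0).all()

    def test_step_to_half_reads_fifty_percent(self):
        df = self._measures([80, 80, 80, 40, 40, 40],
                            ["baseline"] * 3 + ["drug"] * 3)
        series = normalize_to_baseline(df)
        assert epoch_mean_pct(series, "drug") == pytest.approx(50.0)
        assert epoch_mean_pct(series, "baseline") == pytest.approx(100.0)

    def test_baseline_mean_is_hundred_by_construction(self):
        rng = np.random.default_rng(0)
        amps = rng.uniform(50, 150, 10)
        df = self._measures(amps, ["baseline"] * 10)
        series = normalize_to_baseline(df)
        assert series.table["norm_pct"].mean() == pytest.approx(100.0)

    def test_degenerate_baselines_rejected(self):
        with pytest.raises(ValidationError):
            normalize_to_baseline(self._measures([1.0], ["baseline"]))
        with pytest.raises(ValidationError):
            normalize_to_baseline(
                self._measures([0.0, 0.0, 5.0],
                               ["baseline", "baseline", "drug"])
            )


class TestDoseResponse:
    def test_summary_table_and_small_group_flag(self):
        table = dose_response({0: [100, 104], 10: [95, 93, 97], 1000: [78]})
        assert list(table["n"]) == [2, 3, 1]
        assert table.loc[2, "mean_pct"] == 78
        assert np.isnan(table.loc[2, "sem_pct"])
        assert table.loc[1, "sem_pct"] == pytest.approx(
            np.std([95, 93, 97], ddof=1) / np.sqrt(3)
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            dose_response({0: [100.0, 101.0]})
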