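"""Synthetic voltage-clamp sweep generator with exact ground truth.

Evoked release follows the standard two-variable facilitation/depression
recursion (release fraction ``u`` facilitating toward 1 with time constant
``tau_facil``, vesicle resource ``x`` recovering toward 1 with ``tau_rec``).
Release at each pulse is binomial over ``n_sites`` independent sites, each
released vesicle contributing a unit-peak double-exponential inward kernel
scaled by the quantal amplitude ``q``.  The per-site stochastic model has
expectation equal to the deterministic recursion, which therefore serves as
a closed-form oracle for every simulated protocol.

Drug or plasticity effects are injected as a multiplicative scale on either
``U`` (presynaptic: changes paired-pulse ratio) or ``q`` (postsynaptic:
leaves paired-pulse ratio unchanged), so downstream estimators can be tested
for their ability to distinguish the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .core_io import SweepRecord, TestPulse, ValidationError


@dataclass(frozen=True)
class ReleaseModelParams:
    """Generative parameters for evoked-release simulation.

    Parameters
    ----------
    n_sites : int
        Independent release sites.
    U : float
        Baseline release fraction per site, in (0, 1].
    tau_facil : float
        Facilitation decay time constant, seconds.
    tau_rec : float
        Vesicle recovery time constant, seconds.
    q : float
        Quantal peak amplitude, pA (positive; currents are inward).
    tau_rise_ms, tau_decay_ms : float
        EPSC kernel time constants (double exponential, unit peak).
    noise_sd : float
        Additive Gaussian recording noise, pA.
    artefact_pa, artefact_width_ms : float
        Biphasic stimulus artefact amplitude and total width.
    seed : int
        Default RNG seed for simulations using these parameters.
    """

    n_sites: int = 200
    U: float = 0.35
    tau_facil: float = 0.2
    tau_rec: float = 0.5
    q: float = 2.0
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 8.0
    noise_sd: float = 5.0
    artefact_pa: float = 200.0
    artefact_width_ms: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValidationError("U must be in (0, 1]")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValidationError("tau_rise must be < tau_decay")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.q <= 0 or self.n_sites < 1:
            raise ValidationError("q must be > 0 and n_sites >= 1")


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane/seal model for baseline current and test pulses."""

    r_input_mohm: float = 150.0
    tau_m_ms: float = 10.0
    holding_pa: float = -20.0


@dataclass(frozen=True)
class StimProtocol:
    """Electrical stimulation layout within one sweep."""

    kind: str = "single"  # single | paired | train | test_pulse_only
    isi_s: float = 0.05
    n_pulses: int = 1
    stim_start_s: float = 1.5
    tail_s: float = 0.3
    test_pulse: TestPulse | None = TestPulse(onset_s=0.2)

    def __post_init__(self) -> None:
        kinds = {"single", "paired", "train", "test_pulse_only"}
        if self.kind not in kinds:
            raise ValidationError(f"protocol kind must be in {sorted(kinds)}")
        n = {"single": 1, "paired": 2}.get(self.kind, self.n_pulses)
        if self.kind == "test_pulse_only":
            n = 0
        object.__setattr__(self, "n_pulses", n)

    @property
    def stim_times(self) -> tuple[float, ...]:
        return tuple(
            self.stim_start_s + k * self.isi_s for k in range(self.n_pulses)
        )

    @property
    def duration_s(self) -> float:
        if self.n_pulses:
            return self.stim_times[-1] + self.tail_s
        tp = self.test_pulse
        base = tp.onset_s + tp.duration_s if tp else 0.0
        return base + self.tail_s


@dataclass
class GroundTruth:
    """Injected truth accompanying a simulated sweep."""

    expected_amplitudes: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )
    released_counts: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    epoch_scale: float = 1.0


def epsc_kernel(
    tau_rise_ms: float, tau_decay_ms: float, sampling_rate: float
) -> np.ndarray:
    """Unit-peak double-exponential kernel sampled at ``sampling_rate``.

    ``g(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / g(t_peak)`` with
    ``t_peak = tau_r tau_d / (tau_d - tau_r) * ln(tau_d / tau_r)``.
    """
    tr, td = tau_rise_ms / 1e3, tau_decay_ms / 1e3
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    span = td * 8.0
    t = np.arange(0.0, span, 1.0 / sampling_rate)
    g = np.exp(-t / td) - np.exp(-t / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return g / peak


def kernel_peak_time_s(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Analytic time-to-peak of the double-exponential kernel, seconds."""
    tr, td = tau_rise_ms / 1e3, tau_decay_ms / 1e3
    return tr * td / (td - tr) * np.log(td / tr)


# ---------------------------------------------------------------------------
# facilitation/depression recursion (deterministic oracle)
# ---------------------------------------------------------------------------

def _release_fractions(
    U: float, tau_facil: float, tau_rec: float, isi_s: float, n_pulses: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pulse (u_k, x_k) from the two-variable recursion.

    u1 = U, x1 = 1; release r_k = u_k x_k; after each pulse u jumps to
    u + U(1-u) and decays toward U with tau_facil; x drops to x(1-u) and
    recovers toward 1 with tau_rec.
    """
    u = np.empty(n_pulses)
    x = np.empty(n_pulses)
    u[0], x[0] = U, 1.0
    for k in range(n_pulses - 1):
        u_plus = u[k] + U * (1.0 - u[k])
        x_plus = x[k] * (1.0 - u[k])
        fd = np.exp(-isi_s / tau_facil) if tau_facil > 0 else 0.0
        fr = np.exp(-isi_s / tau_rec) if tau_rec > 0 else 0.0
        u[k + 1] = U + (u_plus - U) * fd
        x[k + 1] = 1.0 + (x_plus - 1.0) * fr
    return u, x


def expected_release_series(
    params: ReleaseModelParams,
    isi_s: float,
    n_pulses: int,
    epoch_scale: float = 1.0,
    scale_target: str = "U",
) -> np.ndarray:
    """Expected peak amplitudes (pA) for each pulse in a train.

    Element ``k`` equals ``u_k x_k n_sites q`` (the kernel has unit peak).
    Deterministic; serves as the oracle for stochastic simulations.
    """
    if n_pulses < 1:
        raise ValidationError("n_pulses must be >= 1")
    U, q = _scaled_uq(params, epoch_scale, scale_target)
    u, x = _release_fractions(U, params.tau_facil, params.tau_rec, isi_s, n_pulses)
    return u * x * params.n_sites * q


def _scaled_uq(
    params: ReleaseModelParams, epoch_scale: float, scale_target: str
) -> tuple[float, float]:
    if scale_target not in ("U", "q"):
        raise ValidationError("scale_target must be 'U' or 'q'")
    if epoch_scale < 0:
        raise ValidationError("epoch_scale must be >= 0")
    if scale_target == "U":
        return min(params.U * epoch_scale, 1.0), params.q
    return params.U, params.q * epoch_scale


def expected_ppr(
    params: ReleaseModelParams, isi_s: float = 0.05, **kw
) -> float:
    """Expected second/first amplitude ratio at the given ISI."""
    amps = expected_release_series(params, isi_s, 2, **kw)
    return float(amps[1] / amps[0])


def calibrate_U_for_ppr(
    target_ppr: float,
    isi_s: float = 0.05,
    tau_facil: float = 0.2,
    tau_rec: float = 0.5,
) -> float:
    """Solve for U so the recursion's paired-pulse ratio equals ``target_ppr``.

    The PPR is monotone decreasing in U with supremum ``1 + exp(-isi/tau_f)``
    as U -> 0, so the solution is found by bracketing.
    """

    def f(U: float) -> float:
        u, x = _release_fractions(U, tau_facil, tau_rec, isi_s, 2)
        return (u[1] * x[1]) / (u[0] * x[0]) - target_ppr

    return float(brentq(f, 1e-6, 1.0 - 1e-9, xtol=1e-12))


def calibrate_U_for_train_ratio(
    target_ratio: float,
    n_pulses: int = 10,
    isi_s: float = 0.05,
    tau_facil: float = 0.02,
    tau_rec: float = 0.5,
) -> float:
    """Solve for U so the last/first expected-amplitude ratio hits target."""

    def f(U: float) -> float:
        u, x = _release_fractions(U, tau_facil, tau_rec, isi_s, n_pulses)
        return (u[-1] * x[-1]) / (u[0] * x[0]) - target_ratio

    return float(brentq(f, 1e-6, 1.0 - 1e-9, xtol=1e-12))


# ---------------------------------------------------------------------------
# trace assembly
# ---------------------------------------------------------------------------

def _add_kernel(trace: np.ndarray, kernel: np.ndarray, idx: int, amp_pa: float) -> None:
    """Add an inward (negative) scaled kernel starting at sample ``idx``."""
    end = min(idx + kernel.size, trace.size)
    if end > idx >= 0:
        trace[idx:end] -= amp_pa * kernel[: end - idx]


def _add_artefact(
    trace: np.ndarray, idx: int, amp_pa: float, width_ms: float, fs: float
) -> None:
    half = max(1, int(round(width_ms / 2e3 * fs)))
    end1 = min(idx + half, trace.size)
    end2 = min(idx + 2 * half, trace.size)
    trace[idx:end1] += amp_pa
    trace[end1:end2] -= amp_pa


def _add_test_pulse(
    trace: np.ndarray, tp: TestPulse, membrane: MembraneParams, fs: float
) -> None:
    """Exponentially settling current step for a voltage test pulse."""
    di = tp.step_mv / membrane.r_input_mohm * 1e3  # mV/MΩ = nA -> pA
    tau = membrane.tau_m_ms / 1e3
    i0 = int(round(tp.onset_s * fs))
    i1 = min(int(round((tp.onset_s + tp.duration_s) * fs)), trace.size)
    t = np.arange(i1 - i0) / fs
    trace[i0:i1] += di * (1.0 - np.exp(-t / tau))
    t2 = np.arange(trace.size - i1) / fs
    level = di * (1.0 - np.exp(-tp.duration_s / tau))
    trace[i1:] += level * np.exp(-t2 / tau)


def simulate_sweep(
    protocol: StimProtocol,
    params: ReleaseModelParams,
    epoch_scale: float = 1.0,
    scale_target: str = "U",
    seed: int | None = None,
    membrane: MembraneParams | None = None,
    sampling_rate: float = 10_000.0,
    epoch: str = "baseline",
    sweep_index: int = 0,
    timestamp: float = 0.0,
    deterministic: bool = False,
) -> tuple[SweepRecord, GroundTruth]:
    """Simulate one evoked sweep; same seed gives an identical trace.

    Release at pulse ``k`` is binomial: each currently available site
    releases with probability ``u_k``; released sites recover independently
    with probability ``1 - exp(-isi/tau_rec)`` before the next pulse, so the
    expected per-pulse amplitude equals :func:`expected_release_series`.
    With ``deterministic=True`` the binomial draw is replaced by its
    expectation (each pulse contributes exactly the recursion amplitude),
    giving exact pass-through for noiseless oracle tests.
    """
    if protocol.n_pulses >= 2 and protocol.isi_s <= params.artefact_width_ms / 1e3:
        raise ValidationError("ISI must exceed the artefact width")
    membrane = membrane or MembraneParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fs = sampling_rate
    n = int(round(protocol.duration_s * fs))
    trace = np.full(n, membrane.holding_pa, dtype=np.float64)

    U, q = _scaled_uq(params, epoch_scale, scale_target)
    kernel = epsc_kernel(params.tau_rise_ms, params.tau_decay_ms, fs)
    stim_times = protocol.stim_times
    expected = (
        expected_release_series(
            params, protocol.isi_s, protocol.n_pulses, epoch_scale, scale_target
        )
        if protocol.n_pulses
        else np.empty(0)
    )

    released = np.zeros(protocol.n_pulses, dtype=int)
    if deterministic:
        for k, t_stim in enumerate(stim_times):
            _add_kernel(trace, kernel, int(round(t_stim * fs)), expected[k])
        released = np.round(expected / q).astype(int) if q > 0 else released
    elif protocol.n_pulses and U > 0:
        u_k = np.empty(protocol.n_pulses)
        u_k[0] = U
        for k in range(protocol.n_pulses - 1):
            fd = np.exp(-protocol.isi_s / params.tau_facil) if params.tau_facil > 0 else 0.0
            u_plus = u_k[k] + U * (1.0 - u_k[k])
            u_k[k + 1] = U + (u_plus - U) * fd
        available = np.ones(params.n_sites, dtype=bool)
        p_rec = 1.0 - np.exp(-protocol.isi_s / params.tau_rec) if params.tau_rec > 0 else 1.0
        for k, t_stim in enumerate(stim_times):
            fire = available & (rng.random(params.n_sites) < u_k[k])
            released[k] = int(fire.sum())
            available &= ~fire
            _add_kernel(trace, kernel, int(round(t_stim * fs)), released[k] * q)
            recover = ~available & (rng.random(params.n_sites) < p_rec)
            available |= recover

    for t_stim in stim_times:
        _add_artefact(
            trace, int(round(t_stim * fs)), params.artefact_pa,
            params.artefact_width_ms, fs,
        )
    if protocol.test_pulse is not None:
        _add_test_pulse(trace, protocol.test_pulse, membrane, fs)
    if params.noise_sd > 0:
        trace += rng.normal(0.0, params.noise_sd, size=n)

    sweep = SweepRecord(
        samples=trace,
        sampling_rate=fs,
        stim_times=stim_times,
        test_pulse=protocol.test_pulse,
        sweep_index=sweep_index,
        epoch=epoch,
        timestamp=timestamp,
    )
    truth = GroundTruth(
        expected_amplitudes=expected,
        released_counts=released,
        epoch_scale=epoch_scale,
    )
    return sweep, truth


def simulate_drug_experiment(
    params: ReleaseModelParams,
    protocol: StimProtocol,
    epoch_scale: float,
    n_baseline: int = 10,
    n_drug: int = 10,
    scale_target: str = "U",
    sweep_interval_s: float = 30.0,
    seed: int | None = None,
    membrane: MembraneParams | None = None,
    deterministic: bool = False,
) -> tuple[list[SweepRecord], list[GroundTruth]]:
    """Baseline sweeps followed by drug-epoch sweeps, 30 s apart.

    Mirrors the bath-application design: a stable baseline, then the same
    stimulation with release scaled by ``epoch_scale``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sweeps, truths = [], []
    for i in range(n_baseline + n_drug):
        in_drug = i >= n_baseline
        sw, gt = simulate_sweep(
            protocol,
            params,
            epoch_scale=epoch_scale if in_drug else 1.0,
            scale_target=scale_target,
            seed=int(rng.integers(2**31)),
            membrane=membrane,
            epoch="drug" if in_drug else "baseline",
            sweep_index=i,
            timestamp=i * sweep_interval_s,
            deterministic=deterministic,
        )
        sweeps.append(sw)
        truths.append(gt)
    return sweeps, truths


def simulate_ltd_series(
    params: ReleaseModelParams,
    induction_protocol: str = "10hz",
    true_post_fraction: float = 0.6422,
    baseline_s: float = 300.0,
    post_s: float = 1500.0,
    sweep_interval_s: float = 30.0,
    isi_s: float = 0.05,
    scale_target: str = "q",
    seed: int | None = None,
    membrane: MembraneParams | None = None,
    deterministic: bool = False,
) -> tuple[list[SweepRecord], dict]:
    """Simulate a long-term depression experiment with paired-pulse probes.

    Baseline paired-pulse sweeps every 30 s for ``baseline_s``; an induction
    gap (5 min of 10 Hz stimulation, or 4 x 1 s of 100 Hz with 10 s
    inter-train intervals — probe sweeps are not acquired during induction);
    then post-induction sweeps whose expected first-pulse amplitude is
    ``true_post_fraction`` times the baseline expectation.

    Returns the sweep list and a truth dict with ``induction_end_s`` and the
    injected fraction.
    """
    if induction_protocol == "10hz":
        induction_s = 300.0
    elif induction_protocol == "100hz":
        induction_s = 4 * 1.0 + 3 * 10.0
    else:
        raise ValidationError("induction_protocol must be '10hz' or '100hz'")
    induction_end = baseline_s + induction_s
    if post_s < 1200.0:
        raise ValidationError(
            "post duration must cover the magnitude window (>= 1200 s)"
        )
    protocol = StimProtocol(kind="paired", isi_s=isi_s)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sweeps: list[SweepRecord] = []
    idx = 0
    t = 0.0
    while t < baseline_s:
        sw, _ = simulate_sweep(
            protocol, params, 1.0, scale_target,
            seed=int(rng.integers(2**31)), membrane=membrane,
            epoch="baseline", sweep_index=idx, timestamp=t,
            deterministic=deterministic,
        )
        sweeps.append(sw)
        idx += 1
        t += sweep_interval_s
    t = induction_end + sweep_interval_s
    while t <= induction_end + post_s:
        sw, _ = simulate_sweep(
            protocol, params, true_post_fraction, scale_target,
            seed=int(rng.integers(2**31)), membrane=membrane,
            epoch="post_induction", sweep_index=idx, timestamp=t,
            deterministic=deterministic,
        )
        sweeps.append(sw)
        idx += 1
        t += sweep_interval_s
    truth = {
        "induction_end_s": induction_end,
        "true_post_fraction": true_post_fraction,
        "scale_target": scale_target,
    }
    return sweeps, truth


def simulate_sepsc_trace(
    rate_hz: float,
    duration_s: float = 120.0,
    seed: int = 0,
    median_amp_pa: float = 8.0,
    sigma_log: float = 0.4,
    tau_rise_ms: float = 1.0,
    tau_decay_ms: float = 8.0,
    noise_sd: float = 2.0,
    sampling_rate: float = 10_000.0,
    holding_pa: float = -20.0,
    amp_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> tuple[SweepRecord, GroundTruth]:
    """Simulate a spontaneous-EPSC recording.

    Event times are a homogeneous Poisson process; amplitudes default to
    log-normal with the given median (the recordings this emulates have a
    median spontaneous amplitude near 8 pA).  The ground-truth event list is
    returned alongside the trace.
    """
    if rate_hz < 0 or duration_s <= 0:
        raise ValidationError("rate must be >= 0 and duration > 0")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    if amp_dist is not None:
        amps = np.asarray(amp_dist(rng, n_events), dtype=float)
    else:
        amps = rng.lognormal(np.log(median_amp_pa), sigma_log, size=n_events)
    n = int(round(duration_s * sampling_rate))
    trace = np.full(n, holding_pa, dtype=np.float64)
    kernel = epsc_kernel(tau_rise_ms, tau_decay_ms, sampling_rate)
    for t_ev, a in zip(times, amps):
        _add_kernel(trace, kernel, int(round(t_ev * sampling_rate)), a)
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)
    sweep = SweepRecord(samples=trace, sampling_rate=sampling_rate)
    truth = GroundTruth(event_times=times, event_amplitudes=amps)
    return sweep, truth
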