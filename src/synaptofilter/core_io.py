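"""Shared data model, file I/O and configuration.

Conventions used throughout the package (stated once, asserted everywhere):

* time is in seconds, 0 at sweep start; currents in pA (inward negative at
  a -70 mV holding potential); sampling rate in Hz
* image stacks are indexed ``(channel, z, y, x)`` with 0-based pixel indices;
  pixel sizes in µm
* results tables are tidy CSV and carry the configuration hash and RNG seed
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

EPOCHS = frozenset(
    {"baseline", "drug", "post_induction", "induction", "post_light"}
)

CHANNEL_ROLES = ("marker", "probe", "bead")


class FormatError(ValueError):
    """A file is malformed or metadata fields are missing."""


class ValidationError(ValueError):
    """A record violates the data-model invariants."""


class ConfigurationError(ValueError):
    """A configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class TestPulse:
    """Hyperpolarizing membrane test pulse delivered within a sweep.

    The default is the 100 ms, -5 mV pulse used to monitor input and series
    resistance on every sweep.
    """

    onset_s: float
    duration_s: float = 0.1
    step_mv: float = -5.0


@dataclass(frozen=True)
class SweepRecord:
    """One voltage-clamp current trace with stimulus metadata.

    Parameters
    ----------
    samples : ndarray
        Membrane current in pA, inward negative.
    sampling_rate : float
        Samples per second (the recordings this emulates were sampled at
        10 kHz).
    stim_times : tuple of float
        Stimulus onset times in seconds, strictly increasing, within the
        sweep.
    test_pulse : TestPulse or None
        Resistance-monitoring pulse metadata, if one was delivered.
    holding_potential : float
        Command potential in mV.
    sweep_index : int
        Acquisition order within the experiment.
    epoch : str
        One of ``baseline, drug, post_induction, induction, post_light``.
    timestamp : float
        Seconds since the start of the experiment.
    """

    samples: np.ndarray
    sampling_rate: float
    stim_times: tuple[float, ...] = ()
    test_pulse: TestPulse | None = None
    holding_potential: float = -70.0
    sweep_index: int = 0
    epoch: str = "baseline"
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "stim_times", tuple(float(t) for t in self.stim_times))
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")
        if self.epoch not in EPOCHS:
            raise ValidationError(
                f"epoch {self.epoch!r} not in {sorted(EPOCHS)}"
            )
        st = np.asarray(self.stim_times)
        if st.size:
            if np.any(np.diff(st) <= 0):
                raise ValidationError("stim_times must be strictly increasing")
            if st[0] < 0 or st[-1] >= self.duration:
                raise ValidationError(
                    "stim_times must lie within [0, sweep duration)"
                )

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Time base in seconds, 0 at sweep start."""
        return np.arange(self.samples.size) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Sample index of time ``t`` (floor)."""
        return int(np.floor(t * self.sampling_rate))


@dataclass(frozen=True)
class ImageStack:
    """A multi-channel confocal z-stack.

    ``voxels`` is indexed ``(channel, z, y, x)``; ``channel_roles`` maps each
    role in use (``marker`` somatic transcript, ``probe`` transcript of
    interest, ``bead`` retrograde tracer) to its channel index.
    """

    voxels: np.ndarray
    pixel_size_xy: float
    z_step: float = 1.0
    channel_roles: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "channel_roles", dict(self.channel_roles))
        if voxels.ndim != 4:
            raise ValidationError("voxels must be (channel, z, y, x)")
        if self.z_step <= 0 or self.pixel_size_xy <= 0:
            raise ValidationError("voxel geometry must be positive")
        if voxels.size and voxels.min() < 0:
            raise ValidationError("intensities must be non-negative")
        n_chan = voxels.shape[0]
        seen: dict[int, str] = {}
        for role, chan in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise ConfigurationError(f"unknown channel role {role!r}")
            if not 0 <= chan < n_chan:
                raise ConfigurationError(
                    f"role {role!r} maps to channel {chan} outside 0..{n_chan - 1}"
                )
            if chan in seen:
                raise ConfigurationError(
                    f"channels must map to exactly one role; channel {chan} "
                    f"claimed by {seen[chan]!r} and {role!r}"
                )
            seen[chan] = role

    @property
    def n_z(self) -> int:
        return self.voxels.shape[1]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` sub-stack for a declared role."""
        if role not in self.channel_roles:
            raise ConfigurationError(f"no channel declared for role {role!r}")
        return self.voxels[self.channel_roles[role]]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters, serialisable to/from YAML.

    Windows follow the published measurement definitions: a 1 s pre-stimulus
    baseline, a 1 ms average around the EPSC peak, and a peak search window
    after blanking the stimulation artefact.
    """

    # evoked EPSC quantification
    peak_search_ms: tuple[float, float] = (2.0, 50.0)  # post-stimulus
    artefact_blank_ms: float = 2.0
    baseline_window_s: float = 1.0
    peak_average_ms: float = 1.0
    local_baseline_ms: float = 1.0  # pre-stimulus window for pulses 2..n
    noise_floor_pa: float = 1.0
    decay_fit_span_taus: float = 5.0

    # spontaneous-event detection
    detect_k: float = 3.5
    detect_smooth_ms: float = 1.0
    detect_baseline_block_ms: float = 50.0
    refractory_ms: float = 5.0
    max_rise_ms: float = 5.0
    min_half_decay_ms: float = 3.5

    # FISH segmentation / counting
    z_group_size: int = 3
    z_project: str = "max"  # or "sum"
    threshold_method: str = "otsu"  # or "fixed"
    threshold_value: float = 0.0
    segment_smooth_sigma_px: float = 4.0
    seed_min_distance_px: int = 10
    min_cell_area_px2: float = 100.0
    puncta_min_separation_px: int = 3
    dedup_centroid_px: float = 5.0

    # classification cutoffs: cell is positive when count > cutoff (strict)
    class_cutoffs: dict = field(
        default_factory=lambda: {"probe": 10, "bead": 3}
    )

    # statistics
    alpha: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peak_search_ms
        if not (0 <= lo < hi):
            raise ConfigurationError("peak search window must be positive and ordered")
        for name in ("artefact_blank_ms", "baseline_window_s", "peak_average_ms",
                     "local_baseline_ms", "detect_smooth_ms", "refractory_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.z_group_size < 1:
            raise ConfigurationError("z_group_size must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peak_search_ms"] = list(d["peak_search_ms"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "peak_search_ms" in d:
            d["peak_search_ms"] = tuple(d["peak_search_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        """Short stable digest identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stamp(self, table: pd.DataFrame) -> pd.DataFrame:
        """Attach the config hash and seed to a tidy results table."""
        out = table.copy()
        out["config_hash"] = self.hash
        out["seed"] = self.seed
        return out


# ---------------------------------------------------------------------------
# sweep I/O
# ---------------------------------------------------------------------------

def write_sweeps(sweeps: Sequence[SweepRecord], path: str | Path) -> None:
    """Write sweeps to an HDF5 store, one group per sweep.

    Layout: ``/sweeps/<i>/current`` (float64 pA) with attributes
    ``sampling_rate_hz``, ``stim_times_s``, ``epoch``, ``timestamp_s``,
    ``holding_mv``, ``sweep_index`` and, when present, ``test_pulse``
    (onset, duration, step in mV).
    """
    with h5py.File(path, "w") as fh:
        root = fh.create_group("sweeps")
        for i, sw in enumerate(sweeps):
            g = root.create_group(str(i))
            g.create_dataset("current", data=sw.samples, dtype=np.float64)
            g.attrs["sampling_rate_hz"] = float(sw.sampling_rate)
            g.attrs["stim_times_s"] = np.asarray(sw.stim_times, dtype=np.float64)
            g.attrs["epoch"] = sw.epoch
            g.attrs["timestamp_s"] = float(sw.timestamp)
            g.attrs["holding_mv"] = float(sw.holding_potential)
            g.attrs["sweep_index"] = int(sw.sweep_index)
            if sw.test_pulse is not None:
                tp = sw.test_pulse
                g.attrs["test_pulse"] = np.array(
                    [tp.onset_s, tp.duration_s, tp.step_mv], dtype=np.float64
                )


def _sweep_from_group(g: h5py.Group) -> SweepRecord:
    required = ("sampling_rate_hz", "stim_times_s", "epoch")
    for name in required:
        if name not in g.attrs:
            raise FormatError(f"sweep group {g.name!r} missing attribute {name!r}")
    if "current" not in g:
        raise FormatError(f"sweep group {g.name!r} missing dataset 'current'")
    tp = None
    if "test_pulse" in g.attrs:
        onset, dur, step = (float(v) for v in g.attrs["test_pulse"])
        tp = TestPulse(onset, dur, step)
    epoch = g.attrs["epoch"]
    if isinstance(epoch, bytes):
        epoch = epoch.decode()
    return SweepRecord(
        samples=np.asarray(g["current"], dtype=np.float64),
        sampling_rate=float(g.attrs["sampling_rate_hz"]),
        stim_times=tuple(float(t) for t in np.atleast_1d(g.attrs["stim_times_s"])),
        test_pulse=tp,
        holding_potential=float(g.attrs.get("holding_mv", -70.0)),
        sweep_index=int(g.attrs.get("sweep_index", 0)),
        epoch=str(epoch),
        timestamp=float(g.attrs.get("timestamp_s", 0.0)),
    )


def read_sweeps(path: str | Path, format: str | None = None) -> list[SweepRecord]:
    """Read sweeps from HDF5 (one group per sweep) or single-sweep CSV.

    The CSV dialect is two columns ``time_s,current_pA``; the sampling rate
    is inferred from the time-column spacing.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    format = format.lower()
    if format in ("hdf5", "h5"):
        with h5py.File(path, "r") as fh:
            if "sweeps" not in fh:
                raise FormatError("HDF5 store missing group 'sweeps'")
            keys = sorted(fh["sweeps"], key=int)
            return [_sweep_from_group(fh["sweeps"][k]) for k in keys]
    if format == "csv":
        df = pd.read_csv(path)
        for col in ("time_s", "current_pA"):
            if col not in df.columns:
                raise FormatError(f"CSV missing column {col!r}")
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise FormatError("time_s column must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise FormatError("time_s column must be uniformly sampled")
        return [
            SweepRecord(
                samples=df["current_pA"].to_numpy(dtype=float),
                sampling_rate=1.0 / dt[0],
            )
        ]
    raise FormatError(f"unknown sweep format {format!r}")


def write_sweep_csv(sweep: SweepRecord, path: str | Path) -> None:
    """Write a single sweep as ``time_s,current_pA`` CSV."""
    pd.DataFrame(
        {"time_s": sweep.time, "current_pA": sweep.samples}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image-stack I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a JSON sidecar.

    Pages are ordered channel-major (all z of channel 0, then channel 1, ...);
    the sidecar records the channel-role map and voxel geometry.
    """
    import tifffile

    path = Path(path)
    vox = stack.voxels
    pages = vox.reshape(-1, vox.shape[2], vox.shape[3])
    tifffile.imwrite(path, pages)
    meta = {
        "channels": {role: int(c) for role, c in stack.channel_roles.items()},
        "n_channels": int(vox.shape[0]),
        "n_z": int(vox.shape[1]),
        "pixel_size_um": float(stack.pixel_size_xy),
        "z_step_um": float(stack.z_step),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Raises
    ------
    ConfigurationError
        If the sidecar's channel-role map is missing or incomplete.
    """
    import tifffile

    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigurationError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("channels", "n_channels", "n_z", "pixel_size_um", "z_step_um"):
        if key not in meta:
            raise ConfigurationError(f"sidecar missing field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    c, z = int(meta["n_channels"]), int(meta["n_z"])
    if pages.shape[0] != c * z:
        raise FormatError(
            f"TIFF has {pages.shape[0]} pages, expected {c * z} (= channels x z)"
        )
    vox = pages.reshape(c, z, pages.shape[1], pages.shape[2])
    return ImageStack(
        voxels=vox,
        pixel_size_xy=float(meta["pixel_size_um"]),
        z_step=float(meta["z_step_um"]),
        channel_roles={str(k): int(v) for k, v in meta["channels"].items()},
    )
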