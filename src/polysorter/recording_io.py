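"""Raw multichannel recording I/O and optional preprocessing.

Recordings are flat little-endian int16 binaries, channel-interleaved
(sample-major), with a YAML sidecar carrying channel count, dtype, gain
[uV/LSB], sampling interval [us], site positions [um] and the masked
channel list.  In memory a recording is a float64 ``channels x samples``
matrix in microvolts.

Masked (dead) channels are stored as zeros and excluded from every
downstream statistic: the common mean, spatial-smoothing weights, noise
estimation and event detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Gaussian-sigma per unit median absolute deviation: 1 / Phi^-1(0.75).
MAD_TO_SIGMA = 0.6745


@dataclass(frozen=True)
class ProbeGeometry:
    """Electrode site layout.

    Parameters
    ----------
    positions : (n_channels, 2) array
        Site (x, y) coordinates in micrometers.
    masked : frozenset of int
        Dead channels (0-based), excluded from all statistics.
    neighbor_radius_um : float
        Channels within this center-to-center distance of channel ``n``
        form its immediate-neighbor set ``Z_n``.
    """

    positions: np.ndarray
    masked: frozenset = field(default_factory=frozenset)
    neighbor_radius_um: float = 100.0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("site positions must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "masked", frozenset(int(m) for m in self.masked))
        bad = [m for m in self.masked if not 0 <= m < len(pos)]
        if bad:
            raise ValueError(f"masked channels outside probe: {bad}")

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    @property
    def live_channels(self) -> np.ndarray:
        """Non-masked channel indices, ascending."""
        return np.array(
            [c for c in range(self.n_channels) if c not in self.masked], dtype=int
        )

    def distance(self, n: int, m: int) -> float:
        return float(np.hypot(*(self.positions[n] - self.positions[m])))

    def neighbors(self, n: int) -> np.ndarray:
        """Immediate neighbor set Z_n: live channels within the radius, n excluded."""
        d = np.hypot(*(self.positions - self.positions[n]).T)
        mask = (d <= self.neighbor_radius_um) & (d > 0)
        for m in self.masked:
            mask[m] = False
        return np.flatnonzero(mask)


@dataclass
class VoltageRecord:
    """A ``channels x samples`` voltage matrix [uV] plus sampling metadata."""

    V: np.ndarray
    dt_us: float
    geometry: ProbeGeometry

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=np.float64)
        if self.V.ndim != 2:
            raise ValueError("V must be 2-D (channels x samples)")
        if self.V.shape[0] != self.geometry.n_channels:
            raise ValueError("channel count mismatch with geometry")
        if self.V.shape[1] < 1:
            raise ValueError("need at least one sample")
        if self.dt_us <= 0:
            raise ValueError("dt must be positive")
        if self.geometry.masked:
            self.V[list(self.geometry.masked), :] = 0.0

    @property
    def n_channels(self) -> int:
        return self.V.shape[0]

    @property
    def n_samples(self) -> int:
        return self.V.shape[1]

    def copy(self) -> "VoltageRecord":
        return VoltageRecord(self.V.copy(), self.dt_us, self.geometry)


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-channel noise scale [uV]; zeros only on masked/constant channels."""

    sigma_uV: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sigma_uV, dtype=float)
        if np.any(s < 0):
            raise ValueError("noise scale must be nonnegative")
        object.__setattr__(self, "sigma_uV", s)


# ---------------------------------------------------------------------------
# file format

def _metadata_dict(record: VoltageRecord, gain_uV: float) -> dict:
    g = record.geometry
    return {
        "n_channels": int(record.n_channels),
        "dtype": "int16",
        "gain_uV": float(gain_uV),
        "dt_us": float(record.dt_us),
        "positions": [[float(x), float(y)] for x, y in g.positions],
        "masked": sorted(int(m) for m in g.masked),
        "neighbor_radius_um": float(g.neighbor_radius_um),
    }


def write_recording(record: VoltageRecord, path, metadata_path=None, gain_uV: float = 0.25):
    """Write int16 flat binary (sample-major interleave) plus YAML sidecar."""
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(".yaml")
    counts = np.round(record.V / gain_uV)
    if np.any(np.abs(counts) > 32767):
        warnings.warn("voltage exceeds int16 range at this gain; clipping")
        counts = np.clip(counts, -32768, 32767)
    counts.astype("<i2").T.tofile(path)  # interleaved: sample-major
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(_metadata_dict(record, gain_uV), fh)


def read_recording(path, metadata_path=None) -> VoltageRecord:
    """Read a flat binary + sidecar pair written by :func:`write_recording`."""
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(".yaml")
    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("n_channels", "dtype", "gain_uV", "dt_us", "positions"):
        if key not in meta:
            raise ValueError(f"sidecar missing required key {key!r}")
    if meta["dtype"] != "int16":
        raise ValueError(f"unknown sample encoding {meta['dtype']!r}")
    n_ch = int(meta["n_channels"])
    raw = np.fromfile(path, dtype="<i2")
    if raw.size % n_ch != 0:
        raise ValueError(
            f"file length {raw.size} samples not divisible by {n_ch} channels"
        )
    V = raw.reshape(-1, n_ch).T.astype(np.float64) * float(meta["gain_uV"])
    geometry = ProbeGeometry(
        positions=np.asarray(meta["positions"], dtype=float),
        masked=frozenset(meta.get("masked", [])),
        neighbor_radius_um=float(meta.get("neighbor_radius_um", 100.0)),
    )
    return VoltageRecord(V, float(meta["dt_us"]), geometry)


# ---------------------------------------------------------------------------
# preprocessing

def remove_common_mean(record: VoltageRecord) -> VoltageRecord:
    """Subtract the across-channel mean at each sample (common-average reference).

    The mean is taken over non-masked channels only; masked channels stay zero.
    """
    live = record.geometry.live_channels
    if len(live) < 2:
        raise ValueError("need at least 2 non-masked channels")
    out = record.copy()
    mean = out.V[live].mean(axis=0)
    out.V[live] -= mean
    return out


def temporal_smooth(record: VoltageRecord, passes: int = 1) -> VoltageRecord:
    """Repeatedly convolve each channel with the (0.25, 0.5, 0.25) kernel.

    Endpoints are handled by edge replication.  Repetition approximates a
    Gaussian low-pass whose width grows with the number of passes.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    out = record.copy()
    live = record.geometry.live_channels
    for _ in range(passes):
        V = out.V[live]
        padded = np.pad(V, ((0, 0), (1, 1)), mode="edge")
        out.V[live] = 0.5 * V + 0.25 * padded[:, 2:] + 0.25 * padded[:, :-2]
    return out


def spatial_smooth(record: VoltageRecord, sigma_um: float) -> VoltageRecord:
    """Average across channels with Gaussian weights of inter-site distance.

    Weights are normalized to sum to 1 over non-masked channels, so a
    spatially uniform signal is preserved exactly.
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be positive")
    g = record.geometry
    live = g.live_channels
    pos = g.positions[live]
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=-1)
    W = np.exp(-d2 / (2.0 * sigma_um**2))
    W /= W.sum(axis=1, keepdims=True)
    out = record.copy()
    out.V[live] = W @ record.V[live]
    return out


def sample_hold_delays(n_boards: int = 2, channels_per_board: int = 32,
                       hold_us: float = 1.0) -> np.ndarray:
    """Per-channel acquisition delays [us] for sequentially multiplexed boards.

    Boards run in parallel; within a board channel ``j`` is sampled ``j``
    holds after channel 0, so the largest pairwise delay is
    ``(channels_per_board - 1) * hold_us``.
    """
    return np.tile(np.arange(channels_per_board) * hold_us, n_boards)


def sample_hold_correct(record: VoltageRecord, delays_us: np.ndarray) -> VoltageRecord:
    """Resample each channel so all channels share a common sample clock.

    A channel acquired ``d`` microseconds late holds the value of time
    ``t + d``; interpolating its trace at ``t - d/dt`` sample offsets
    brings it back onto the nominal clock.  Cubic interpolation with edge
    replication is used (band-limited signals at these sub-sample shifts
    are recovered to well under 1% of amplitude).
    """
    delays_us = np.asarray(delays_us, dtype=float)
    if delays_us.shape != (record.n_channels,):
        raise ValueError("one delay per channel required")
    if np.any(delays_us < 0) or np.any(delays_us >= record.dt_us):
        raise ValueError("delays must lie in [0, dt)")
    from scipy.interpolate import CubicSpline

    out = record.copy()
    t = np.arange(record.n_samples, dtype=float)
    for ch in record.geometry.live_channels:
        d = delays_us[ch] / record.dt_us
        if d == 0.0:
            continue
        spline = CubicSpline(t, record.V[ch])
        out.V[ch] = spline(np.clip(t + d, 0, record.n_samples - 1))
    return out


def estimate_noise(record: VoltageRecord) -> NoiseEstimate:
    """Robust per-channel noise scale: median(|V|) / 0.6745 [uV].

    0.6745 is the 0.75 quantile of the standard normal, so for Gaussian
    noise the estimate equals sigma while remaining insensitive to sparse
    large spikes (unlike the RMS).
    """
    if record.n_samples < 100:
        warnings.warn("fewer than 100 samples per channel; noise estimate is crude")
    if record.n_samples == 0:
        raise ValueError("empty channel")
    sigma = np.zeros(record.n_channels)
    live = record.geometry.live_channels
    sigma[live] = np.median(np.abs(record.V[live]), axis=1) / MAD_TO_SIGMA
    return NoiseEstimate(sigma)
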