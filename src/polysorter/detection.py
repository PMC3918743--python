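"""Event detection: thresholded space-time extrema clustered into events.

A *proto-event* is a sample (n, t) whose voltage strictly exceeds the
voltage on all immediate probe neighbors of channel n at time t and on
channel n at t-1 and t+1, and whose magnitude exceeds theta_e times the
channel noise (mirror rule for minima).  A single spike usually fires
several proto-events on adjacent channels; these are coalesced into one
*event* by running the gradient-ascent clusterer on the proto-event
(x, y, t) coordinates, with the time axis scaled so one time kernel
width equals one spatial kernel width.  The resulting event takes the
time of its largest-amplitude proto-event and the channel closest to
the converged scout position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import waveforms as wf
from .gac import GACParams, gac_run
from .recording_io import NoiseEstimate, VoltageRecord

#: default proto-event clustering scales: one site spacing / one spike width
DEFAULT_SPACE_SCALE_UM = 60.0
DEFAULT_TIME_SCALE_US = 250.0


@dataclass
class ProtoEvents:
    """Columnar set of proto-events."""

    channel: np.ndarray       # int
    t: np.ndarray             # int sample index
    amplitude: np.ndarray     # uV, signed
    polarity: np.ndarray      # +1 / -1

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class EventTable:
    """Columnar set of detected events with split integer/fraction times."""

    channel: np.ndarray                     # n_i
    t: np.ndarray                           # integer sample time t_i
    frac: np.ndarray                        # delta_i in [0, 1)
    amplitude: np.ndarray                   # uV of the dominant proto-event
    flagged: np.ndarray = field(default=None)

    def __post_init__(self):
        self.channel = np.asarray(self.channel, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        self.frac = np.asarray(self.frac, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.flagged is None:
            self.flagged = np.zeros(len(self.t), dtype=bool)
        if np.any(self.frac < 0) or np.any(self.frac >= 1):
            raise ValueError("fractional offsets must lie in [0, 1)")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def times(self) -> np.ndarray:
        """Continuous sample times t_i + delta_i."""
        return self.t + self.frac

    def set_times(self, total: np.ndarray, subset=None) -> None:
        total = np.asarray(total, dtype=float)
        t_int = np.floor(total).astype(np.int64)
        if subset is None:
            self.t, self.frac = t_int, total - t_int
        else:
            self.t[subset] = t_int
            self.frac[subset] = total - t_int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "event_id": np.arange(len(self)),
            "channel": self.channel,
            "t_integer": self.t,
            "delta_frac": self.frac,
            "amplitude_uV": self.amplitude,
            "flagged": self.flagged.astype(int),
        })


def detect_proto_events(record: VoltageRecord, noise: NoiseEstimate,
                        theta_e: float = 5.0) -> ProtoEvents:
    """Register thresholded local space-time maxima and minima.

    All comparisons are strict, so exact ties never fire twice; masked
    channels neither fire nor take part in neighbor comparisons.
    """
    if theta_e <= 0:
        raise ValueError("theta_e must be positive")
    V = record.V
    g = record.geometry
    chans, ts, amps, pols = [], [], [], []
    for ch in g.live_channels:
        v = V[ch]
        thr = theta_e * noise.sigma_uV[ch]
        nb = g.neighbors(ch)
        for sign in (1, -1):
            s = sign * v
            cand = np.flatnonzero(s > sign * 0 + thr) if thr > 0 else np.flatnonzero(s > 0)
            cand = cand[(cand > 0) & (cand < record.n_samples - 1)]
            if len(cand) == 0:
                continue
            ok = (s[cand] > s[cand - 1]) & (s[cand] > s[cand + 1])
            for m in nb:
                ok &= s[cand] > sign * V[m, cand]
            cand = cand[ok]
            chans.append(np.full(len(cand), ch))
            ts.append(cand)
            amps.append(v[cand])
            pols.append(np.full(len(cand), sign))
    if not chans:
        z = np.array([], dtype=int)
        return ProtoEvents(z, z, z.astype(float), z)
    channel = np.concatenate(chans)
    t = np.concatenate(ts)
    amplitude = np.concatenate(amps)
    polarity = np.concatenate(pols)
    order = np.lexsort((channel, t))  # time-major, then channel: deterministic
    return ProtoEvents(channel[order], t[order], amplitude[order], polarity[order])


def cluster_proto_events(proto: ProtoEvents, record: VoltageRecord,
                         space_scale_um: float = DEFAULT_SPACE_SCALE_UM,
                         time_scale_us: float = DEFAULT_TIME_SCALE_US,
                         params: GACParams | None = None) -> EventTable:
    """Merge proto-events belonging to one spike via GAC in space-time.

    Coordinates are (x [um], y [um], t [us] * space/time scale) so an
    isotropic kernel of width ``space_scale_um`` spans one time scale
    along the time axis.  Proto-events separated by a temporal gap of
    more than 10 kernel widths cannot interact (Gaussian weight < e^-50)
    and are clustered independently for speed.
    """
    if space_scale_um <= 0 or time_scale_us <= 0:
        raise ValueError("scales must be positive")
    if len(proto) == 0:
        z = np.array([], dtype=int)
        return EventTable(z, z, z.astype(float), z.astype(float))
    params = params or GACParams(
        stationary_delta=1e-3 * space_scale_um, n_min=1)
    g = record.geometry
    t_us = proto.t.astype(float) * record.dt_us
    t_scaled = t_us * (space_scale_um / time_scale_us)
    coords = np.column_stack([g.positions[proto.channel], t_scaled])
    order = np.argsort(proto.t, kind="stable")
    gap = 10.0 * time_scale_us * (space_scale_um / time_scale_us)
    breaks = np.flatnonzero(np.diff(t_scaled[order]) > gap)
    chunks = np.split(order, breaks + 1)
    ev_ch, ev_t, ev_amp = [], [], []
    for chunk in chunks:
        labels, scouts = gac_run(coords[chunk], space_scale_um, params)
        for k in range(labels.max() + 1):
            members = chunk[labels == k]
            rep = members[np.argmax(np.abs(proto.amplitude[members]))]
            # channel closest to the converged scout position
            sx, sy = scouts[k][:2]
            d = np.hypot(g.positions[g.live_channels, 0] - sx,
                         g.positions[g.live_channels, 1] - sy)
            ev_ch.append(int(g.live_channels[np.argmin(d)]))
            ev_t.append(int(proto.t[rep]))
            ev_amp.append(float(proto.amplitude[rep]))
    order = np.lexsort((ev_ch, ev_t))
    ev_t = np.asarray(ev_t)[order]
    ev_ch = np.asarray(ev_ch)[order]
    ev_amp = np.asarray(ev_amp)[order]
    return EventTable(ev_ch, ev_t, np.zeros(len(ev_t)), ev_amp)


def trim_edge_events(events: EventTable, record: VoltageRecord,
                     margin_samples: int | None = None) -> EventTable:
    """Drop events whose template window would leave the record."""
    if margin_samples is None:
        margin_samples = max(-wf.TAU_MIN, wf.TAU_MAX) + wf.HALF_WIDTH + 8
    keep = (events.t >= margin_samples) & \
           (events.t < record.n_samples - margin_samples)
    return EventTable(events.channel[keep], events.t[keep],
                      events.frac[keep], events.amplitude[keep],
                      events.flagged[keep])


def align_events_to_trough(events: EventTable, record: VoltageRecord,
                           window_ms: float = 0.5) -> EventTable:
    """Move each event time to the interpolated minimum on its channel.

    The most negative interpolated sample within +/- ``window_ms`` of
    the current time becomes the new time (integer + fractional parts).
    Events whose window would leave the record are clamped and flagged,
    as are all-positive waveforms (trough = least-positive point).
    """
    if len(events) == 0:
        return events
    half = window_ms * 1000.0 / record.dt_us
    n_fine = int(round(half * wf.GRID))
    fine = np.arange(-n_fine, n_fine + 1) / wf.GRID
    times = events.times
    ok = wf.valid_window(record, times, taus=np.array([-half, half]))
    clamped = ~ok
    new_total = times.copy()
    flagged = events.flagged.copy()
    for start in range(0, len(events), 4096):
        sl = slice(start, min(start + 4096, len(events)))
        idx = np.flatnonzero(ok[sl]) + start
        if len(idx) == 0:
            continue
        # per-event channel: interpolate each event on its own channel
        for ch in np.unique(events.channel[idx]):
            sel = idx[events.channel[idx] == ch]
            F = wf.extract_waveforms(record, np.array([ch]), times[sel], fine)
            best = np.argmin(F[:, 0, :], axis=1)
            new_total[sel] = wf._snap(times[sel]) + fine[best]
            flagged[sel] |= F[np.arange(len(sel)), 0, best] > 0
    flagged |= clamped
    out = EventTable(events.channel.copy(), events.t.copy(),
                     events.frac.copy(), events.amplitude.copy(), flagged)
    out.set_times(new_total)
    return out
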