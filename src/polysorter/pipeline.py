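"""Pipeline orchestration: configuration, sorting session, stages, report.

The sorter runs five stages: (a) event detection and trough alignment;
(b) formation of channel-based clusters (all events assigned to one
electrode channel); (c) recursive splitting of each channel cluster
into unsplittable sub-clusters; (d) automated pairwise merging and
event reassignment, ending with a distinctness status per cluster;
(e) optional application of a declarative user decision file.

Every stage is a pure function of (inputs, config, seed); a single
global seed fans out to the per-stage random generators, so reruns with
identical inputs reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, features as ft, gac, pairwise, recording_io, waveforms as wf
from .detection import EventTable
from .gac import GACParams
from .recording_io import VoltageRecord
from .waveforms import Cluster


@dataclass
class PipelineConfig:
    """Every tunable parameter of the sort, with the defaults used throughout."""

    # preprocessing
    car: bool = False                  # common-average reference
    smooth_passes: int = 0
    spatial_sigma_um: float | None = None
    sh_correct: bool = False
    # detection
    theta_e: float = 5.0
    det_space_scale_um: float = detection.DEFAULT_SPACE_SCALE_UM
    det_time_scale_us: float = detection.DEFAULT_TIME_SCALE_US
    # alignment
    tau0: int = 38
    ls_range: float = 5.0
    ls_rounds: int = 2
    remove_flagged: bool = False
    # clustering
    sigma1: float = 5.0
    sigma_growth: float = 1.10
    theta_c: int = 8
    theta_n: float = 5.0
    n_min: int = 50
    split_strategy: str = "best-score"
    n_pcs_split: int = 3
    # seeds
    seed: int = 0

    def gac_params(self) -> GACParams:
        return GACParams(sigma1=self.sigma1, growth=self.sigma_growth,
                         theta_N=self.theta_n, theta_c=self.theta_c,
                         n_min=self.n_min, split_strategy=self.split_strategy)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.theta_e <= 0:
            raise ValueError("theta_e must be positive")
        if self.smooth_passes < 0:
            raise ValueError("smooth_passes must be >= 0")
        if self.spatial_sigma_um is not None and self.spatial_sigma_um <= 0:
            raise ValueError("spatial_sigma_um must be positive")
        self.gac_params()  # validates the clustering block


class SortSession:
    """Mutable state of one sorting run: record, events, clusters."""

    def __init__(self, record: VoltageRecord, events: EventTable,
                 config: PipelineConfig):
        self.record = record
        self.events = events
        self.config = config
        self.clusters: dict[int, Cluster] = {}
        self._next_id = 1
        self.rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0])

    # -- cluster bookkeeping -------------------------------------------------

    def new_cluster(self, event_indices: np.ndarray) -> int:
        cid = self._next_id
        self._next_id += 1
        self.clusters[cid] = Cluster(id=cid, event_indices=event_indices)
        return cid

    def delete_cluster(self, cid: int) -> None:
        self.clusters.pop(cid, None)

    def labels(self) -> np.ndarray:
        """Per-event cluster id; 0 = unassigned/deleted."""
        lab = np.zeros(len(self.events), dtype=np.int64)
        for cid, cl in self.clusters.items():
            lab[cl.event_indices] = cid
        return lab

    # -- template maintenance ------------------------------------------------

    def recompute_cluster(self, cid: int, ls_rounds: int | None = None,
                          template_mean_align: bool = False) -> None:
        """Template + channel assignment + least-squares realignment rounds.

        Each round realigns every event to the current template and then
        recomputes the template; further rounds produce increasingly
        small changes.  Optionally finishes with the second-derivative
        template-mean alignment used before pairwise comparison.
        """
        cl = self.clusters[cid]
        if cl.n_events == 0:
            self.delete_cluster(cid)
            return
        rounds = self.config.ls_rounds if ls_rounds is None else ls_rounds
        self._set_template(cl)
        for _ in range(rounds):
            times = self.events.times[cl.event_indices]
            new_times, _, flagged = wf.align_least_squares(
                self.record, cl.template, times, search=self.config.ls_range)
            ok = wf.valid_window(self.record, new_times)
            new_times[~ok] = times[~ok]
            self.events.set_times(new_times, subset=cl.event_indices)
            self.events.flagged[cl.event_indices] |= flagged
            if self.config.remove_flagged and np.any(flagged):
                cl.event_indices = cl.event_indices[~flagged]
                if cl.n_events == 0:
                    self.delete_cluster(cid)
                    return
            self._set_template(cl)
        if template_mean_align:
            # the noise floor of the template contributes second-difference
            # weight centered on the window, diluting tau_bar below the true
            # offset; iterate to the fixed point so every cluster lands on
            # the same canonical center regardless of its size or SNR
            for _ in range(12):
                tau_bar = wf.align_template_mean(
                    self.record, self.events.times[cl.event_indices],
                    cl.template.P, tau0=self.config.tau0, rng=self.rng)
                if abs(tau_bar) < 0.02:
                    break
                total = self.events.times[cl.event_indices] + tau_bar
                ok = wf.valid_window(self.record, total)
                total[~ok] = self.events.times[cl.event_indices][~ok]
                self.events.set_times(total, subset=cl.event_indices)
            self._set_template(cl)

    def _set_template(self, cl: Cluster) -> None:
        times = self.events.times[cl.event_indices]
        tpl = wf.compute_template(self.record, times, rng=self.rng)
        cl.template = wf.assign_channels(tpl, self.record.geometry)

    # -- features ------------------------------------------------------------

    def cluster_features(self, cluster: Cluster, n_components: int = 3):
        if cluster.template is None or len(cluster.template.P) == 0:
            return None
        if cluster.n_events < n_components + 1:
            return None
        times = self.events.times[cluster.event_indices]
        W = wf.extract_waveforms(self.record, cluster.template.P, times)
        return ft.waveform_features(W, cluster.template.P, wf.TAUS,
                                    n_components=n_components)

    def indices_features(self, idx: np.ndarray, n_components: int = 3):
        """Features of an ad-hoc event set (used when recombining a pair)."""
        if len(idx) < n_components + 1:
            return None
        times = self.events.times[idx]
        tpl = wf.compute_template(self.record, times, rng=self.rng)
        tpl = wf.assign_channels(tpl, self.record.geometry)
        if len(tpl.P) == 0:
            return None
        W = wf.extract_waveforms(self.record, tpl.P, times)
        return ft.waveform_features(W, tpl.P, wf.TAUS, n_components=n_components)

    # -- structural edits used by the split and merge stages -------------------

    def split_cluster(self, cid: int, split: np.ndarray, remainder: np.ndarray,
                      deleted: np.ndarray) -> int | None:
        """Split off a sub-cluster; returns the new cluster id (or None)."""
        cl = self.clusters[cid]
        new_id = None
        if len(split) >= self.config.n_min:
            new_id = self.new_cluster(split)
            self.recompute_cluster(new_id)
        if len(remainder) >= self.config.n_min:
            cl.event_indices = remainder
            cl.status = "unsplittable-pending"
            self.recompute_cluster(cid)
        else:
            self.delete_cluster(cid)
        return new_id

    def merge_clusters(self, k: int, l: int) -> int:
        """Merge two clusters; the lower id survives and is re-templated."""
        keep, drop = min(k, l), max(k, l)
        merged = np.concatenate([self.clusters[keep].event_indices,
                                 self.clusters[drop].event_indices])
        self.clusters[keep].event_indices = np.sort(merged)
        self.delete_cluster(drop)
        self.recompute_cluster(keep, template_mean_align=True)
        self.clusters[keep].status = "unsplittable"
        return keep

    def reassign_pair(self, k: int, l: int, a: np.ndarray, b: np.ndarray,
                      deleted: np.ndarray) -> None:
        """Replace the memberships of a pair after a combined re-split."""
        self.clusters[k].event_indices = np.sort(a)
        self.clusters[l].event_indices = np.sort(b)
        self.recompute_cluster(k, template_mean_align=True)
        self.recompute_cluster(l, template_mean_align=True)


@dataclass
class SortResult:
    """Output bundle of one sorting run."""

    events: EventTable
    labels: np.ndarray
    clusters: dict
    measures: dict
    config: PipelineConfig
    n_events_detected: int
    n_initial_clusters: int = 0
    n_pairs_examined: int = 0

    def cluster_summary(self) -> pd.DataFrame:
        recs = []
        for cid in sorted(self.clusters):
            cl = self.clusters[cid]
            t = cl.template
            recs.append({
                "cluster": cid, "n_events": cl.n_events, "status": cl.status,
                "center_channel": t.center_channel if t else -1,
                "x_um": round(t.x, 2) if t else np.nan,
                "y_um": round(t.y, 2) if t else np.nan,
                "channels": ";".join(map(str, t.P)) if t is not None else "",
            })
        return pd.DataFrame(recs)

    def pair_table(self) -> pd.DataFrame:
        recs = []
        for (k, l), pm in sorted(self.measures.items()):
            recs.append({
                "k": k, "l": l, "d_um": round(pm.d_um, 2),
                "overlap_flag": int(pm.spatially_overlapping),
                "q_uV": round(pm.q_uV, 3) if np.isfinite(pm.q_uV) else np.nan,
                "o": round(pm.o, 4) if np.isfinite(pm.o) else np.nan,
                "dt_status": int(pm.distinct()),
            })
        return pd.DataFrame(recs,
                            columns=["k", "l", "d_um", "overlap_flag",
                                     "q_uV", "o", "dt_status"])

    def template_table(self) -> pd.DataFrame:
        """Long-format export of every cluster's template and SD."""
        recs = []
        for cid in sorted(self.clusters):
            t = self.clusters[cid].template
            if t is None:
                continue
            for ch in t.P:
                row = t.row_of(ch)
                for j in range(t.T.shape[1]):
                    recs.append({"cluster": cid, "channel": int(ch),
                                 "tau": int(j - 10),
                                 "T_uV": round(float(t.T[row, j]), 4),
                                 "SD_uV": round(float(t.SD[row, j]), 4)})
        return pd.DataFrame(recs,
                            columns=["cluster", "channel", "tau", "T_uV",
                                     "SD_uV"])

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ev = self.events.to_frame()
        ev["cluster"] = self.labels
        ev.to_csv(out / "events.csv", index=False)
        self.cluster_summary().to_csv(out / "clusters.csv", index=False)
        self.pair_table().to_csv(out / "pairs.csv", index=False)
        self.template_table().to_csv(out / "templates.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump({"config": dataclasses.asdict(self.config),
                       "n_events_detected": int(self.n_events_detected),
                       "n_initial_clusters": int(self.n_initial_clusters),
                       "n_pairs_examined": int(self.n_pairs_examined)},
                      fh, indent=2)


def pair_count(n_clusters: int) -> int:
    """Number of unordered cluster pairs to examine (4950 for 100 clusters)."""
    return n_clusters * (n_clusters - 1) // 2


def preprocess(record: VoltageRecord, config: PipelineConfig) -> VoltageRecord:
    if config.car:
        record = recording_io.remove_common_mean(record)
    if config.smooth_passes > 0:
        record = recording_io.temporal_smooth(record, config.smooth_passes)
    if config.spatial_sigma_um:
        record = recording_io.spatial_smooth(record, config.spatial_sigma_um)
    if config.sh_correct:
        delays = recording_io.sample_hold_delays(
            n_boards=max(1, record.n_channels // 32) or 1,
            channels_per_board=min(record.n_channels, 32))
        record = recording_io.sample_hold_correct(record, delays[:record.n_channels])
    return record


def detect_events(record: VoltageRecord, config: PipelineConfig) -> EventTable:
    noise = recording_io.estimate_noise(record)
    proto = detection.detect_proto_events(record, noise, theta_e=config.theta_e)
    events = detection.cluster_proto_events(
        proto, record, space_scale_um=config.det_space_scale_um,
        time_scale_us=config.det_time_scale_us)
    events = detection.trim_edge_events(events, record)
    return detection.align_events_to_trough(events, record)


def form_channel_clusters(session: SortSession) -> None:
    """One initial cluster per non-masked channel with enough events.

    Channels with fewer than 4 events (too few for any pairwise
    comparison) are left unclustered.  Clusters below the minimum split
    size are marked unsplittable immediately; they stay in play so the
    merge stage can recombine fragments of units straddling two
    channels, and are deleted at the end if still below minimum size.
    """
    for ch in session.record.geometry.live_channels:
        idx = np.flatnonzero(session.events.channel == ch)
        if len(idx) < 4:
            continue
        cid = session.new_cluster(idx)
        session.recompute_cluster(cid)
        if cid in session.clusters and len(idx) < session.config.n_min:
            session.clusters[cid].status = "unsplittable"


def run_sort(record: VoltageRecord, config: PipelineConfig | None = None,
             decisions=None) -> SortResult:
    """Execute the full five-stage sort on a recording."""
    config = config or PipelineConfig()
    config.validate()
    record = preprocess(record, config)
    events = detect_events(record, config)
    session = SortSession(record, events, config)
    form_channel_clusters(session)
    gac.split_channel_clusters(session, config.gac_params(),
                               n_components=config.n_pcs_split)
    n_initial = len(session.clusters)
    # template-mean alignment readies every stable cluster for comparison
    for cid in list(session.clusters):
        session.recompute_cluster(cid, ls_rounds=0, template_mean_align=True)
    measures = pairwise.auto_merge_and_reassign(session, params=config.gac_params())
    # the minimum-size rule applies to whatever survives merging
    dropped = [c for c, cl in session.clusters.items()
               if cl.n_events < config.n_min]
    for cid in dropped:
        session.delete_cluster(cid)
    if dropped:
        measures = {k: v for k, v in measures.items()
                    if k[0] in session.clusters and k[1] in session.clusters}
        pairwise.assign_statuses(session, measures)
    if decisions is not None:
        measures = pairwise.apply_user_decisions(session, decisions, measures)
    return SortResult(events=session.events, labels=session.labels(),
                      clusters=session.clusters, measures=measures,
                      config=config, n_events_detected=len(events),
                      n_initial_clusters=n_initial,
                      n_pairs_examined=pair_count(len(session.clusters)))


def report(result: SortResult) -> pd.DataFrame:
    """One-row summary table of a sorting run.

    Columns: detected events, cluster counts before and after the
    pairwise stage (distinct / total), pairs examined, and the
    percentage of detected events carrying a final cluster label.
    """
    if result.n_events_detected == 0:
        return pd.DataFrame()
    n_total = len(result.clusters)
    n_distinct = sum(cl.status == "distinct" for cl in result.clusters.values())
    classified = float(np.mean(result.labels > 0)) * 100.0
    return pd.DataFrame([{
        "events": result.n_events_detected,
        "initial_clusters": result.n_initial_clusters,
        "pairs_examined": result.n_pairs_examined,
        "final_distinct": n_distinct,
        "final_total": n_total,
        "pct_events_classified": round(classified, 2),
    }])
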