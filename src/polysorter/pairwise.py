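"""Pairwise cluster comparison, merging, reassignment and distinctness.

Two complementary similarity measures guide the second sorting stage:

* ``q`` — the RMS voltage difference between two templates over the
  union of their channel sets (channels absent from one template
  contribute zeros), in microvolts.  Symmetric and >= 0.
* ``o`` — a nearest-neighbor overlap index in the common principal
  component (cPC) space of the temporarily merged pair: with ``p_k``
  the fraction of the smaller cluster's points whose nearest neighbor
  comes from its own cluster and ``e = N_k / (N_k + N_l)`` the fully
  mixed expectation, ``o = (1 - p_k) / (1 - e)``.  0 for fully separated
  clusters, ~1 (occasionally slightly more) for fully mixed ones.

A cluster pair passes the distinctness test DT if any of: their channel
sets barely overlap, q > 25 uV, o < 0.05, or the user declared them
distinct.  A cluster is "distinct" only when DT holds against every
other cluster.  The automated stage merges pairs with q < 5 uV and
o > 0.9, and re-clusters pairs with 0.05 <= o < 0.15 to reassign
events, restoring the originals when the combination is unclusterable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import features as ft
from . import waveforms as wf
from .gac import GACParams, decide_split, sigma_sweep

Q_DISTINCT_UV = 25.0
O_DISTINCT = 0.05
Q_MERGE_UV = 5.0
O_MERGE = 0.9
O_RECLUSTER_LO = 0.05
O_RECLUSTER_HI = 0.15
CPC_MAX_POINTS = 2000


@dataclass
class PairMeasures:
    """Similarity measures for a cluster pair (k, l)."""

    k: int
    l: int
    spatially_overlapping: bool
    d_um: float = np.nan
    q_uV: float = np.nan
    o: float = np.nan
    #: RMS template difference after realigning both clusters' events to
    #: the merged template; free of the per-cluster registration noise
    #: that inflates q for fragments of one unit, so the merge rule uses it
    q_aligned_uV: float = np.nan
    user_distinct: bool = False

    def distinct(self) -> bool:
        """The four-rule distinctness test DT(k, l)."""
        if not self.spatially_overlapping:
            return True
        if np.isfinite(self.q_uV) and self.q_uV > Q_DISTINCT_UV:
            return True
        if np.isfinite(self.o) and self.o < O_DISTINCT:
            return True
        return self.user_distinct


def spatial_overlap(P_k: np.ndarray, P_l: np.ndarray) -> bool:
    """Pair overlaps if at least half of either channel set is shared.

    A two-channel template overlaps anything that shares one of its
    channels; a three-channel template does not overlap a template
    sharing only one of the three.
    """
    P_k, P_l = set(map(int, P_k)), set(map(int, P_l))
    if not P_k or not P_l:
        raise ValueError("channel sets must be nonempty")
    shared = len(P_k & P_l)
    return shared >= len(P_k) / 2.0 or shared >= len(P_l) / 2.0


def rms_template_diff(t_k: wf.Template, t_l: wf.Template) -> float:
    """RMS voltage difference q over the union channel set [uV]."""
    union = sorted(set(map(int, t_k.P)) | set(map(int, t_l.P)))
    if not union:
        raise ValueError("empty channel union")
    sq = 0.0
    for ch in union:
        diff = t_k.waveform(ch) - t_l.waveform(ch)
        sq += float(diff @ diff)
    return float(np.sqrt(sq / (wf.N_TAU * len(union))))


def template_center_distance(t_k: wf.Template, t_l: wf.Template) -> float:
    return float(np.hypot(t_k.x - t_l.x, t_k.y - t_l.y))


def nn_same_origin_fraction(points: np.ndarray, origin: np.ndarray,
                            which: int) -> float:
    """Fraction of cluster ``which`` points whose nearest neighbor (self
    excluded, Euclidean) shares their origin."""
    tree = cKDTree(points)
    sel = np.flatnonzero(origin == which)
    _, nn = tree.query(points[sel], k=2)
    return float(np.mean(origin[nn[:, 1]] == which))


def overlap_index(points: np.ndarray, origin: np.ndarray) -> float:
    """Nearest-neighbor overlap index o for a labeled 2-cluster point set."""
    n0, n1 = int(np.sum(origin == 0)), int(np.sum(origin == 1))
    if n0 + n1 < 4 or n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 points per cluster and 4 total")
    small = 0 if n0 <= n1 else 1
    nk = min(n0, n1)
    p_k = nn_same_origin_fraction(points, origin, small)
    e = nk / (n0 + n1)
    return (1.0 - p_k) / (1.0 - e)


def cpc_overlap(session, cid_k: int, cid_l: int,
                rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Overlap index o of two clusters in their common PC space.

    The pair is temporarily merged: a joint template is computed, all
    events are (non-destructively) least-squares realigned to it, the
    variance-ranked points over the joint channel set feed a PCA, and
    the labeled scores in the first two components are compared by
    nearest-neighbor origin counting.  Equal fractions of both clusters
    are subsampled so at most 2000 points enter the comparison.

    Returns ``(o, q_aligned)``: the overlap index and the RMS difference
    [uV] between the two clusters' mean waveforms after the common
    realignment, which cancels the small independent registration
    offsets each cluster's own template alignment leaves behind.
    """
    rng = rng or session.rng
    ck, cl = session.clusters[cid_k], session.clusters[cid_l]
    idx = np.concatenate([ck.event_indices, cl.event_indices])
    origin = np.concatenate([np.zeros(ck.n_events, dtype=int),
                             np.ones(cl.n_events, dtype=int)])
    n_total = len(idx)
    if n_total < 4:
        raise ValueError("need at least 4 events in the pair")
    if n_total > CPC_MAX_POINTS:
        f = CPC_MAX_POINTS / n_total
        keep = []
        for which, cl_obj in ((0, ck), (1, cl)):
            sub = np.flatnonzero(origin == which)
            n_keep = max(2, int(f * len(sub)))
            keep.append(rng.choice(sub, n_keep, replace=False))
        keep = np.sort(np.concatenate(keep))
        idx, origin = idx[keep], origin[keep]
    times = session.events.times[idx]
    merged = wf.compute_template(session.record, times, rng=rng)
    merged = wf.assign_channels(merged, session.record.geometry)
    new_times, _, _ = wf.align_least_squares(session.record, merged, times)
    ok = wf.valid_window(session.record, new_times)
    new_times, origin = new_times[ok], origin[ok]
    W = wf.extract_waveforms(session.record, merged.P, new_times)
    mean_k = W[origin == 0].mean(axis=0)
    mean_l = W[origin == 1].mean(axis=0)
    q_aligned = float(np.sqrt(np.mean((mean_k - mean_l) ** 2)))
    fs = ft.waveform_features(W, merged.P, wf.TAUS, n_components=2)
    return overlap_index(fs.scores, origin), q_aligned


def compute_pair_measures(session, cid_k: int, cid_l: int) -> PairMeasures:
    """All pairwise measures for one cluster pair (o only when overlapping)."""
    t_k = session.clusters[cid_k].template
    t_l = session.clusters[cid_l].template
    pm = PairMeasures(k=cid_k, l=cid_l,
                      spatially_overlapping=spatial_overlap(t_k.P, t_l.P),
                      d_um=template_center_distance(t_k, t_l))
    if pm.spatially_overlapping:
        pm.q_uV = rms_template_diff(t_k, t_l)
        pm.o, pm.q_aligned_uV = cpc_overlap(session, cid_k, cid_l)
    return pm


def distinctness_test(pm: PairMeasures) -> bool:
    return pm.distinct()


def assign_statuses(session, measures: dict) -> None:
    """Mark each cluster distinct only if DT holds against all others."""
    ids = sorted(session.clusters)
    for cid in ids:
        cl = session.clusters[cid]
        ok = all(measures[key].distinct()
                 for key in measures if cid in key)
        cl.status = "distinct" if ok else "ambiguous"


def all_pair_measures(session) -> dict:
    ids = sorted(session.clusters)
    return {(k, l): compute_pair_measures(session, k, l)
            for i, k in enumerate(ids) for l in ids[i + 1:]}


def _refresh_measures(session, measures: dict, changed: set) -> None:
    """Recompute every pair involving a changed cluster; drop dead ids."""
    ids = sorted(session.clusters)
    for key in [k for k in measures
                if k[0] not in session.clusters or k[1] not in session.clusters]:
        del measures[key]
    for cid in changed:
        if cid not in session.clusters:
            continue
        for other in ids:
            if other == cid:
                continue
            key = (min(cid, other), max(cid, other))
            user = measures[key].user_distinct if key in measures else False
            measures[key] = compute_pair_measures(session, *key)
            measures[key].user_distinct = user


def auto_merge_and_reassign(session, measures: dict | None = None,
                            params: GACParams | None = None) -> dict:
    """Automated merging and event reassignment between cluster pairs.

    Iterates until quiescent: (1) merge any spatially overlapping pair
    with an aligned RMS difference < 5 uV and o > 0.9; (2) for pairs
    with 0.05 <= o < 0.15, combine the events and run the stability
    split test — a splittable combination reassigns events between the
    two original cluster ids (outliers in below-minimum sub-clusters
    are deleted), an unclusterable one restores the originals and the
    pair stays ambiguous; (3) a pair that is still ambiguous with
    substantial overlap (o >= 0.15) and near-identical aligned
    waveforms gets the same combined split test, but an unclusterable
    combination now means the pair is a single over-divided unit and is
    merged.  Each pair is combined-and-tested at most once per outer
    loop; every change refreshes all measures involving the changed
    clusters.  Returns the final measure table.
    """
    params = params or session.config.gac_params()
    if measures is None:
        measures = all_pair_measures(session)

    def _merge_q(pm):
        return pm.q_aligned_uV if np.isfinite(pm.q_aligned_uV) else pm.q_uV

    while True:
        changed_any = False
        # -- merge rule
        while True:
            cand = [pm for pm in measures.values()
                    if pm.spatially_overlapping and np.isfinite(_merge_q(pm))
                    and _merge_q(pm) < Q_MERGE_UV and np.isfinite(pm.o)
                    and pm.o > O_MERGE]
            if not cand:
                break
            pm = min(cand, key=_merge_q)
            keep = session.merge_clusters(pm.k, pm.l)
            _refresh_measures(session, measures, {keep})
            changed_any = True
        # -- recombine-and-split rule
        tested = set()
        for key in sorted(measures):
            pm = measures.get(key)
            if pm is None or key in tested:
                continue
            if not (pm.spatially_overlapping and np.isfinite(pm.o)
                    and O_RECLUSTER_LO <= pm.o < O_RECLUSTER_HI):
                continue
            tested.add(key)
            if _recluster_pair(session, pm.k, pm.l, params):
                _refresh_measures(session, measures, {pm.k, pm.l})
                changed_any = True
        # -- over-divided unit rule
        for key in sorted(measures):
            pm = measures.get(key)
            if pm is None or key in tested or pm.distinct():
                continue
            if not (pm.spatially_overlapping and np.isfinite(pm.o)
                    and pm.o >= O_RECLUSTER_HI
                    and np.isfinite(_merge_q(pm))
                    and _merge_q(pm) < Q_MERGE_UV):
                continue
            tested.add(key)
            if _recluster_pair(session, pm.k, pm.l, params):
                _refresh_measures(session, measures, {pm.k, pm.l})
            else:
                keep = session.merge_clusters(pm.k, pm.l)
                _refresh_measures(session, measures, {keep})
            changed_any = True
        if not changed_any:
            break
    assign_statuses(session, measures)
    return measures


def _recluster_pair(session, cid_k: int, cid_l: int, params: GACParams) -> bool:
    """Combine a pair, split-test it, and reassign events on success."""
    ck, cl = session.clusters[cid_k], session.clusters[cid_l]
    idx = np.concatenate([ck.event_indices, cl.event_indices])
    fs = session.indices_features(idx, n_components=3)
    if fs is None:
        return False
    gp = sigma_sweep(fs.scores, params)
    decision = decide_split(gp, params)
    if not decision.splittable:
        return False
    a = idx[decision.split_members]
    b = idx[decision.remainder_members]
    dead = idx[decision.deleted_members]
    if len(b) < params.n_min:
        # degenerate split: nearly everything in one sub-cluster
        return False
    session.reassign_pair(cid_k, cid_l, a, b, dead)
    return True


def apply_user_decisions(session, decisions, measures: dict) -> dict:
    """Apply a declarative review file to the sorted clusters.

    ``decisions`` is an iterable of (k, l, action) with action one of
    'merge', 'merge-and-split', 'declare-distinct' or 'leave', applied
    in order.  Unknown cluster ids raise; conflicting actions on one
    pair raise.  Statuses are recomputed at the end.
    """
    seen = {}
    params = session.config.gac_params()
    for k, l, action in decisions:
        k, l = int(k), int(l)
        key = (min(k, l), max(k, l))
        if key in seen and seen[key] != action:
            raise ValueError(f"conflicting actions for pair {key}")
        seen[key] = action
        if action == "leave":
            continue
        if k not in session.clusters or l not in session.clusters:
            raise KeyError(f"unknown cluster id in pair {key}")
        if action == "declare-distinct":
            if key not in measures:
                measures[key] = compute_pair_measures(session, *key)
            measures[key].user_distinct = True
        elif action == "merge":
            keep = session.merge_clusters(k, l)
            _refresh_measures(session, measures, {keep})
        elif action == "merge-and-split":
            if _recluster_pair(session, k, l, params):
                _refresh_measures(session, measures, {k, l})
        else:
            raise ValueError(f"unknown action {action!r}")
    assign_statuses(session, measures)
    return measures
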