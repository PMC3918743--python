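"""Gradient-ascent clustering (GAC) with scout merging and bandwidth sweep.

Every data point spawns a movable duplicate ("scout") that climbs the
Gaussian kernel density estimate of the fixed data cloud by the
mean-shift update.  After each movement step, scout pairs closer than
the merge distance ``eps`` coalesce (the higher-index scout is deleted
and hands its cluster labels to the lower one), so a single scout ends
up on each density peak carrying the labels of all points whose ascent
paths met there.  A scout counts as stationary once it has moved less
than 0.001 (feature units, i.e. microvolts in PC space) for 25
successive iterations.

Cluster structure is probed at multiple scales by sweeping the kernel
width upward by 10% per step until everything fuses into one cluster.
Sub-clusters are tracked across consecutive widths (same cluster if the
size changed by < theta_N percent and the position moved by < 0.14
sigma); the stability score S of a sub-cluster is the number of sweep
rows its track spans.  A cluster splits only if some score reaches
theta_c; the most stable sub-cluster is then split off at the midpoint
width of its stable range, and sub-clusters below the minimum size have
their events deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass(frozen=True)
class GACParams:
    """Tunable constants of the clustering stage (defaults in microvolts)."""

    sigma1: float = 5.0          # initial kernel width
    growth: float = 1.10         # multiplicative sigma step per sweep row
    theta_N: float = 5.0         # size-change tracking threshold [%]
    theta_c: int = 8             # stability-score threshold for splitting
    n_min: int = 50              # minimum cluster size
    position_factor: float = 0.14  # position tracking threshold, x sigma
    stationary_delta: float = 0.001
    stationary_iters: int = 25
    max_iters: int = 3000
    subsample_target: int = 5000  # density-sum stride m = N // target + 1
    max_sweep_rows: int = 120
    split_strategy: str = "best-score"

    def __post_init__(self):
        if self.sigma1 <= 0 or self.growth <= 1 or self.n_min < 1:
            raise ValueError("invalid GAC parameters")
        if self.split_strategy not in ("best-score", "max-summed-score", "max-count"):
            raise ValueError(f"unknown split strategy {self.split_strategy!r}")
        if self.split_strategy != "best-score":
            raise NotImplementedError(
                "only the best-score split strategy is implemented")


@njit(cache=True)
def _gac_core(points, data, sigma, eps, stat_delta, stat_iters, max_iters):
    """Scout ascent + merging.  Returns (labels, n_clusters, scout_pos)."""
    N, D = points.shape
    nd = data.shape[0]
    K = N
    s = points.copy()
    quiet = np.zeros(N, dtype=np.int64)
    c = np.arange(N)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    eps2 = eps * eps
    it = 0
    while it < max_iters:
        it += 1
        all_frozen = True
        for k in range(K):
            if quiet[k] >= stat_iters:
                continue
            num = np.zeros(D)
            den = 0.0
            for i in range(nd):
                d2 = 0.0
                for d in range(D):
                    diff = data[i, d] - s[k, d]
                    d2 += diff * diff
                w = np.exp(-d2 * inv2s2)
                den += w
                for d in range(D):
                    num[d] += w * (data[i, d] - s[k, d])
            move2 = 0.0
            if den > 0.0:
                for d in range(D):
                    step = num[d] / den
                    s[k, d] += step
                    move2 += step * step
            if move2 < stat_delta * stat_delta:
                quiet[k] += 1
            else:
                quiet[k] = 0
            if quiet[k] < stat_iters:
                all_frozen = False
        # merge pass: ascending index pairs; delete the higher index
        i = 0
        while i < K:
            j = i + 1
            while j < K:
                d2 = 0.0
                for d in range(D):
                    diff = s[i, d] - s[j, d]
                    d2 += diff * diff
                if d2 < eps2:
                    for n in range(N):
                        if c[n] == j:
                            c[n] = i
                        elif c[n] > j:
                            c[n] -= 1
                    for m in range(j, K - 1):
                        for d in range(D):
                            s[m, d] = s[m + 1, d]
                        quiet[m] = quiet[m + 1]
                    K -= 1
                else:
                    j += 1
            i += 1
        if all_frozen:
            break
    return c, K, s[:K].copy()


def gac_run(points: np.ndarray, sigma: float,
            params: GACParams = GACParams()) -> tuple[np.ndarray, np.ndarray]:
    """Partition ``points`` at kernel width ``sigma``.

    Returns ``(labels, scout_positions)`` with labels in 0..K-1.  The
    density sum uses every m-th point (m = N // subsample_target + 1);
    scouts always start from every point.  Deterministic for fixed
    input order: merges scan ascending index pairs.
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    if points.ndim != 2 or len(points) < 1:
        raise ValueError("points must be a non-empty 2-D array")
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite coordinates")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    stride = len(points) // params.subsample_target + 1
    data = np.ascontiguousarray(points[::stride])
    labels, K, scouts = _gac_core(
        points, data, float(sigma), float(sigma),
        params.stationary_delta, params.stationary_iters, params.max_iters)
    return labels, scouts


# ---------------------------------------------------------------------------
# bandwidth sweep and sub-cluster tracking


@dataclass
class SweepRow:
    """One bandwidth step of a clustering pass, sub-clusters size-ranked."""

    m: int
    sigma: float
    labels: np.ndarray          # (N,) size-rank-ordered sub-cluster ids
    sizes: np.ndarray           # (K,) descending
    positions: np.ndarray       # (K, D) mean member coordinates


@dataclass
class GACPass:
    """Record of a full sigma sweep over one set of points."""

    rows: list = field(default_factory=list)
    scores: list = field(default_factory=list)   # per row: (K,) int S values
    tracks: list = field(default_factory=list)   # [(row_idx list, sub_idx list)]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_frame(self):
        """Tabular view mirroring a clustering-pass table (CSV-friendly)."""
        import pandas as pd
        kmax = max(len(r.sizes) for r in self.rows)
        recs = []
        for r, sc in zip(self.rows, self.scores):
            rec = {"m": r.m, "sigma": round(r.sigma, 3), "K": len(r.sizes)}
            for k in range(kmax):
                if k < len(r.sizes):
                    rec[f"C{k + 1}"] = int(r.sizes[k])
                    rec[f"S{k + 1}"] = int(sc[k])
                else:
                    rec[f"C{k + 1}"] = 0
                    rec[f"S{k + 1}"] = 0
            recs.append(rec)
        return pd.DataFrame(recs)


def _rank_by_size(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(len(ids), dtype=np.int64)
    remap[order] = np.arange(len(ids))
    lut = dict(zip(ids.tolist(), remap.tolist()))
    new = np.array([lut[v] for v in labels], dtype=np.int64)
    return new, counts[order]


def sigma_sweep(points: np.ndarray, params: GACParams = GACParams()) -> GACPass:
    """Run GAC at geometrically increasing widths until one cluster remains."""
    points = np.asarray(points, dtype=float)
    gp = GACPass()
    sigma = params.sigma1
    for m in range(1, params.max_sweep_rows + 1):
        labels, _ = gac_run(points, sigma, params)
        labels, sizes = _rank_by_size(labels)
        pos = np.stack([points[labels == k].mean(axis=0)
                        for k in range(len(sizes))])
        gp.rows.append(SweepRow(m=m, sigma=sigma, labels=labels,
                                sizes=sizes, positions=pos))
        if len(sizes) == 1:
            break
        sigma *= params.growth
    track_subclusters(gp, params)
    return gp


def track_subclusters(gp: GACPass, params: GACParams = GACParams()) -> list:
    """Match sub-clusters across consecutive sweep rows and score stability.

    A sub-cluster continues a track from the previous row if its size
    changed by less than ``theta_N`` percent and its position (member
    mean) moved by less than ``position_factor * sigma`` of the current
    row.  Ambiguities resolve to the closest position, each predecessor
    feeding at most one successor.  The score ``S`` of every sub-cluster
    equals the number of rows spanned by its track.
    """
    if gp.n_rows == 0:
        gp.scores, gp.tracks = [], []
        return []
    track_of = [np.full(len(r.sizes), -1, dtype=int) for r in gp.rows]
    tracks: list[tuple[list, list]] = []
    for k in range(len(gp.rows[0].sizes)):
        tracks.append(([0], [k]))
        track_of[0][k] = len(tracks) - 1
    for ri in range(1, gp.n_rows):
        prev, cur = gp.rows[ri - 1], gp.rows[ri]
        pos_tol = params.position_factor * cur.sigma
        # candidate matches: (distance, prev_k, cur_k), greedy nearest-first
        cands = []
        for kc in range(len(cur.sizes)):
            for kp in range(len(prev.sizes)):
                dsize = abs(cur.sizes[kc] - prev.sizes[kp]) / prev.sizes[kp]
                if dsize * 100.0 >= params.theta_N:
                    continue
                dist = np.linalg.norm(cur.positions[kc] - prev.positions[kp])
                if dist < pos_tol:
                    cands.append((dist, kp, kc))
        cands.sort()
        used_prev, used_cur = set(), set()
        for dist, kp, kc in cands:
            if kp in used_prev or kc in used_cur:
                continue
            used_prev.add(kp)
            used_cur.add(kc)
            t = track_of[ri - 1][kp]
            tracks[t][0].append(ri)
            tracks[t][1].append(kc)
            track_of[ri][kc] = t
        for kc in range(len(cur.sizes)):
            if track_of[ri][kc] < 0:
                tracks.append(([ri], [kc]))
                track_of[ri][kc] = len(tracks) - 1
    gp.tracks = tracks
    gp.scores = [np.array([len(tracks[track_of[ri][k]][0])
                           for k in range(len(gp.rows[ri].sizes))], dtype=int)
                 for ri in range(gp.n_rows)]
    return tracks


@dataclass
class SplitDecision:
    """Outcome of the stability test on one cluster's sweep."""

    splittable: bool
    sigma: float = np.nan
    best_score: int = 0
    split_members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    deleted_members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    remainder_members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def decide_split(gp: GACPass, params: GACParams = GACParams()) -> SplitDecision:
    """Split off the most stable sub-cluster, or declare unsplittability.

    If no track reaches a score of ``theta_c`` the cluster is
    unsplittable.  Otherwise the highest-scoring track wins (ties break
    to the larger sub-cluster), the partition at the midpoint row of its
    stable range is adopted, its sub-cluster becomes the split, and any
    sub-cluster smaller than ``n_min`` at that row has its events
    deleted.  Member arrays are positional indices into the point set
    the sweep was run on.
    """
    best_t, best_key = -1, (-1, -1)
    for t, (rows_, subs_) in enumerate(gp.tracks):
        score = len(rows_)
        size = max(gp.rows[ri].sizes[k] for ri, k in zip(rows_, subs_))
        if size < params.n_min:
            # below-minimum sub-clusters are never split off; without this
            # an isolated outlier (size and position trivially stable)
            # would outscore every real sub-cluster
            continue
        if (score, size) > best_key:
            best_key = (score, size)
            best_t = t
    best_score = best_key[0]
    if best_t < 0 or best_score < params.theta_c:
        return SplitDecision(splittable=False, best_score=max(best_score, 0))
    rows_, subs_ = gp.tracks[best_t]
    mid = len(rows_) // 2
    ri, kk = rows_[mid], subs_[mid]
    row = gp.rows[ri]
    split = np.flatnonzero(row.labels == kk)
    small = np.flatnonzero(row.sizes < params.n_min)
    deleted = np.flatnonzero(np.isin(row.labels, small) & (row.labels != kk))
    remainder = np.flatnonzero((row.labels != kk) & ~np.isin(row.labels, small))
    return SplitDecision(splittable=True, sigma=row.sigma,
                         best_score=best_score, split_members=split,
                         deleted_members=deleted, remainder_members=remainder)


def split_channel_clusters(session, params: GACParams | None = None,
                           n_components: int = 3, max_depth: int = 200) -> None:
    """Recursively split every pending cluster until all are unsplittable.

    For each cluster: build PCA features from its events, sweep the
    kernel width, and either mark the cluster unsplittable or split off
    the most stable sub-cluster (deleting below-minimum-size
    sub-clusters).  Both fragments are re-templated, realigned and
    re-featured, and re-enter the queue — removal of a dominant
    sub-cluster frequently reveals new splittable structure in a fresh
    projection of the remainder.
    """
    params = params or session.config.gac_params()
    queue = [cid for cid, cl in session.clusters.items()
             if cl.status == "unsplittable-pending"]
    depth = 0
    while queue and depth < max_depth:
        depth += 1
        cid = queue.pop(0)
        cluster = session.clusters.get(cid)
        if cluster is None or cluster.status == "deleted":
            continue
        if cluster.n_events < params.n_min:
            session.delete_cluster(cid)
            continue
        fs = session.cluster_features(cluster, n_components=n_components)
        if fs is None or fs.scores.shape[1] < 1:
            cluster.status = "unsplittable"
            continue
        gp = sigma_sweep(fs.scores, params)
        decision = decide_split(gp, params)
        if not decision.splittable or \
                len(decision.split_members) == cluster.n_events:
            # nothing would actually leave the cluster
            cluster.status = "unsplittable"
            continue
        idx = cluster.event_indices
        new_id = session.split_cluster(
            cid,
            split=idx[decision.split_members],
            remainder=idx[decision.remainder_members],
            deleted=idx[decision.deleted_members])
        if new_id is not None:
            queue.append(new_id)
        if cid in session.clusters:
            queue.append(cid)
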