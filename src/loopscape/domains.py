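"""Clustering loops into chromatin-domain groups from histone meta-profiles.

Each intrachromosomal interaction is summarized by a matrix of histone
marks x 30 equally sized bins: 10 bins between the two anchors' inner
edges and 10 flanking bins (one loop-length each) on either side.  After
normalization the profiles are clustered with k-means (k = 8) and clusters
that are mirror images of each other (a loop has no intrinsic left/right)
are merged, yielding the final domain groups ordered by median loop
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

N_BINS = 30
N_INNER = 10


class CoverageTrack:
    """Step-function coverage with O(log n) interval sums, per chromosome."""

    def __init__(self, bedgraph: pd.DataFrame):
        self._chroms = {}
        for chrom, sub in bedgraph.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            vals = sub["value"].to_numpy(dtype=float)
            # prefix integral at segment boundaries
            seg = vals * (ends - starts)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            self._chroms[chrom] = (starts, ends, vals, cum)

    def _integral_to(self, chrom, pos):
        starts, ends, vals, cum = self._chroms[chrom]
        pos = np.asarray(pos, dtype=float)
        k = np.searchsorted(ends, pos, side="left")
        k = np.clip(k, 0, len(starts) - 1)
        inside = np.clip(pos - starts[k], 0, ends[k] - starts[k])
        return cum[k] + vals[k] * inside

    def window_sum(self, chrom, start, end) -> np.ndarray:
        """Total signal over [start, end) (vectorized)."""
        if chrom not in self._chroms:
            return np.zeros(np.shape(np.asarray(start)))
        return self._integral_to(chrom, end) - self._integral_to(chrom, start)

    def total(self) -> float:
        return float(sum(c[3][-1] for c in self._chroms.values()))


def bin_signals(calls: pd.DataFrame, coverage: dict[str, pd.DataFrame],
                n_bins: int = N_BINS) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Per-interaction meta-profiles: marks x 30 bins of summed coverage.

    The inner span runs between the anchors' inner edges (end1 .. start2)
    and is split into 10 equal bins; each flank is one inner-span wide and
    is split into 10 bins, so all 30 bins share one width.  Interactions
    with an inner span shorter than 30 bp are flagged degenerate and
    excluded.

    Returns (profiles array of shape (n_kept, n_marks, 30), the kept calls
    with a ``degenerate`` column, mark names).
    """
    if n_bins % 3:
        raise ValueError("n_bins must be divisible by 3")
    per_side = n_bins // 3
    marks = sorted(coverage)
    tracks = {m: CoverageTrack(coverage[m]) for m in marks}
    calls = calls.reset_index(drop=True).copy()
    inner = calls["start2"] - calls["end1"]
    calls["degenerate"] = inner < n_bins
    kept = calls.loc[~calls["degenerate"]].reset_index(drop=True)

    profiles = np.zeros((len(kept), len(marks), n_bins))
    for i, row in kept.iterrows():
        span = int(row["start2"] - row["end1"])
        left0 = row["end1"] - span
        edges = np.concatenate([
            np.linspace(left0, row["end1"], per_side + 1)[:-1],
            np.linspace(row["end1"], row["start2"], per_side + 1)[:-1],
            np.linspace(row["start2"], row["start2"] + span, per_side + 1),
        ])
        for mi, m in enumerate(marks):
            profiles[i, mi] = tracks[m].window_sum(row["chrom"], edges[:-1], edges[1:])
    return profiles, kept, marks


def normalize_profiles(profiles: np.ndarray,
                       mark_depths: np.ndarray | None = None) -> np.ndarray:
    """Depth-normalize per mark, then z-transform each interaction x mark row.

    Each mark is divided by its total signal across all profiles (so deep
    and shallow marks weigh equally), then every 30-bin row is centred and
    scaled to unit SD; constant rows become all-zeros.  The z step is
    idempotent.
    """
    out = profiles.astype(float).copy()
    if out.size == 0:
        return out
    depths = mark_depths if mark_depths is not None else out.sum(axis=(0, 2))
    depths = np.where(depths > 0, depths, 1.0)
    out /= depths[None, :, None]
    mu = out.mean(axis=2, keepdims=True)
    sd = out.std(axis=2, keepdims=True)
    z = np.where(sd > 1e-12, (out - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return z


@dataclass
class DomainGroups:
    """k-means labels, the symmetric-merge map and final group labels."""

    kmeans_labels: np.ndarray
    group: np.ndarray                 # final group per interaction, 1-based
    merge_map: dict[int, int]         # k-means cluster -> final group
    centroids: np.ndarray             # (k, marks, bins)
    inertia: float

    @property
    def n_groups(self) -> int:
        return len(set(self.merge_map.values()))


def _mirror(centroid: np.ndarray) -> np.ndarray:
    """Reverse bin order per mark: the left-right reflection of a profile."""
    return centroid[..., ::-1]


def cluster_loops(profiles: np.ndarray, lengths: np.ndarray, k: int = 8,
                  seed: int = 0, n_init: int = 10,
                  mirror_corr_cutoff: float = 0.7) -> DomainGroups:
    """k-means over flattened profiles, then merge mirror-image clusters.

    A loop has no orientation, so a cluster and its left-right mirror
    describe the same domain type.  Cluster pairs whose centroid /
    mirrored-centroid Pearson correlation exceeds ``mirror_corr_cutoff``
    are merged greedily (best pair first); remaining clusters stand alone.
    Final groups are renumbered 1..G by increasing median loop length.
    """
    n, n_marks, n_bins = profiles.shape
    if n < k:
        raise ValueError(f"need at least k={k} profiles, got {n}")
    X = profiles.reshape(n, -1)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2 ** 31)).fit(X)
    labels = km.labels_
    centroids = km.cluster_centers_.reshape(k, n_marks, n_bins)

    corr = np.full((k, k), -np.inf)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            a = centroids[i].ravel()
            b = _mirror(centroids[j]).ravel()
            if a.std() < 1e-12 or b.std() < 1e-12:
                corr[i, j] = 1.0 if np.allclose(a, b) else -np.inf
            else:
                corr[i, j] = pearsonr(a, b)[0]
    sym = np.minimum(corr, corr.T)  # require the relation both ways

    unmerged = set(range(k))
    merge_map: dict[int, int] = {}
    gid = 0
    while True:
        best, best_val = None, mirror_corr_cutoff
        for i in sorted(unmerged):
            for j in sorted(unmerged):
                if i < j and sym[i, j] > best_val:
                    best, best_val = (i, j), sym[i, j]
        if best is None:
            break
        i, j = best
        merge_map[i] = merge_map[j] = gid
        unmerged -= {i, j}
        gid += 1
    for i in sorted(unmerged):
        merge_map[i] = gid
        gid += 1

    prelim = np.array([merge_map[l] for l in labels])
    med = {}
    for g in set(merge_map.values()):
        sel = prelim == g
        med[g] = float(np.median(lengths[sel])) if sel.any() else np.inf
    order = sorted(med, key=lambda g: (med[g], g))
    rank = {g: r + 1 for r, g in enumerate(order)}
    merge_map = {c: rank[g] for c, g in merge_map.items()}
    group = np.array([merge_map[l] for l in labels])
    return DomainGroups(kmeans_labels=labels, group=group, merge_map=merge_map,
                        centroids=centroids, inertia=float(km.inertia_))
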