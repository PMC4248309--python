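"""Small numpy-based interval engine (0-based half-open throughout).

All helpers operate per chromosome on plain integer arrays; callers group
DataFrames by chromosome.  Targets are pre-sorted by start; a prefix
running-maximum of ends handles overlapping target intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class IntervalIndex:
    """Query structure over one chromosome's intervals."""

    def __init__(self, starts, ends, payload=None):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        self.order = order
        self.payload = None if payload is None else np.asarray(payload)[order]
        # running max of ends lets us stop the backward scan early
        self.cummax_end = np.maximum.accumulate(self.ends) if len(self.ends) else self.ends

    def __len__(self):
        return len(self.starts)

    def contains_point(self, pos: np.ndarray) -> list[np.ndarray]:
        """Indices (into sorted order) of intervals containing each point."""
        return self.overlapping(pos, np.asarray(pos) + 1)

    def overlapping(self, q_start, q_end) -> list[np.ndarray]:
        """For each query interval, indices of targets overlapping it."""
        q_start = np.atleast_1d(np.asarray(q_start, dtype=np.int64))
        q_end = np.atleast_1d(np.asarray(q_end, dtype=np.int64))
        out = []
        hi_all = np.searchsorted(self.starts, q_end, side="left")
        for qs, hi in zip(q_start, hi_all):
            hits = []
            k = hi - 1
            while k >= 0 and self.cummax_end[k] > qs:
                if self.ends[k] > qs:
                    hits.append(k)
                k -= 1
            out.append(np.array(hits[::-1], dtype=np.int64))
        return out

    def any_overlap(self, q_start, q_end) -> np.ndarray:
        """Boolean: does each query overlap at least one target? Vectorized."""
        q_start = np.asarray(q_start, dtype=np.int64)
        q_end = np.asarray(q_end, dtype=np.int64)
        if len(self.starts) == 0:
            return np.zeros(q_start.shape, dtype=bool)
        hi = np.searchsorted(self.starts, q_end, side="left")
        res = np.zeros(q_start.shape, dtype=bool)
        nz = hi > 0
        res[nz] = self.cummax_end[hi[nz] - 1] > q_start[nz]
        return res


def by_chrom(df: pd.DataFrame, start="start", end="end", chrom="chrom") -> dict[str, IntervalIndex]:
    """Build one IntervalIndex per chromosome; payload = original row index."""
    out = {}
    for c, sub in df.groupby(chrom, sort=False):
        out[c] = IntervalIndex(sub[start].to_numpy(), sub[end].to_numpy(),
                               payload=sub.index.to_numpy())
    return out


def any_overlap_df(query: pd.DataFrame, targets: pd.DataFrame,
                   qcols=("chrom", "start", "end"),
                   tcols=("chrom", "start", "end")) -> np.ndarray:
    """Per query row: does it overlap any target interval (same chromosome)?"""
    idx = by_chrom(targets, start=tcols[1], end=tcols[2], chrom=tcols[0])
    res = np.zeros(len(query), dtype=bool)
    for c, sub in query.groupby(qcols[0], sort=False):
        if c in idx:
            pos = np.flatnonzero(query[qcols[0]].to_numpy() == c)
            res[pos] = idx[c].any_overlap(sub[qcols[1]].to_numpy(), sub[qcols[2]].to_numpy())
    return res


def overlap_pairs(query: pd.DataFrame, targets: pd.DataFrame,
                  qcols=("chrom", "start", "end"),
                  tcols=("chrom", "start", "end")) -> pd.DataFrame:
    """All (query_index, target_index) pairs of overlapping intervals."""
    idx = by_chrom(targets, start=tcols[1], end=tcols[2], chrom=tcols[0])
    qi, ti = [], []
    for c, sub in query.groupby(qcols[0], sort=False):
        if c not in idx:
            continue
        tree = idx[c]
        hits = tree.overlapping(sub[qcols[1]].to_numpy(), sub[qcols[2]].to_numpy())
        for q_label, h in zip(sub.index, hits):
            if len(h):
                qi.extend([q_label] * len(h))
                ti.extend(tree.payload[h])
    return pd.DataFrame({"query": qi, "target": ti})


def overlap_bp(qs: int, qe: int, ts: np.ndarray, te: np.ndarray) -> np.ndarray:
    """Overlap length in bp between one query and many targets."""
    return np.maximum(0, np.minimum(qe, te) - np.maximum(qs, ts))
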