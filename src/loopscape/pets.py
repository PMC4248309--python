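"""PET filtering and assignment to extended binding peaks (anchors).

Coordinates are 0-based half-open everywhere; a mate's position is its
midpoint floor((start + end) / 2).  PETs are canonically ordered so that
(chrom1, start1) <= (chrom2, start2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from loopscape.config import DEFAULT_EXTENSION_BP, DEFAULT_SELF_CIRC_MAX_SPAN

PET_COLS = ["chrom1", "start1", "end1", "strand1",
            "chrom2", "start2", "end2", "strand2", "name"]


@dataclass
class AnchorSet:
    """Binding peaks extended symmetrically to serve as interaction endpoints.

    The extension (default ±1500 bp) widens each peak before PET mates are
    assigned, so that tags shifted off the summit by sonication still land
    on their peak.
    """

    anchors: pd.DataFrame  # columns: chrom, start, end, id
    extension_bp: int = DEFAULT_EXTENSION_BP

    def __post_init__(self):
        if self.extension_bp < 0:
            raise ValueError("extension_bp must be >= 0")
        df = self.anchors.reset_index(drop=True)
        if len(df) and df["id"].duplicated().any():
            raise ValueError("anchor ids must be unique")
        self.anchors = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    def __len__(self):
        return len(self.anchors)

    @property
    def midpoints(self) -> pd.Series:
        a = self.anchors
        return (a["start"] + a["end"]) // 2

    def extended(self) -> pd.DataFrame:
        """Anchor intervals widened by extension_bp on both sides (floored at 0)."""
        a = self.anchors.copy()
        a["ext_start"] = np.maximum(0, a["start"] - self.extension_bp)
        a["ext_end"] = a["end"] + self.extension_bp
        return a

    def midpoint_by_id(self) -> dict:
        return dict(zip(self.anchors["id"], self.midpoints))

    def coords_by_id(self) -> pd.DataFrame:
        return self.anchors.set_index("id")


@dataclass
class FilterReport:
    """Conserved accounting of what happened to every input PET.

    Each PET is counted in exactly one class (first matching rule wins:
    duplicate, then self-circularization, then — during anchoring —
    interchromosomal, unanchored, self-anchor).
    """

    n_input: int = 0
    n_duplicates_removed: int = 0
    n_self_circ: int = 0
    n_interchrom: int = 0
    n_unanchored: int = 0
    n_self_anchor: int = 0
    n_retained: int = 0

    def assert_conserved(self) -> None:
        total = (self.n_duplicates_removed + self.n_self_circ + self.n_interchrom
                 + self.n_unanchored + self.n_self_anchor + self.n_retained)
        if total != self.n_input:
            raise AssertionError(
                f"FilterReport not conserved: input={self.n_input} but classes sum to {total}")

    def to_dict(self) -> dict:
        return asdict(self)


def canonicalize(pets: pd.DataFrame) -> pd.DataFrame:
    """Order mates so (chrom1, start1) <= (chrom2, start2) lexicographically."""
    pets = pets.reset_index(drop=True).copy()
    swap = (pets["chrom1"] > pets["chrom2"]) | (
        (pets["chrom1"] == pets["chrom2"]) & (pets["start1"] > pets["start2"]))
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"),
                 ("end1", "end2"), ("strand1", "strand2")):
        va, vb = pets[a].copy(), pets[b].copy()
        pets.loc[swap, a] = vb[swap]
        pets.loc[swap, b] = va[swap]
    return pets


def mate_midpoints(pets: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    m1 = (pets["start1"].to_numpy() + pets["end1"].to_numpy()) // 2
    m2 = (pets["start2"].to_numpy() + pets["end2"].to_numpy()) // 2
    return m1, m2


def filter_pets(pets: pd.DataFrame,
                self_circ_max_span: int = DEFAULT_SELF_CIRC_MAX_SPAN,
                report: FilterReport | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Collapse duplicates and divert self-circularization artifacts.

    Duplicates are PETs identical on both mates' coordinates and strands;
    one copy is kept.  Self-circularization PETs — same chromosome, span
    (end2 - start1) at most ``self_circ_max_span``, convergent orientation
    (+ then - after canonical ordering) — come from a fragment ligating to
    itself.  They are returned as a separate stream: still usable for peak
    calling, never for interaction calling.

    Returns (clean PETs, self-circularization PETs, FilterReport).
    """
    report = report or FilterReport()
    pets = canonicalize(pets)
    report.n_input += len(pets)

    key_cols = ["chrom1", "start1", "end1", "strand1",
                "chrom2", "start2", "end2", "strand2"]
    dup_mask = pets.duplicated(subset=key_cols, keep="first")
    report.n_duplicates_removed += int(dup_mask.sum())
    pets = pets.loc[~dup_mask]

    span = pets["end2"] - pets["start1"]
    self_circ = ((pets["chrom1"] == pets["chrom2"])
                 & (span <= self_circ_max_span)
                 & (pets["strand1"] == "+") & (pets["strand2"] == "-"))
    report.n_self_circ += int(self_circ.sum())
    sc = pets.loc[self_circ].reset_index(drop=True)
    clean = pets.loc[~self_circ].reset_index(drop=True)
    report.n_retained = report.n_input - (report.n_duplicates_removed + report.n_self_circ
                                          + report.n_interchrom + report.n_unanchored
                                          + report.n_self_anchor)
    report.assert_conserved()
    return clean, sc, report


def _assign_mates(chroms: np.ndarray, mids: np.ndarray, anchors: AnchorSet) -> np.ndarray:
    """Map each mate midpoint to an anchor id ('' if unassigned).

    A midpoint inside several extended anchors goes to the anchor with the
    nearest (un-extended) midpoint; ties break to the lexicographically
    smaller id.
    """
    ext = anchors.extended()
    out = np.full(len(mids), "", dtype=object)
    for chrom, sub in ext.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        if not len(sel):
            continue
        starts = sub["ext_start"].to_numpy()
        ends = sub["ext_end"].to_numpy()
        amid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        ids = sub["id"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends, amid, ids = starts[order], ends[order], amid[order], ids[order]
        cummax = np.maximum.accumulate(ends)
        pos = mids[sel]
        hi = np.searchsorted(starts, pos, side="right")
        for row, (p, h) in zip(sel, zip(pos, hi)):
            best = None
            k = h - 1
            while k >= 0 and cummax[k] > p:
                if starts[k] <= p < ends[k]:
                    cand = (abs(int(amid[k]) - int(p)), str(ids[k]))
                    if best is None or cand < best:
                        best = cand
                k -= 1
            if best is not None:
                out[row] = best[1]
    return out


def assign_to_anchors(pets: pd.DataFrame, anchors: AnchorSet,
                      report: FilterReport | None = None,
                      ) -> tuple[pd.DataFrame, FilterReport]:
    """Label each PET with the two anchors its mate midpoints fall in.

    PETs whose mates sit on different chromosomes, whose either mate falls
    outside every extended anchor, or whose two mates land on the same
    anchor are dropped and accounted in the FilterReport.  Output anchor
    ids are ordered so anchor1 < anchor2.

    Returns a DataFrame (name, chrom, anchor1, anchor2, distance) where
    distance is the absolute difference of the two anchor midpoints.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    own_report = report is None
    report = report or FilterReport()
    if own_report:
        report.n_input += len(pets)

    inter = pets["chrom1"] != pets["chrom2"]
    report.n_interchrom += int(inter.sum())
    pets = pets.loc[~inter].reset_index(drop=True)

    m1, m2 = mate_midpoints(pets)
    chroms = pets["chrom1"].to_numpy()
    a1 = _assign_mates(chroms, m1, anchors)
    a2 = _assign_mates(chroms, m2, anchors)

    unanchored = (a1 == "") | (a2 == "")
    self_anchor = (~unanchored) & (a1 == a2)
    report.n_unanchored += int(unanchored.sum())
    report.n_self_anchor += int(self_anchor.sum())

    keep = ~(unanchored | self_anchor)
    mid = anchors.midpoint_by_id()
    lo = np.where(a1 < a2, a1, a2)[keep]
    hi = np.where(a1 < a2, a2, a1)[keep]
    out = pd.DataFrame({
        "name": pets.loc[keep, "name"].to_numpy(),
        "chrom": chroms[keep],
        "anchor1": lo,
        "anchor2": hi,
    })
    out["distance"] = np.abs(
        np.array([mid[a] for a in out["anchor2"]], dtype=np.int64)
        - np.array([mid[a] for a in out["anchor1"]], dtype=np.int64)) if len(out) else np.array([], dtype=np.int64)
    report.n_retained = report.n_input - (report.n_duplicates_removed + report.n_self_circ
                                          + report.n_interchrom + report.n_unanchored
                                          + report.n_self_anchor)
    report.assert_conserved()
    return out, report


def naive_peak_caller(tags: pd.DataFrame, window_bp: int = 500, min_tags: int = 10,
                      extension_bp: int = DEFAULT_EXTENSION_BP) -> AnchorSet:
    """Sliding-window tag-density peak caller (plumbing fallback).

    ``tags`` needs columns chrom, pos (sorted by chrom, pos).  Any window of
    ``window_bp`` holding >= min_tags tags seeds a peak; overlapping or
    adjacent windows merge.  Dedicated peak callers are the expected source
    of anchors; this exists so the pipeline runs without one.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    for chrom, sub in tags.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy())
        n = len(pos)
        # window [pos[i], pos[i]+window_bp) contains pos[i..j)
        j = np.searchsorted(pos, pos + window_bp, side="left")
        dense = np.flatnonzero(j - np.arange(n) >= min_tags)
        if not len(dense):
            continue
        start, end = None, None
        for i in dense:
            w_start, w_end = int(pos[i]), int(pos[j[i] - 1]) + 1
            if start is None:
                start, end = w_start, w_end
            elif w_start <= end:
                end = max(end, w_end)
            else:
                rows.append((chrom, start, end))
                start, end = w_start, w_end
        rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df["id"] = [f"P{i:06d}" for i in range(len(df))]
    return AnchorSet(df, extension_bp=extension_bp)
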