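"""Regulatory-element annotation and overlap of calls with TADs and 5C pairs.

A regulatory element is a DNase hypersensitive site (DHS) labeled with the
chromatin state it overlaps the most.  Interactions are typed by the
element labels of their two anchors, classified against topologically
associated domains (TADs), and validated against 5C interaction pairs with
a distance-matched permutation test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from loopscape.config import substream
from loopscape.intervals import by_chrom, overlap_bp

#: Label priority for ties and for reducing an anchor's element set to one
#: label; promoter identity dominates.
LABEL_PRIORITY = ["TSS", "PF", "E", "WE", "CTCF", "T", "R", "undefined"]
_PRIO = {lab: k for k, lab in enumerate(LABEL_PRIORITY)}


def annotate_dhs(dhs: pd.DataFrame, states: pd.DataFrame) -> pd.DataFrame:
    """Label each DHS with its dominant chromatin state.

    Per DHS the overlap in bp with each state label is accumulated; the
    label with maximal overlap wins, ties break by the fixed priority
    order, and a DHS overlapping no state at all is labeled "undefined".
    The result is independent of input row order.
    """
    dhs = dhs.reset_index(drop=True)
    states = states.reset_index(drop=True)
    idx = by_chrom(states)
    labels = []
    dominant = []
    st_labels = states["state"].to_numpy()
    for _, row in dhs.iterrows():
        best_lab, best_bp = "undefined", 0
        tree = idx.get(row["chrom"])
        if tree is not None:
            hits = tree.overlapping(np.array([row["start"]]), np.array([row["end"]]))[0]
            if len(hits):
                bp_by_label: dict[str, int] = {}
                ov = overlap_bp(row["start"], row["end"], tree.starts[hits], tree.ends[hits])
                for h, o in zip(hits, ov):
                    lab = st_labels[tree.payload[h]]
                    bp_by_label[lab] = bp_by_label.get(lab, 0) + int(o)
                best_lab = min(bp_by_label,
                               key=lambda l: (-bp_by_label[l], _PRIO.get(l, len(_PRIO))))
                best_bp = bp_by_label[best_lab]
        labels.append(best_lab)
        dominant.append(best_bp)
    out = dhs.copy()
    out["state"] = labels
    out["dominant_bp"] = dominant
    return out


def _anchor_labels(calls: pd.DataFrame, elements: pd.DataFrame) -> tuple[list, list]:
    elements = elements.reset_index(drop=True)
    idx = by_chrom(elements)
    el_state = elements["state"].to_numpy()

    def label_side(side):
        labs = []
        for _, row in calls.iterrows():
            tree = idx.get(row["chrom"])
            lab = "undefined"
            if tree is not None:
                hits = tree.overlapping(np.array([row[f"start{side}"]]),
                                        np.array([row[f"end{side}"]]))[0]
                if len(hits):
                    cand = [el_state[tree.payload[h]] for h in hits]
                    lab = min(cand, key=lambda l: _PRIO.get(l, len(_PRIO)))
            labs.append(lab)
        return labs

    return label_side(1), label_side(2)


def classify_interactions(calls: pd.DataFrame, elements: pd.DataFrame,
                          factor_col: str = "source_dataset") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type each interaction by its anchors' element labels.

    Each anchor takes the highest-priority label among the elements it
    overlaps; the unordered label pair (e.g. "E-TSS", "CTCF-CTCF") is the
    interaction type.  Also returns the per-factor composition table
    (percentage of calls of each type).
    """
    calls = calls.reset_index(drop=True).copy()
    l1, l2 = _anchor_labels(calls, elements)
    pair = [f"{min(a, b)}-{max(a, b)}" for a, b in zip(l1, l2)]
    calls["label1"], calls["label2"], calls["interaction_type"] = l1, l2, pair

    fac = calls[factor_col] if factor_col in calls else pd.Series(["all"] * len(calls))
    comp = (pd.DataFrame({"factor": fac, "interaction_type": pair})
            .groupby(["factor", "interaction_type"]).size().reset_index(name="n"))
    comp["percent"] = comp.groupby("factor")["n"].transform(lambda s: 100.0 * s / s.sum())
    return calls, comp


def tad_overlap(calls: pd.DataFrame, tads: pd.DataFrame,
                border_pad: int = 20_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify interactions against TADs.

    An interaction is ``intra`` when both anchor midpoints fall inside the
    same TAD away from any padded border, ``inter`` when they fall in two
    distinct TADs, ``border`` when it stays in one TAD but touches a TAD
    border padded ``border_pad`` bp each side, and ``unassigned`` when an
    anchor lies outside every TAD.
    """
    tads = tads.sort_values(["chrom", "start"]).reset_index(drop=True)
    tad_idx = by_chrom(tads)
    borders = []
    for _, row in tads.iterrows():
        for edge in (row["start"], row["end"]):
            borders.append((row["chrom"], max(0, edge - border_pad), edge + border_pad))
    borders = pd.DataFrame(borders, columns=["chrom", "start", "end"])
    border_idx = by_chrom(borders)

    classes = []
    calls = calls.reset_index(drop=True).copy()
    for _, row in calls.iterrows():
        m1 = (row["start1"] + row["end1"]) // 2
        m2 = (row["start2"] + row["end2"]) // 2
        tree = tad_idx.get(row["chrom"])
        t1 = tree.contains_point(np.array([m1]))[0] if tree is not None else []
        t2 = tree.contains_point(np.array([m2]))[0] if tree is not None else []
        if len(t1) == 0 or len(t2) == 0:
            classes.append("unassigned")
            continue
        if t1[0] != t2[0]:
            classes.append("inter")
            continue
        btree = border_idx.get(row["chrom"])
        lo, hi = min(m1, m2), max(m1, m2)
        touches = bool(btree.any_overlap(np.array([lo]), np.array([hi + 1]))[0]) \
            if btree is not None else False
        classes.append("border" if touches else "intra")
    calls["tad_class"] = classes
    summary = (pd.Series(classes).value_counts().rename_axis("tad_class")
               .reset_index(name="n"))
    summary["fraction"] = summary["n"] / max(len(calls), 1)
    return calls, summary


def _pairs_match(q: pd.DataFrame, t: pd.DataFrame) -> np.ndarray:
    """Does each query BEDPE row reciprocally overlap some target row
    (end-1 with end-1 and end-2 with end-2, same chromosome)?"""
    res = np.zeros(len(q), dtype=bool)
    q = q.reset_index(drop=True)
    for chrom, sub in q.groupby("chrom1", sort=False):
        tt = t.loc[t["chrom1"] == chrom]
        if not len(tt):
            continue
        s1, e1 = tt["start1"].to_numpy(), tt["end1"].to_numpy()
        s2, e2 = tt["start2"].to_numpy(), tt["end2"].to_numpy()
        for i in sub.index:
            r = q.loc[i]
            hit = ((r["start1"] < e1) & (r["end1"] > s1)
                   & (r["start2"] < e2) & (r["end2"] > s2)).any()
            res[i] = bool(hit)
    return res


def fivec_overlap(calls: pd.DataFrame, fivec: pd.DataFrame,
                  tested_region: pd.DataFrame,
                  pad: int = 10_000, n_perm: int = 1000,
                  seed: int = 0) -> dict:
    """Fraction of calls confirmed by 5C, with a distance-matched null.

    Call ends are padded ``pad`` bp in both directions; only calls whose
    padded ends both lie inside the 5C-tested region are scored.  The
    observed value is the percentage matching a 5C pair (reciprocal
    any-overlap of both ends).  The expected distribution re-draws, for
    each permutation, random pairs inside the tested region with the same
    interaction-distance multiset as the observed calls, and the p-value is
    (1 + #permutations >= observed) / (1 + n_perm).
    """
    rng = substream(seed, "fivec")
    c = calls.reset_index(drop=True).copy()
    c["p_start1"] = np.maximum(0, c["start1"] - pad)
    c["p_end1"] = c["end1"] + pad
    c["p_start2"] = np.maximum(0, c["start2"] - pad)
    c["p_end2"] = c["end2"] + pad

    reg_idx = by_chrom(tested_region)
    inside = np.zeros(len(c), dtype=bool)
    for chrom, sub in c.groupby("chrom", sort=False):
        tree = reg_idx.get(chrom)
        if tree is None:
            continue
        s = np.flatnonzero(c["chrom"].to_numpy() == chrom)
        # each padded end must be fully contained in a tested interval
        def contained(st, en):
            hits = tree.overlapping(st, en)
            return np.array([any(tree.starts[h] <= a and tree.ends[h] >= b for h in hh)
                             for hh, a, b in zip(hits, st, en)])
        inside[s] = (contained(sub["p_start1"].to_numpy(), sub["p_end1"].to_numpy())
                     & contained(sub["p_start2"].to_numpy(), sub["p_end2"].to_numpy()))
    tested = c.loc[inside].reset_index(drop=True)
    if len(tested) == 0:
        return {"observed_percent": float("nan"), "expected_percent": float("nan"),
                "expected_distribution": np.array([]), "p": float("nan"), "n_tested": 0}

    qdf = pd.DataFrame({
        "chrom1": tested["chrom"], "start1": tested["p_start1"], "end1": tested["p_end1"],
        "start2": tested["p_start2"], "end2": tested["p_end2"]})
    observed = 100.0 * _pairs_match(qdf, fivec).mean()

    dists = ((tested["p_start2"] + tested["p_end2"]) // 2
             - (tested["p_start1"] + tested["p_end1"]) // 2).to_numpy()
    width1 = (tested["p_end1"] - tested["p_start1"]).to_numpy()
    width2 = (tested["p_end2"] - tested["p_start2"]).to_numpy()
    reg = tested_region.reset_index(drop=True)
    exp = np.empty(n_perm)
    for k in range(n_perm):
        ridx = rng.integers(0, len(reg), size=len(tested))
        rs = reg["start"].to_numpy()[ridx]
        re_ = reg["end"].to_numpy()[ridx]
        rchrom = reg["chrom"].to_numpy()[ridx]
        span = np.maximum(1, re_ - rs - dists - width2)
        m1 = rs + (rng.random(len(tested)) * span).astype(np.int64)
        s1 = m1
        e1 = m1 + width1
        s2 = m1 + dists
        e2 = s2 + width2
        rnd = pd.DataFrame({"chrom1": rchrom, "start1": s1, "end1": e1,
                            "start2": s2, "end2": e2})
        exp[k] = 100.0 * _pairs_match(rnd, fivec).mean()
    p = (1 + int((exp >= observed).sum())) / (1 + n_perm)
    return {"observed_percent": float(observed), "expected_percent": float(exp.mean()),
            "expected_distribution": exp, "p": float(p), "n_tested": int(len(tested))}
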