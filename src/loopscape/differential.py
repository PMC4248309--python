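"""Condition-specific interaction calling with binding control.

Interactions called in either of two conditions are compared at the PET
level while controlling for anchor-binding differences: a candidate whose
anchors are not RAD21-bound in *both* conditions is set aside (its
interaction difference could simply reflect binding loss) rather than
tested.  Each remaining candidate is tested with Fisher's exact test on
(n_A, N_A - n_A; n_B, N_B - n_B), where N is the condition's total
anchored intrachromosomal PET count, followed by Benjamini–Hochberg across
candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from loopscape.config import DEFAULT_EXTENSION_BP
from loopscape.intervals import any_overlap_df
from loopscape.pets import AnchorSet
from loopscape.caller import count_pairs


def _anchor_bound(anchor_ids: pd.Series, anchors: AnchorSet, peaks: pd.DataFrame,
                  pad: int = DEFAULT_EXTENSION_BP) -> np.ndarray:
    """Is each anchor (padded +- pad) overlapped by any peak?"""
    coords = anchors.coords_by_id()
    q = pd.DataFrame({
        "chrom": coords.loc[anchor_ids, "chrom"].to_numpy(),
        "start": np.maximum(0, coords.loc[anchor_ids, "start"].to_numpy() - pad),
        "end": coords.loc[anchor_ids, "end"].to_numpy() + pad,
    })
    return any_overlap_df(q, peaks)


def call_differential(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                      pets_a: pd.DataFrame, pets_b: pd.DataFrame,
                      rad21_a: pd.DataFrame, rad21_b: pd.DataFrame,
                      anchors: AnchorSet,
                      fdr: float = 0.05,
                      binding_pad: int = DEFAULT_EXTENSION_BP,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call interactions specific to one of two conditions.

    Parameters
    ----------
    calls_a, calls_b
        Caller output tables for each condition (rows with ``passed`` are
        the condition's interactions); both conditions must be anchored on
        the shared ``anchors`` set.
    pets_a, pets_b
        Anchored PET tables per condition (used for per-pair counts and
        library sizes).
    rad21_a, rad21_b
        RAD21 peak BED frames per condition, for the binding control.
    fdr
        Benjamini–Hochberg level for declaring a candidate differential.

    Returns
    -------
    (tested, binding_explained)
        ``tested`` carries n_A, n_B, N_A, N_B, p, q, differential flag and
        direction ('A-specific'/'B-specific'); ``binding_explained`` lists
        candidates excluded because an anchor lost binding in one condition.
    """
    n_lib_a = len(pets_a)
    n_lib_b = len(pets_b)
    if n_lib_a == 0 or n_lib_b == 0:
        raise ValueError("zero library size in one condition")

    def passing(df):
        return df.loc[df["passed"], ["anchor1", "anchor2", "chrom"]] if "passed" in df \
            else df[["anchor1", "anchor2", "chrom"]]

    cand = (pd.concat([passing(calls_a), passing(calls_b)])
            .drop_duplicates()
            .reset_index(drop=True))

    cnt_a = count_pairs(pets_a).set_index(["anchor1", "anchor2"])["n_pets"]
    cnt_b = count_pairs(pets_b).set_index(["anchor1", "anchor2"])["n_pets"]
    key = list(zip(cand["anchor1"], cand["anchor2"]))
    cand["n_A"] = [int(cnt_a.get(k, 0)) for k in key]
    cand["n_B"] = [int(cnt_b.get(k, 0)) for k in key]
    cand["N_A"] = n_lib_a
    cand["N_B"] = n_lib_b

    bound = np.ones(len(cand), dtype=bool)
    for peaks in (rad21_a, rad21_b):
        for side in ("anchor1", "anchor2"):
            bound &= _anchor_bound(cand[side], anchors, peaks, pad=binding_pad)
    binding_explained = cand.loc[~bound].reset_index(drop=True)
    tested = cand.loc[bound].reset_index(drop=True)
    if len(tested) == 0:
        tested["p"] = tested["q"] = np.array([], dtype=float)
        tested["differential"] = np.array([], dtype=bool)
        tested["direction"] = np.array([], dtype=object)
        return tested, binding_explained

    pvals = np.array([
        stats.fisher_exact([[na, n_lib_a - na], [nb, n_lib_b - nb]])[1]
        for na, nb in zip(tested["n_A"], tested["n_B"])
    ])
    tested["p"] = pvals
    tested["q"] = multipletests(pvals, method="fdr_bh")[1]
    tested["differential"] = tested["q"] <= fdr
    rate_a = tested["n_A"] / n_lib_a
    rate_b = tested["n_B"] / n_lib_b
    tested["direction"] = np.where(rate_a >= rate_b, "A-specific", "B-specific")
    return tested, binding_explained
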