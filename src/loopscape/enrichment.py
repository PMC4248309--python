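"""TF and HOT-region enrichment at interacting loci.

"Loci" throughout are the ChIA-PET binding-site universe (the merged
anchor set); a locus is *interacting* when it is an endpoint of at least
one passed interaction.  Expected overlap comes from a size-matched random
subset of the universe, significance from Fisher's exact test with
Bonferroni correction across factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from loopscape.config import substream
from loopscape.intervals import any_overlap_df


def tf_enrichment(interacting_loci: pd.DataFrame, all_loci: pd.DataFrame,
                  tf_peaksets: dict[str, pd.DataFrame],
                  seed: int = 0, n_draws: int = 1) -> pd.DataFrame:
    """Per-TF enrichment at interacting loci.

    For each TF: observed = fraction of interacting loci overlapping a TF
    peak; expected = the same fraction on a size-matched random subset of
    all loci (one draw by default; ``n_draws`` > 1 averages the expected
    fraction while the 2x2 test uses the first draw).  A TF is ``high``
    when the Bonferroni-adjusted p <= 0.01, log2(obs/exp) > 0.35 and the
    TF is present at >= 35% of interacting loci; ``weak`` when only the
    p-value criterion holds; ``none`` otherwise.
    """
    rng = substream(seed, "tf_enrichment")
    n_int = len(interacting_loci)
    n_tf = max(len(tf_peaksets), 1)
    records = []
    draws = [all_loci.iloc[rng.choice(len(all_loci), size=min(n_int, len(all_loci)),
                                      replace=False)].reset_index(drop=True)
             for _ in range(max(n_draws, 1))]
    for tf, peaks in tf_peaksets.items():
        if len(peaks) == 0 or n_int == 0:
            records.append((tf, 0, 0.0, np.nan, 1.0, 1.0, "none"))
            continue
        obs_hit = any_overlap_df(interacting_loci, peaks)
        exp_fracs = [any_overlap_df(d, peaks).mean() for d in draws]
        exp_frac = float(np.mean(exp_fracs))
        obs_frac = float(obs_hit.mean())
        exp_hit0 = any_overlap_df(draws[0], peaks)
        table = [[int(obs_hit.sum()), int(n_int - obs_hit.sum())],
                 [int(exp_hit0.sum()), int(len(draws[0]) - exp_hit0.sum())]]
        p = float(stats.fisher_exact(table)[1])
        p_adj = min(1.0, p * n_tf)
        log2_ratio = float(np.log2(obs_frac / exp_frac)) if obs_frac > 0 and exp_frac > 0 \
            else (np.inf if obs_frac > 0 else 0.0)
        cat = categorize_enrichment(p_adj, log2_ratio, obs_frac)
        records.append((tf, int(obs_hit.sum()), log2_ratio, p, p_adj, obs_frac, cat))
    out = pd.DataFrame(records, columns=["tf", "n_interacting_bound", "log2_obs_exp",
                                         "p", "p_bonferroni", "presence_fraction",
                                         "category"])
    # keep column order stable regardless of the degenerate-row path above
    return out


def categorize_enrichment(p_adj: float, log2_ratio: float, presence: float) -> str:
    """Pure categorical rule: high / weak / none."""
    if not p_adj <= 0.01:
        return "none"
    if log2_ratio > 0.35 and presence >= 0.35:
        return "high"
    return "weak"


def hot_enrichment(calls: pd.DataFrame, interacting_loci: pd.DataFrame,
                   all_loci: pd.DataFrame, hot: pd.DataFrame,
                   n_rewires: int = 10_000, seed: int = 0) -> dict:
    """HOT-region enrichment at interacting loci and among interactions.

    Locus level: Fisher's exact test comparing HOT overlap of interacting
    loci vs a size-matched random locus subset.  Pair level: the observed
    number of interactions linking two HOT regions is compared to its
    distribution over ``n_rewires`` random re-pairings of the interaction
    ends; the permutation mean is the expected HOT-HOT count and
    p = (1 + #rewires >= observed) / (1 + n_rewires).
    """
    rng = substream(seed, "hot")
    out: dict = {}
    if len(hot) == 0 or len(interacting_loci) == 0 or len(calls) == 0:
        return {"locus_p": 1.0, "pair_p": 1.0, "observed_hot_hot": 0,
                "expected_hot_hot": 0.0, "n_interacting_hot": 0, "n_expected_hot": 0}

    int_hot = any_overlap_df(interacting_loci, hot)
    draw = all_loci.iloc[rng.choice(len(all_loci),
                                    size=min(len(interacting_loci), len(all_loci)),
                                    replace=False)].reset_index(drop=True)
    exp_hot = any_overlap_df(draw, hot)
    table = [[int(int_hot.sum()), int(len(int_hot) - int_hot.sum())],
             [int(exp_hot.sum()), int(len(draw) - exp_hot.sum())]]
    out["locus_p"] = float(stats.fisher_exact(table)[1])
    out["n_interacting_hot"] = int(int_hot.sum())
    out["n_expected_hot"] = int(exp_hot.sum())

    end1 = calls[["chrom", "start1", "end1"]].rename(
        columns={"start1": "start", "end1": "end"})
    end2 = calls[["chrom", "start2", "end2"]].rename(
        columns={"start2": "start", "end2": "end"})
    h1 = any_overlap_df(end1, hot)
    h2 = any_overlap_df(end2, hot)
    observed = int((h1 & h2).sum())
    # random re-pairing of ends: permute which end-2 goes with which end-1
    sims = np.empty(n_rewires)
    n = len(calls)
    for k in range(n_rewires):
        perm = rng.permutation(n)
        sims[k] = int((h1 & h2[perm]).sum())
    out["observed_hot_hot"] = observed
    out["expected_hot_hot"] = float(sims.mean())
    out["pair_p"] = (1 + int((sims >= observed).sum())) / (1 + n_rewires)
    out["rewired_distribution"] = sims
    return out


def distal_proximal_target_counts(tf_peaksets: dict[str, pd.DataFrame],
                                  genes: pd.DataFrame, calls: pd.DataFrame,
                                  promoter_pad: int = 5000) -> pd.DataFrame:
    """Per TF: number of proximal vs distal target genes.

    Proximal target: gene with a TF peak in its promoter (TSS +- pad).
    Distal target: gene whose promoter anchors an interaction whose other
    anchor carries a TF peak (promoter-promoter interactions excluded).
    Counts are de-duplicated per gene; computed with the network builders
    so the two views of the data cannot drift apart.
    """
    from loopscape.networks import build_proximal, build_distal

    prox = build_proximal(tf_peaksets, genes, promoter_pad=promoter_pad)
    dist = build_distal(tf_peaksets, calls, genes, promoter_pad=promoter_pad)
    rows = []
    for tf in tf_peaksets:
        n_p = len({v for u, v in prox.edges if u == tf})
        n_d = len({v for u, v in dist.edges if u == tf})
        rows.append((tf, n_p, n_d,
                     n_d / n_p if n_p else np.inf if n_d else np.nan))
    return pd.DataFrame(rows, columns=["tf", "n_proximal_targets",
                                       "n_distal_targets", "distal_proximal_ratio"])
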