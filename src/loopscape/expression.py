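"""Distal chromatin state vs expression, cell-specific genes, GO enrichment.

The distal-state analysis asks, for every gene whose promoter anchors an
interaction, which chromatin states sit at the other end of its loops and
how the gene's expression (RPKM) varies with that distal state.  GO
enrichment is the classic per-term Fisher's exact test with
Benjamini–Hochberg correction; the proximal-vs-distal comparison reports
log2(p_proximal / p_distal) per TF x term, so negative values mean
stronger proximal enrichment and positive values stronger distal
enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from loopscape.intervals import by_chrom


def upstream_promoters(genes: pd.DataFrame, upstream: int = 2000) -> pd.DataFrame:
    """Strand-aware promoters: the ``upstream`` bp 5' of the TSS."""
    plus = genes["strand"] != "-"
    start = np.where(plus, np.maximum(0, genes["tss"] - upstream), genes["tss"])
    end = np.where(plus, genes["tss"], genes["tss"] + upstream)
    # a zero-width promoter (TSS at the chromosome edge) keeps 1 bp
    end = np.maximum(end, start + 1)
    return pd.DataFrame({"chrom": genes["chrom"], "start": start,
                         "end": end, "gene": genes["gene"]}).reset_index(drop=True)


def gene_distal_states(calls: pd.DataFrame, elements: pd.DataFrame,
                       genes: pd.DataFrame, promoter_upstream: int = 2000) -> pd.DataFrame:
    """(gene, distal state) pairs over all promoter-anchored interactions.

    One gene can loop to several distal elements and so appear with
    several states (membership is not exclusive).
    """
    prom = upstream_promoters(genes, promoter_upstream)
    elements = elements.reset_index(drop=True)
    prom_idx = by_chrom(prom)
    el_idx = by_chrom(elements)
    el_state = elements["state"].to_numpy()
    calls = calls.reset_index(drop=True)
    rows = []
    for chrom, sub in calls.groupby("chrom", sort=False):
        ptree = prom_idx.get(chrom)
        etree = el_idx.get(chrom)
        if ptree is None or etree is None:
            continue
        for _, r in sub.iterrows():
            for pside, dside in ((1, 2), (2, 1)):
                ph = ptree.overlapping(np.array([r[f"start{pside}"]]),
                                       np.array([r[f"end{pside}"]]))[0]
                if not len(ph):
                    continue
                eh = etree.overlapping(np.array([r[f"start{dside}"]]),
                                       np.array([r[f"end{dside}"]]))[0]
                g_here = prom["gene"].to_numpy()[ptree.payload[ph]]
                states = {el_state[etree.payload[h]] for h in eh}
                for g in g_here:
                    for s in states:
                        rows.append((g, s))
    return pd.DataFrame(rows, columns=["gene", "state"]).drop_duplicates().reset_index(drop=True)


def distal_state_expression(calls: pd.DataFrame, elements: pd.DataFrame,
                            genes: pd.DataFrame, expr: pd.DataFrame,
                            expr_col: str | None = None,
                            promoter_upstream: int = 2000) -> dict:
    """Expression by distal chromatin state, with pairwise Wilcoxon tests.

    Returns a dict with ``rpkm_by_state`` (state -> RPKM array),
    ``gene_states`` and ``wilcoxon_p`` (symmetric DataFrame of two-sided
    rank-sum p-values; diagonal 1).
    """
    expr_col = expr_col or [c for c in expr.columns if c != "gene"][0]
    rpkm = expr.set_index("gene")[expr_col]
    gs = gene_distal_states(calls, elements, genes, promoter_upstream)
    by_state: dict[str, np.ndarray] = {}
    for state, sub in gs.groupby("state"):
        vals = rpkm.reindex(sub["gene"]).dropna().to_numpy()
        if len(vals):
            by_state[state] = vals
    states = sorted(by_state)
    pmat = pd.DataFrame(np.ones((len(states), len(states))), index=states, columns=states)
    for i, a in enumerate(states):
        for j, b in enumerate(states):
            if i < j:
                p = stats.ranksums(by_state[a], by_state[b]).pvalue
                pmat.loc[a, b] = pmat.loc[b, a] = p
    return {"rpkm_by_state": by_state, "gene_states": gs, "wilcoxon_p": pmat}


def cell_specific_genes(expr: pd.DataFrame, focal_line: str,
                        threshold: float = 10.0) -> tuple[set[str], set[str]]:
    """Focal-line-specific and broadly expressed gene sets.

    Specific: strictly above ``threshold`` RPKM in the focal line and at or
    below it in every other line.  Broad: strictly above the threshold in
    every line.
    """
    lines = [c for c in expr.columns if c != "gene"]
    if len(lines) < 2:
        raise ValueError("need at least two cell lines")
    if focal_line not in lines:
        raise ValueError(f"unknown focal line {focal_line!r}")
    others = [c for c in lines if c != focal_line]
    focal_hi = expr[focal_line] > threshold
    others_lo = (expr[others] <= threshold).all(axis=1)
    all_hi = (expr[lines] > threshold).all(axis=1)
    specific = set(expr.loc[focal_hi & others_lo, "gene"])
    broad = set(expr.loc[all_hi, "gene"])
    return specific, broad


def go_enrichment(genes: set[str], background: set[str], annotations: pd.DataFrame,
                  min_fold: float = 1.2, alpha: float = 0.05,
                  keep_all: bool = False) -> pd.DataFrame:
    """Classic Fisher-per-term GO enrichment with BH correction.

    ``annotations`` maps gene -> term (flat table).  The 2x2 per term is
    (in-set / out-of-set) x (in-term / out-of-term) over the background;
    fold = (set fraction in term) / (background fraction in term).  Rows
    with q < alpha and fold > min_fold pass; by default only passing rows
    are returned (``keep_all=True`` returns every term with a ``passed``
    flag).
    """
    genes = set(genes) & set(background)
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    ann = annotations.loc[annotations["gene"].isin(background)]
    n_set, n_bg = len(genes), len(background)
    rows = []
    for term, sub in ann.groupby("term"):
        in_term = set(sub["gene"])
        a = len(genes & in_term)
        b = n_set - a
        c = len(in_term) - a
        d = n_bg - n_set - c
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        fold = (a / n_set) / (len(in_term) / n_bg) if n_set and in_term else 0.0
        rows.append((term, a, len(in_term), fold, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "fold", "p"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = np.array([], dtype=float)
    out["passed"] = (out["q"] < alpha) & (out["fold"] > min_fold)
    out = out.sort_values("p").reset_index(drop=True)
    return out if keep_all else out.loc[out["passed"]].reset_index(drop=True)


def proximal_vs_distal_go(proximal_targets: dict[str, set[str]],
                          distal_targets: dict[str, set[str]],
                          annotations: pd.DataFrame,
                          background: set[str] | None = None,
                          epsilon: float = 1e-300) -> pd.DataFrame:
    """log2(p_proximal / p_distal) per TF x GO term.

    Only TFs with targets in both networks are compared; p-values are
    floored at ``epsilon`` before ratioing.  Negative entries mean the
    term is more strongly enriched among the TF's proximal targets,
    positive entries among its distal targets.
    """
    tfs = sorted(set(proximal_targets) & set(distal_targets))
    tfs = [t for t in tfs if proximal_targets[t] and distal_targets[t]]
    if background is None:
        background = set(annotations["gene"])
    terms = sorted(annotations["term"].unique())
    mat = pd.DataFrame(np.zeros((len(tfs), len(terms))), index=tfs, columns=terms)
    for tf in tfs:
        pp = go_enrichment(proximal_targets[tf], background, annotations,
                           keep_all=True).set_index("term")["p"]
        pd_ = go_enrichment(distal_targets[tf], background, annotations,
                            keep_all=True).set_index("term")["p"]
        for term in terms:
            p1 = max(float(pp.get(term, 1.0)), epsilon)
            p2 = max(float(pd_.get(term, 1.0)), epsilon)
            mat.loc[tf, term] = np.log2(p1 / p2)
    return mat
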