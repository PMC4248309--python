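"""Proximal/distal/combined TF-target networks and their three-tier hierarchy.

A proximal edge TF -> gene records a TF peak inside the gene's promoter
(TSS +- 5 kb); a distal edge records a TF peak at one anchor of an
interaction whose other anchor holds a gene promoter (promoter-promoter
interactions are excluded).  The combined network is the edge union.
TF-only networks (induced subgraphs on the factor nodes) are organized
into three tiers by simulated annealing maximizing downward-pointing edges
(tier 1 on top; an edge u -> v is downward when tier(u) < tier(v)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import networkx as nx

from loopscape.config import substream
from loopscape.intervals import by_chrom


def promoter_intervals(genes: pd.DataFrame, pad: int = 5000) -> pd.DataFrame:
    """Symmetric promoters [TSS - pad, TSS + pad) per gene."""
    return pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.maximum(0, genes["tss"] - pad),
        "end": genes["tss"] + pad,
        "gene": genes["gene"],
    }).reset_index(drop=True)


def _genes_hit(prom: pd.DataFrame, peaks: pd.DataFrame) -> set[str]:
    idx = by_chrom(peaks)
    hit = set()
    for chrom, sub in prom.groupby("chrom", sort=False):
        tree = idx.get(chrom)
        if tree is None:
            continue
        ov = tree.any_overlap(sub["start"].to_numpy(), sub["end"].to_numpy())
        hit.update(sub.loc[sub.index[ov], "gene"])
    return hit


def build_proximal(tf_peaksets: dict[str, pd.DataFrame], genes: pd.DataFrame,
                   promoter_pad: int = 5000) -> nx.DiGraph:
    """Edges TF -> gene for every TF peak overlapping the gene's promoter."""
    g = nx.DiGraph(flavor="proximal")
    prom = promoter_intervals(genes, promoter_pad)
    for tf, peaks in tf_peaksets.items():
        g.add_node(tf, kind="tf")
        for gene in _genes_hit(prom, peaks):
            g.add_edge(tf, gene)
    return g


def build_distal(tf_peaksets: dict[str, pd.DataFrame], calls: pd.DataFrame,
                 genes: pd.DataFrame, promoter_pad: int = 5000) -> nx.DiGraph:
    """Edges TF -> gene through interactions: TF at one anchor, promoter at
    the other; promoter-promoter interactions are skipped."""
    g = nx.DiGraph(flavor="distal")
    prom = promoter_intervals(genes, promoter_pad)
    prom_idx = by_chrom(prom)
    calls = calls.reset_index(drop=True)

    def genes_at(side):
        """Per call: genes whose promoter overlaps the side's anchor."""
        out = [[] for _ in range(len(calls))]
        for chrom, sub in calls.groupby("chrom", sort=False):
            tree = prom_idx.get(chrom)
            if tree is None:
                continue
            hits = tree.overlapping(sub[f"start{side}"].to_numpy(),
                                    sub[f"end{side}"].to_numpy())
            for row, h in zip(sub.index, hits):
                out[row] = list(prom["gene"].to_numpy()[tree.payload[h]])
        return out

    g1, g2 = genes_at(1), genes_at(2)
    pp = [bool(a) and bool(b) for a, b in zip(g1, g2)]  # promoter-promoter

    for tf, peaks in tf_peaksets.items():
        g.add_node(tf, kind="tf")
        idx = by_chrom(peaks)
        for side, gene_lists in ((1, g2), (2, g1)):
            for row in range(len(calls)):
                if pp[row] or not gene_lists[row]:
                    continue
                r = calls.iloc[row]
                tree = idx.get(r["chrom"])
                if tree is None:
                    continue
                if tree.any_overlap(np.array([r[f"start{side}"]]),
                                    np.array([r[f"end{side}"]]))[0]:
                    for gene in gene_lists[row]:
                        g.add_edge(tf, gene)
    return g


def combine_networks(proximal: nx.DiGraph, distal: nx.DiGraph) -> nx.DiGraph:
    g = nx.DiGraph(flavor="combined")
    g.add_nodes_from(proximal.nodes(data=True))
    g.add_nodes_from(distal.nodes(data=True))
    g.add_edges_from(proximal.edges)
    g.add_edges_from(distal.edges)
    return g


def tf_only(network: nx.DiGraph, tf_list: list[str]) -> nx.DiGraph:
    """Induced subgraph on the TF nodes (self-loops retained)."""
    missing = set(tf_list) - set(network.nodes)
    if missing:
        raise ValueError(f"TFs absent from network: {sorted(missing)}")
    return network.subgraph(tf_list).copy()


@dataclass
class Hierarchy:
    """Three-tier assignment of a TF-only network."""

    tiers: dict[str, int]                 # node -> 1 (top), 2, 3
    n_downward: int
    n_upward: int
    n_lateral: int
    build_objectives: list = field(default_factory=list)

    def edge_counts(self):
        return self.n_downward, self.n_upward, self.n_lateral


def _count_edges(edges: list[tuple[int, int]], tier: np.ndarray) -> tuple[int, int, int]:
    down = up = lat = 0
    for u, v in edges:
        tu, tv = tier[u], tier[v]
        if tu < tv:
            down += 1
        elif tu > tv:
            up += 1
        else:
            lat += 1
    return down, up, lat


def _anneal_once(edges, n_nodes, rng, moves_per_level, cooling, patience):
    tier = rng.integers(1, 4, size=n_nodes)
    out_edges = [[] for _ in range(n_nodes)]
    in_edges = [[] for _ in range(n_nodes)]
    for u, v in edges:
        out_edges[u].append(v)
        in_edges[v].append(u)

    def node_down(node, t):
        s = sum(1 for v in out_edges[node] if v != node and t < tier[v])
        s += sum(1 for u in in_edges[node] if u != node and tier[u] < t)
        return s

    obj = _count_edges(edges, tier)[0]
    best_tier, best_obj = tier.copy(), obj

    # calibrate T0 so ~80% of random moves would be accepted
    deltas = []
    for _ in range(100):
        node = rng.integers(0, n_nodes)
        new_t = rng.integers(1, 4)
        d = node_down(node, new_t) - node_down(node, tier[node])
        if d < 0:
            deltas.append(-d)
    t = (np.mean(deltas) / -np.log(0.8)) if deltas else 1.0

    stale = 0
    while stale < patience:
        accepted = 0
        for _ in range(moves_per_level):
            node = rng.integers(0, n_nodes)
            new_t = rng.integers(1, 4)
            if new_t == tier[node]:
                continue
            d = node_down(node, new_t) - node_down(node, tier[node])
            if d >= 0 or rng.random() < np.exp(d / max(t, 1e-12)):
                tier[node] = new_t
                obj += d
                accepted += 1
                if obj > best_obj:
                    best_obj, best_tier = obj, tier.copy()
        stale = 0 if accepted else stale + 1
        t *= cooling
        if t < 1e-6:
            break
    return best_tier, best_obj


def fit_hierarchy(tf_network: nx.DiGraph, n_builds: int = 5, seed: int = 0,
                  moves_per_node: int = 3, cooling: float = 0.95,
                  patience: int = 3) -> Hierarchy:
    """Organize TF nodes into three tiers maximizing downward edges.

    ``n_builds`` independent annealing runs; the assignment with the most
    downward-pointing edges is kept (lateral edges do not enter the
    objective).  Every run tracks its best-seen state, so the reported
    objective never regresses within a run.
    """
    if tf_network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    nodes = sorted(tf_network.nodes)
    node_id = {n: i for i, n in enumerate(nodes)}
    edges = [(node_id[u], node_id[v]) for u, v in tf_network.edges]
    rng = substream(seed, "hierarchy")
    moves = max(moves_per_node * len(nodes), 10)
    best = None
    objectives = []
    for _ in range(n_builds):
        tier, obj = _anneal_once(edges, len(nodes), rng, moves, cooling, patience)
        objectives.append(obj)
        if best is None or obj > best[1]:
            best = (tier, obj)
    tier, obj = best
    down, up, lat = _count_edges(edges, tier)
    assert down == obj
    return Hierarchy(tiers={n: int(tier[node_id[n]]) for n in nodes},
                     n_downward=down, n_upward=up, n_lateral=lat,
                     build_objectives=objectives)


def exhaustive_hierarchy(tf_network: nx.DiGraph) -> int:
    """Brute-force optimum of the downward-edge objective (small networks)."""
    nodes = sorted(tf_network.nodes)
    node_id = {n: i for i, n in enumerate(nodes)}
    edges = [(node_id[u], node_id[v]) for u, v in tf_network.edges]
    best = 0
    for assign in product((1, 2, 3), repeat=len(nodes)):
        t = np.array(assign)
        best = max(best, _count_edges(edges, t)[0])
    return best


def tier_degree_stats(network: nx.DiGraph, hierarchy: Hierarchy) -> pd.DataFrame:
    """Degree (in + out in the full network) of each tiered node, by tier."""
    rows = []
    for node, tier in hierarchy.tiers.items():
        deg = network.in_degree(node) + network.out_degree(node) \
            if node in network else 0
        rows.append((node, tier, deg))
    return pd.DataFrame(rows, columns=["node", "tier", "degree"])
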