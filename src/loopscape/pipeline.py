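"""End-to-end orchestration: simulate -> filter -> anchor -> call -> integrate.

``run_pipeline`` executes the enabled stages in dependency order on a
synthetic experiment, writes every product as plain text under ``outdir``
and returns a manifest (inputs, outputs, row counts, config hash).  Rerun
with the same configuration and seed, every output file is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from loopscape import io
from loopscape.config import SimConfig, CallerConfig, DEFAULT_SELF_CIRC_MAX_SPAN
from loopscape.simulate import (simulate_peaks, make_loop_truth, simulate_pets,
                                simulate_companion_tracks)
from loopscape.pets import filter_pets, assign_to_anchors
from loopscape.caller import call_interactions
from loopscape.annotate import annotate_dhs, classify_interactions, tad_overlap
from loopscape.enrichment import tf_enrichment, hot_enrichment
from loopscape.som import som_fit, som_interaction_enrichment
from loopscape.domains import bin_signals, normalize_profiles, cluster_loops
from loopscape.networks import (build_proximal, build_distal, combine_networks,
                                tf_only, fit_hierarchy)
from loopscape.expression import distal_state_expression, go_enrichment

PACKAGE_VERSION = "0.1.0"


#: Stages in dependency order; disabling one disables its dependents.
STAGE_ORDER = ["simulate", "filter", "anchor", "call", "annotate",
               "enrich", "som", "domains", "network", "expression"]
STAGE_DEPS = {
    "filter": ["simulate"], "anchor": ["filter"], "call": ["anchor"],
    "annotate": ["call"], "enrich": ["annotate"], "som": ["enrich"],
    "domains": ["call"], "network": ["annotate"], "expression": ["annotate"],
}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    stages: tuple[str, ...] = tuple(STAGE_ORDER)
    self_circ_max_span: int = DEFAULT_SELF_CIRC_MAX_SPAN
    border_pad: int = 20_000
    promoter_pad: int = 5000
    promoter_upstream: int = 2000
    som_grid: tuple[int, int] = (4, 4)
    som_restarts: int = 10
    domains_k: int = 8
    hierarchy_builds: int = 5
    hot_rewires: int = 10_000
    seed: int = 0

    def __post_init__(self):
        self.sim.seed = self.seed
        self.caller.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["genome"] = [list(g) for g in self.sim.genome]
        d["stages"] = list(self.stages)
        d["som_grid"] = list(self.som_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        sim["genome"] = [tuple(g) for g in sim.get("genome", SimConfig().genome)]
        caller = d.pop("caller", {})
        d["stages"] = tuple(d.get("stages", STAGE_ORDER))
        d["som_grid"] = tuple(d.get("som_grid", (4, 4)))
        return cls(sim=SimConfig(**sim), caller=CallerConfig(**caller), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _resolve_stages(requested) -> list[str]:
    enabled = set(requested)
    for stage in STAGE_ORDER:
        if stage in enabled:
            missing = [d for d in STAGE_DEPS.get(stage, []) if d not in enabled]
            if missing:
                raise ValueError(
                    f"stage '{stage}' requires upstream stage(s) {missing}; "
                    f"enable them or drop '{stage}'")
    return [s for s in STAGE_ORDER if s in enabled]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages; returns the manifest (also written as JSON)."""
    out = io.ensure_dir(outdir)
    stages = _resolve_stages(config.stages)
    manifest = {"version": PACKAGE_VERSION, "seed": config.seed,
                "config_hash": config.config_hash(), "stages": stages,
                "outputs": {}, "counts": {}}
    state: dict = {}

    def emit(name, writer, obj):
        path = out / name
        writer(obj, path)
        manifest["outputs"][name] = str(path)
        if hasattr(obj, "__len__"):
            manifest["counts"][name] = len(obj)

    if "simulate" in stages:
        peaks = simulate_peaks(config.sim)
        truth = make_loop_truth(peaks, config.sim)
        pets = simulate_pets(peaks, truth, config.sim)
        tracks = simulate_companion_tracks(config.sim, peaks, truth)
        state.update(peaks=peaks, truth=truth, pets=pets, tracks=tracks)
        emit("peaks.bed", lambda o, p: io.write_bed(o.anchors, p, ["chrom", "start", "end", "id"]), peaks)
        emit("pets.bedpe", io.write_bedpe, pets)
        emit("truth.tsv", io.write_table, truth)

    if "filter" in stages:
        clean, self_circ, report = filter_pets(state["pets"], config.self_circ_max_span)
        state.update(clean=clean, self_circ=self_circ, report=report)
        emit("pets.clean.bedpe", io.write_bedpe, clean)

    if "anchor" in stages:
        anchored, report = assign_to_anchors(state["clean"], state["peaks"], state["report"])
        state["anchored"] = anchored
        emit("pets.anchored.tsv", io.write_table, anchored)
        (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        manifest["outputs"]["filter_report.json"] = str(out / "filter_report.json")

    if "call" in stages:
        result = call_interactions(state["anchored"], state["peaks"], config.caller)
        state["result"] = result
        calls = result["calls"]
        state["passed"] = calls.loc[calls["passed"]].reset_index(drop=True)
        bedpe = pd.DataFrame({
            "chrom1": calls["chrom"], "start1": calls["start1"], "end1": calls["end1"],
            "chrom2": calls["chrom"], "start2": calls["start2"], "end2": calls["end2"],
            "name": calls["anchor1"] + "|" + calls["anchor2"],
            "score": calls["z"].round(6), "strand1": ".", "strand2": ".",
        })
        emit("calls.all.bedpe", io.write_bedpe, bedpe)
        emit("calls.passed.bedpe", io.write_bedpe, bedpe.loc[calls["passed"].to_numpy()])
        manifest["counts"]["threshold_z"] = result["threshold"]
        manifest["counts"]["empirical_fdr"] = result["empirical_fdr"]

    if "annotate" in stages:
        tracks = state["tracks"]
        elements = annotate_dhs(tracks["dhs"], tracks["states"])
        typed, comp = classify_interactions(state["passed"], elements)
        typed, tad_summary = tad_overlap(typed, tracks["tads"], config.border_pad)
        state.update(elements=elements, typed=typed)
        emit("elements.tsv", io.write_table, elements)
        emit("calls.annotated.tsv", io.write_table, typed)
        emit("interaction_types.tsv", io.write_table, comp)
        emit("tad_summary.tsv", io.write_table, tad_summary)

    if "enrich" in stages:
        tracks = state["tracks"]
        anchors_df = state["peaks"].anchors
        passed = state["passed"]
        inter_ids = set(passed["anchor1"]) | set(passed["anchor2"])
        interacting = anchors_df.loc[anchors_df["id"].isin(inter_ids)].reset_index(drop=True)
        enr = tf_enrichment(interacting, anchors_df, tracks["tf_peaks"], seed=config.seed)
        hot = hot_enrichment(passed, interacting, anchors_df, tracks["hot"],
                             n_rewires=config.hot_rewires, seed=config.seed)
        state["interacting"] = interacting
        emit("tf_enrichment.tsv", io.write_table, enr)
        (out / "hot_enrichment.json").write_text(json.dumps(
            {k: v for k, v in hot.items() if not isinstance(v, np.ndarray)}, indent=1))
        manifest["outputs"]["hot_enrichment.json"] = str(out / "hot_enrichment.json")

    if "som" in stages:
        tracks = state["tracks"]
        anchors_df = state["peaks"].anchors
        inter_ids = set(state["passed"]["anchor1"]) | set(state["passed"]["anchor2"])
        cols = {}
        for tf, peaks in tracks["tf_peaks"].items():
            key = set(zip(peaks["chrom"], peaks["start"]))
            cols[tf] = [int((c, s) in key) for c, s in
                        zip(anchors_df["chrom"], anchors_df["start"])]
        bmat = pd.DataFrame(cols)
        flags = anchors_df["id"].isin(inter_ids).to_numpy()
        model = som_fit(bmat, grid_dims=config.som_grid,
                        n_restarts=config.som_restarts, seed=config.seed)
        neurons = som_interaction_enrichment(model, flags)
        emit("som_neurons.tsv", io.write_table, neurons)

    if "domains" in stages:
        tracks = state["tracks"]
        profiles, kept, marks = bin_signals(state["passed"], tracks["coverage"])
        if len(kept) >= config.domains_k:
            norm = normalize_profiles(profiles)
            lengths = (kept["start2"] - kept["end1"]).to_numpy()
            groups = cluster_loops(norm, lengths, k=config.domains_k, seed=config.seed)
            kept = kept.assign(domain_group=groups.group)
            emit("loop_domains.tsv", io.write_table,
                 kept[["chrom", "start1", "end1", "start2", "end2", "domain_group"]])

    if "network" in stages:
        tracks = state["tracks"]
        prox = build_proximal(tracks["tf_peaks"], tracks["genes"], config.promoter_pad)
        dist = build_distal(tracks["tf_peaks"], state["passed"], tracks["genes"],
                            config.promoter_pad)
        comb = combine_networks(prox, dist)
        tf_list = sorted(tracks["tf_peaks"])
        hier = {}
        for flavor, net in (("proximal", prox), ("distal", dist), ("combined", comb)):
            sub = tf_only(net, tf_list)
            h = fit_hierarchy(sub, n_builds=config.hierarchy_builds, seed=config.seed)
            hier[flavor] = {"tiers": h.tiers, "downward": h.n_downward,
                            "upward": h.n_upward, "lateral": h.n_lateral}
            edges = pd.DataFrame(sorted(net.edges), columns=["source", "target"])
            edges["flavor"] = flavor
            emit(f"network_{flavor}.tsv", io.write_table, edges)
        (out / "hierarchy.json").write_text(json.dumps(hier, indent=1))
        manifest["outputs"]["hierarchy.json"] = str(out / "hierarchy.json")
        state.update(prox=prox, dist=dist)

    if "expression" in stages:
        tracks = state["tracks"]
        res = distal_state_expression(state["passed"], state["elements"],
                                      tracks["genes"], tracks["rpkm"],
                                      promoter_upstream=config.promoter_upstream)
        med = {s: float(np.median(v)) for s, v in res["rpkm_by_state"].items()}
        emit("distal_state_wilcoxon.tsv", io.write_table,
             res["wilcoxon_p"].reset_index(names="state"))
        e_genes = set(res["gene_states"].loc[res["gene_states"]["state"] == "E", "gene"])
        bg = set(tracks["genes"]["gene"])
        go = go_enrichment(e_genes, bg, tracks["go"], keep_all=True) if e_genes \
            else pd.DataFrame()
        emit("go_e_looped.tsv", io.write_table, go)
        manifest["counts"]["median_rpkm_by_state"] = med

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
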