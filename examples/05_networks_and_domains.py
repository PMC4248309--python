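"""Regulatory networks with tier hierarchy, and loop-domain clustering.

Builds proximal (TF peak in promoter) and distal (TF loops to promoter)
TF-target networks, organizes the TF-only networks into three tiers by
simulated annealing, clusters loops by histone meta-profiles, and relates
distal chromatin state to expression.
"""

import numpy as np

import loopscape as ls
from loopscape.config import SimConfig, CallerConfig
from loopscape.simulate import make_loop_truth

config = SimConfig(seed=5, genome=(("chr1", 5_000_000),), n_peaks=150,
                   n_true_loops=60, n_background_pets=30_000,
                   max_distance_bp=2_500_000)
peaks = ls.simulate_peaks(config)
truth = make_loop_truth(peaks, config)
pets = ls.simulate_pets(peaks, truth, config)
clean, _, report = ls.filter_pets(pets)
anchored, _ = ls.assign_to_anchors(clean, peaks, report)
result = ls.call_interactions(anchored, peaks, CallerConfig(seed=5))
passed = result["calls"].loc[result["calls"]["passed"]].reset_index(drop=True)
tracks = ls.simulate_companion_tracks(config, peaks, truth)

prox = ls.build_proximal(tracks["tf_peaks"], tracks["genes"])
dist = ls.build_distal(tracks["tf_peaks"], passed, tracks["genes"])
comb = ls.combine_networks(prox, dist)
print(f"edges: proximal {prox.number_of_edges()}, distal {dist.number_of_edges()}, "
      f"combined {comb.number_of_edges()}")

tf_net = ls.tf_only(comb, sorted(tracks["tf_peaks"]))
hier = ls.fit_hierarchy(tf_net, n_builds=5, seed=5)
print(f"hierarchy: downward {hier.n_downward}, upward {hier.n_upward}, "
      f"lateral {hier.n_lateral}; tiers {hier.tiers}")

profiles, kept, marks = ls.bin_signals(passed, tracks["coverage"])
groups = ls.cluster_loops(ls.normalize_profiles(profiles),
                          (kept["start2"] - kept["end1"]).to_numpy(),
                          k=8, seed=5)
sizes = np.bincount(groups.group)[1:]
print(f"loop-domain groups (by increasing median length): sizes {list(sizes)}")

elements = ls.annotate_dhs(tracks["dhs"], tracks["states"])
res = ls.distal_state_expression(passed, elements, tracks["genes"],
                                 tracks["rpkm"], expr_col="cellA")
for state in sorted(res["rpkm_by_state"]):
    vals = res["rpkm_by_state"][state]
    print(f"median RPKM with distal {state}: {np.median(vals):.2f} (n={len(vals)})")
# Genes looping to enhancer (E) elements out-express genes looping to
# repressed (R) elements; the hierarchy maximizes edges pointing from
# upper tiers to lower ones.
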