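"""Which factors and co-binding patterns mark interacting loci?

Per-TF Fisher enrichment at interacting loci, HOT-region tests, and a
toroidal self-organizing map of binary TF co-binding profiles with
neuron-level interaction enrichment.
"""

import pandas as pd

import loopscape as ls
from loopscape.config import SimConfig, CallerConfig
from loopscape.simulate import make_loop_truth

config = SimConfig(seed=4, genome=(("chr1", 5_000_000),), n_peaks=150,
                   n_true_loops=25, n_background_pets=30_000,
                   max_distance_bp=2_500_000)
peaks = ls.simulate_peaks(config)
truth = make_loop_truth(peaks, config)
pets = ls.simulate_pets(peaks, truth, config)
clean, _, report = ls.filter_pets(pets)
anchored, _ = ls.assign_to_anchors(clean, peaks, report)
result = ls.call_interactions(anchored, peaks, CallerConfig(seed=4))
passed = result["calls"].loc[result["calls"]["passed"]].reset_index(drop=True)
tracks = ls.simulate_companion_tracks(config, peaks, truth)

anchors = peaks.anchors
inter_ids = set(passed["anchor1"]) | set(passed["anchor2"])
interacting = anchors.loc[anchors["id"].isin(inter_ids)].reset_index(drop=True)

enr = ls.tf_enrichment(interacting, anchors, tracks["tf_peaks"], seed=4)
print("TF enrichment at interacting loci:")
print(enr[["tf", "log2_obs_exp", "p_bonferroni", "category"]].to_string(index=False))

hot = ls.hot_enrichment(passed, interacting, anchors, tracks["hot"],
                        n_rewires=2000, seed=4)
print(f"\nHOT-HOT interactions: observed {hot['observed_hot_hot']} vs "
      f"expected {hot['expected_hot_hot']:.1f} (permutation p = {hot['pair_p']:.4f})")

# binary co-binding matrix: rows = anchors, columns = TFs
cols = {}
for tf, pk in tracks["tf_peaks"].items():
    bound = set(zip(pk["chrom"], pk["start"]))
    cols[tf] = [int((c, s) in bound) for c, s in zip(anchors["chrom"], anchors["start"])]
bmat = pd.DataFrame(cols)
model = ls.som_fit(bmat, grid_dims=(4, 4), n_restarts=10, seed=4)
neurons = ls.som_interaction_enrichment(
    model, anchors["id"].isin(inter_ids).to_numpy())
print(f"\nSOM mean distance: {model.mean_distance:.3f}; "
      f"enriched neurons: {int(neurons['enriched'].sum())}/{len(neurons)}")
# Architectural factors (RAD21/CTCF/ZNF143/SMC3) are planted at loop anchors,
# so they come out 'high' and their co-binding neurons are enriched.
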