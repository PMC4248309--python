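"""Annotate calls by regulatory-element type, TADs and 5C support.

Builds the regulatory-element universe (DHS labeled by dominant chromatin
state), types each interaction by its anchors' element labels, classifies
it against TADs, and measures 5C confirmation against a distance-matched
permutation null.
"""

import loopscape as ls
from loopscape.config import SimConfig, CallerConfig
from loopscape.simulate import make_loop_truth

config = SimConfig(seed=3, genome=(("chr1", 5_000_000),), n_peaks=150,
                   n_true_loops=60, n_background_pets=30_000,
                   max_distance_bp=2_500_000)
peaks = ls.simulate_peaks(config)
truth = make_loop_truth(peaks, config)
pets = ls.simulate_pets(peaks, truth, config)
clean, _, report = ls.filter_pets(pets)
anchored, _ = ls.assign_to_anchors(clean, peaks, report)
result = ls.call_interactions(anchored, peaks, CallerConfig(seed=3))
passed = result["calls"].loc[result["calls"]["passed"]].reset_index(drop=True)
tracks = ls.simulate_companion_tracks(config, peaks, truth, fraction_in_5c=0.7)

elements = ls.annotate_dhs(tracks["dhs"], tracks["states"])
typed, composition = ls.classify_interactions(
    passed.assign(source_dataset="RAD21"), elements)
print("interaction-type composition (%):")
print(composition.sort_values("percent", ascending=False)
      .head(5)[["interaction_type", "percent"]].to_string(index=False))

typed, tad_summary = ls.tad_overlap(typed, tracks["tads"])
print("\nTAD classes:")
print(tad_summary.to_string(index=False))

res = ls.fivec_overlap(passed, tracks["fivec"], tracks["fivec_tested"],
                       n_perm=200, seed=3)
print(f"\n5C support: observed {res['observed_percent']:.1f}% vs expected "
      f"{res['expected_percent']:.1f}% (permutation p = {res['p']:.3f})")
# Most calls fall inside one TAD, and 5C confirmation far exceeds the
# distance-matched expectation because 70% of planted loops are in the 5C set.
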