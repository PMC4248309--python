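"""Element annotation, interaction typing, TAD and 5C overlap."""

import numpy as np
import pandas as pd
import pytest

import loopscape as ls
from loopscape.annotate import (annotate_dhs, classify_interactions,
                                tad_overlap, fivec_overlap, LABEL_PRIORITY)


def bed(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestAnnotateDhs:
    def test_fully_inside_one_state(self):
        dhs = bed([("chr1", 100, 400)])
        states = bed([("chr1", 0, 1000, "E")], ("chrom", "start", "end", "state"))
        assert annotate_dhs(dhs, states)["state"].iloc[0] == "E"

    def test_argmax_overlap_wins(self):
        dhs = bed([("chr1", 0, 800)])
        states = bed([("chr1", 0, 300, "E"), ("chr1", 300, 800, "TSS")],
                     ("chrom", "start", "end", "state"))
        assert annotate_dhs(dhs, states)["state"].iloc[0] == "TSS"

    def test_no_overlap_is_undefined(self):
        dhs = bed([("chr1", 5000, 5400)])
        states = bed([("chr1", 0, 1000, "E")], ("chrom", "start", "end", "state"))
        assert annotate_dhs(dhs, states)["state"].iloc[0] == "undefined"

    def test_tie_breaks_by_priority(self):
        dhs = bed([("chr1", 0, 400)])
        states = bed([("chr1", 0, 200, "R"), ("chr1", 200, 400, "E")],
                     ("chrom", "start", "end", "state"))
        assert annotate_dhs(dhs, states)["state"].iloc[0] == "E"

    def test_order_invariant_and_matches_per_base_oracle(self):
        rng = np.random.default_rng(31)
        labels = ["TSS", "E", "WE", "CTCF", "T", "R"]
        segs, pos = [], 0
        while pos < 200_000:
            w = int(rng.integers(200, 3000))
            segs.append(("chr1", pos, pos + w, labels[int(rng.integers(0, 6))]))
            pos += w + int(rng.integers(0, 500))
        states = bed(segs, ("chrom", "start", "end", "state"))
        dhs = bed([("chr1", int(s), int(s) + int(rng.integers(100, 2500)))
                   for s in rng.integers(0, 200_000, size=300)])
        got = annotate_dhs(dhs, states)["state"]
        shuffled = annotate_dhs(dhs, states.sample(frac=1, random_state=1))["state"]
        assert list(got) == list(shuffled)

        prio = {lab: k for k, lab in enumerate(LABEL_PRIORITY)}
        for k, row in dhs.iterrows():
            bp = {}
            for _, s in states.iterrows():
                ov = min(row["end"], s["end"]) - max(row["start"], s["start"])
                if ov > 0:
                    bp[s["state"]] = bp.get(s["state"], 0) + ov
            expect = min(bp, key=lambda l: (-bp[l], prio[l])) if bp else "undefined"
            assert got.iloc[k] == expect


class TestClassifyInteractions:
    def elements(self):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [100, 5000, 9000, 20_000],
            "end": [600, 5500, 9500, 20_500],
            "state": ["CTCF", "CTCF", "TSS", "E"],
        })

    def call(self, s1, e1, s2, e2):
        return pd.DataFrame([{"chrom": "chr1", "start1": s1, "end1": e1,
                              "start2": s2, "end2": e2,
                              "source_dataset": "RAD21"}])

    def test_ctcf_both_sides(self):
        typed, _ = classify_interactions(self.call(50, 700, 4900, 5600),
                                         self.elements())
        assert typed["interaction_type"].iloc[0] == "CTCF-CTCF"

    def test_priority_tss_over_e(self):
        elements = pd.DataFrame({
            "chrom": "chr1", "start": [100, 150], "end": [600, 650],
            "state": ["E", "TSS"]})
        typed, _ = classify_interactions(self.call(50, 700, 5000, 5600), elements)
        assert typed["label1"].iloc[0] == "TSS"

    def test_no_element_is_undefined(self):
        typed, _ = classify_interactions(self.call(40_000, 41_000, 50_000, 51_000),
                                         self.elements())
        assert typed["interaction_type"].iloc[0] == "undefined-undefined"

    def test_composition_sums_to_100_per_factor(self, small_call, small_tracks):
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].assign(source_dataset="H3K4me3")
        elements = annotate_dhs(small_tracks["dhs"], small_tracks["states"])
        _, comp = classify_interactions(passed, elements)
        for _, grp in comp.groupby("factor"):
            assert grp["percent"].sum() == pytest.approx(100.0)


class TestTadOverlap:
    def tads(self):
        return bed([("chr1", 0, 1_000_000), ("chr1", 1_000_000, 2_000_000)])

    def call(self, m1, m2):
        return pd.DataFrame([{"chrom": "chr1", "start1": m1 - 500, "end1": m1 + 500,
                              "start2": m2 - 500, "end2": m2 + 500}])

    def test_mid_tad_is_intra(self):
        typed, _ = tad_overlap(self.call(400_000, 600_000), self.tads())
        assert typed["tad_class"].iloc[0] == "intra"

    def test_adjacent_tads_is_inter(self):
        typed, _ = tad_overlap(self.call(900_000, 1_100_000), self.tads())
        assert typed["tad_class"].iloc[0] == "inter"

    def test_border_touch_is_border(self):
        typed, _ = tad_overlap(self.call(500_000, 990_000), self.tads())
        assert typed["tad_class"].iloc[0] == "border"

    def test_outside_all_tads_unassigned(self):
        typed, _ = tad_overlap(self.call(2_500_000, 2_600_000), self.tads())
        assert typed["tad_class"].iloc[0] == "unassigned"

    def test_every_call_gets_exactly_one_class(self, small_call, small_tracks):
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        typed, summary = tad_overlap(passed, small_tracks["tads"])
        assert summary["n"].sum() == len(passed)
        assert typed["tad_class"].isin(["intra", "border", "inter", "unassigned"]).all()

    def test_matches_per_anchor_containment_oracle(self, small_call, small_tracks):
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        tads = small_tracks["tads"]
        pad = 20_000
        typed, _ = tad_overlap(passed, tads, border_pad=pad)
        borders = []
        for _, t in tads.iterrows():
            borders += [(max(0, t["start"] - pad), t["start"] + pad),
                        (max(0, t["end"] - pad), t["end"] + pad)]
        for _, r in typed.iterrows():
            m1 = (r["start1"] + r["end1"]) // 2
            m2 = (r["start2"] + r["end2"]) // 2
            t1 = [k for k, t in tads.iterrows() if t["start"] <= m1 < t["end"]]
            t2 = [k for k, t in tads.iterrows() if t["start"] <= m2 < t["end"]]
            if not t1 or not t2:
                expect = "unassigned"
            elif t1[0] != t2[0]:
                expect = "inter"
            else:
                lo, hi = min(m1, m2), max(m1, m2)
                touch = any(lo <= be and bs <= hi for bs, be in borders)
                expect = "border" if touch else "intra"
            assert r["tad_class"] == expect


class TestFivecOverlap:
    def test_forced_full_overlap(self, small_config, small_peaks, small_truth,
                                 small_call):
        tracks = ls.simulate_companion_tracks(small_config, small_peaks,
                                              small_truth, fraction_in_5c=1.0)
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        res = fivec_overlap(passed, tracks["fivec"], tracks["fivec_tested"],
                            n_perm=50, seed=1)
        # nearly every passed call is a planted loop, all of which are in 5C
        assert res["observed_percent"] >= 95.0
        assert res["p"] <= 0.05

    def test_disjoint_pairs_give_zero(self, small_call, small_tracks):
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        fivec = pd.DataFrame({"chrom1": ["chr2"], "start1": [0], "end1": [100],
                              "chrom2": ["chr2"], "start2": [500], "end2": [600],
                              "name": ["x"]})
        res = fivec_overlap(passed, fivec, small_tracks["fivec_tested"],
                            n_perm=20, seed=1)
        assert res["observed_percent"] == 0.0

    def test_no_calls_in_region_is_undefined(self, small_call, small_tracks):
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        region = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [1000]})
        res = fivec_overlap(passed, small_tracks["fivec"], region, n_perm=10, seed=1)
        assert np.isnan(res["observed_percent"]) and res["n_tested"] == 0

    def test_p_value_bounds(self, small_call, small_tracks):
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        res = fivec_overlap(passed, small_tracks["fivec"],
                            small_tracks["fivec_tested"], n_perm=99, seed=2)
        assert 1 / 100 <= res["p"] <= 1.0

    def test_expected_matches_independent_sampler(self, small_call, small_tracks):
        """The permutation mean agrees with an independent re-implementation
        of the distance-matched random draw (3 SE)."""
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        fivec, region = small_tracks["fivec"], small_tracks["fivec_tested"]
        pad, n_perm = 10_000, 300
        res = fivec_overlap(passed, fivec, region, pad=pad, n_perm=n_perm, seed=3)

        rng = np.random.default_rng(1234)
        p1s = np.maximum(0, passed["start1"] - pad)
        p1e = passed["end1"] + pad
        p2s = np.maximum(0, passed["start2"] - pad)
        p2e = passed["end2"] + pad
        dists = ((p2s + p2e) // 2 - (p1s + p1e) // 2).to_numpy()
        w1 = (p1e - p1s).to_numpy()
        w2 = (p2e - p2s).to_numpy()
        f1s, f1e = fivec["start1"].to_numpy(), fivec["end1"].to_numpy()
        f2s, f2e = fivec["start2"].to_numpy(), fivec["end2"].to_numpy()
        length = int(region["end"].iloc[0])
        vals = []
        for _ in range(n_perm):
            hits = 0
            span = np.maximum(1, length - dists - w2)
            s1 = (rng.random(len(passed)) * span).astype(np.int64)
            for a, d, wa, wb in zip(s1, dists, w1, w2):
                s2 = a + d
                ok = ((a < f1e) & (a + wa > f1s) & (s2 < f2e) & (s2 + wb > f2s)).any()
                hits += bool(ok)
            vals.append(100.0 * hits / len(passed))
        se = np.std(vals, ddof=1) / np.sqrt(n_perm) + \
            np.std(res["expected_distribution"], ddof=1) / np.sqrt(n_perm)
        assert abs(res["expected_percent"] - np.mean(vals)) < 3 * se + 0.5
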