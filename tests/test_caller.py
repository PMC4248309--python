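"""Interaction caller: pair counting, DMR rewiring, local Z, empirical FDR."""

import numpy as np
import pandas as pd
import pytest

import loopscape as ls
from loopscape.config import CallerConfig
from loopscape.caller import (count_pairs, rewire, local_z, call_at_fdr,
                              distance_bins, bin_of, pair_universe_per_bin,
                              empirical_fdr_curve, merge_datasets)
from conftest import toy_anchors


def anchored_frame(rows):
    """rows: (anchor1, anchor2, chrom, distance) tuples, one per PET."""
    df = pd.DataFrame(rows, columns=["anchor1", "anchor2", "chrom", "distance"])
    df["name"] = [f"pet{i}" for i in range(len(df))]
    return df


class TestCountPairs:
    def test_counts_and_empty(self):
        df = anchored_frame([("A", "B", "chr1", 100_000)] * 3
                            + [("A", "C", "chr1", 50_000)])
        got = count_pairs(df)
        assert set(zip(got["anchor1"], got["anchor2"], got["n_pets"])) == {
            ("A", "B", 3), ("A", "C", 1)}
        assert len(count_pairs(anchored_frame([]))) == 0

    def test_matches_hash_map_recount(self, small_anchored):
        got = count_pairs(small_anchored)
        oracle = {}
        for _, r in small_anchored.iterrows():
            oracle[(r["anchor1"], r["anchor2"])] = oracle.get(
                (r["anchor1"], r["anchor2"]), 0) + 1
        assert dict(zip(zip(got["anchor1"], got["anchor2"]), got["n_pets"])) == oracle


class TestRewire:
    def test_single_pair_universe_is_forced(self):
        anchors = toy_anchors([10_000, 100_000])
        d = 90_000
        anchored = anchored_frame([("P000000", "P000001", "chr1", d)] * 5)
        null = rewire(anchored, anchors, CallerConfig(seed=1))
        assert (null.rewired["anchor1"] == "P000000").all()
        assert (null.rewired["anchor2"] == "P000001").all()

    def test_distance_histogram_preserved(self, small_anchored, small_peaks):
        cfg = CallerConfig(seed=3)
        null = rewire(small_anchored, small_peaks, cfg)
        obs_hist = np.bincount(bin_of(small_anchored["distance"].to_numpy(), null.edges),
                               minlength=len(null.edges) - 1)
        for h in null.distance_histogram():
            assert np.array_equal(h, obs_hist)

    def test_mean_rewired_pair_counts_match_analytic_expectation(self):
        """On a 50-anchor fixture the rewired count of a pair, averaged over
        100 seeds, approaches n_d / (number of same-chromosome pairs in its
        distance bin)."""
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(np.arange(0, 2_000_000, 10_000), size=50,
                                    replace=False))
        anchors = toy_anchors(list(starts), width=2000)
        mids = anchors.midpoints.to_numpy()
        ids = anchors.anchors["id"].to_numpy()
        # observed PETs: 200 copies of one distance bin
        i, j = 5, 20
        d = abs(int(mids[j]) - int(mids[i]))
        n_pets = 200
        anchored = anchored_frame([(ids[i], ids[j], "chr1", d)] * n_pets)
        edges = distance_bins(np.array([d]), 1)

        totals: dict[tuple, float] = {}
        for seed in range(100):
            null = rewire(anchored, anchors, CallerConfig(seed=seed), edges=edges)
            for _, r in null.pair_counts.iterrows():
                key = (r["anchor1"], r["anchor2"])
                totals[key] = totals.get(key, 0) + r["n_pets"]

        # closed form: a PET picks anchor a uniformly (resampling among
        # eligible anchors when a has no in-bin candidate), then a partner
        # uniformly among a's candidates in the bin
        b = bin_of(np.array([d]), edges)[0]
        lo, hi = edges[b], edges[b + 1]
        n = len(mids)
        cands = {x: [y for y in range(n) if y != x
                     and lo <= abs(int(mids[y]) - int(mids[x])) < hi]
                 for x in range(n)}
        eligible = [x for x in range(n) if cands[x]]
        p_anchor = {x: (1 / n + (n - len(eligible)) / n / len(eligible))
                    if x in eligible else 0.0 for x in range(n)}
        pairs_in_bin = [(x, y) for x in range(n) for y in range(x + 1, n)
                        if y in cands[x]]
        expected = np.array([
            p_anchor[x] / len(cands[x]) + p_anchor[y] / len(cands[y])
            for x, y in pairs_in_bin]) * n_pets
        got = np.array([totals.get((ids[min(x, y)], ids[max(x, y)]), 0) / 100
                        for x, y in pairs_in_bin])
        assert abs(got.sum() - n_pets) < 1e-9  # PET count conserved exactly
        se = np.sqrt(expected / 100)  # binomial-ish SE of the 100-seed mean
        assert np.all(np.abs(got - expected) < 4 * se + 0.02)

    def test_single_anchor_chromosome_passes_through(self):
        anchors = toy_anchors([10_000])
        anchored = anchored_frame([("P000000", "P000000", "chr1", 0)])
        null = rewire(anchored, anchors, CallerConfig(seed=0))
        assert len(null.rewired) == 1


class TestLocalZ:
    def _tiny(self):
        starts = [i * 20_000 for i in range(20)]
        anchors = toy_anchors(starts, width=2000)
        mids = anchors.midpoints.to_numpy()
        ids = anchors.anchors["id"].to_numpy()
        rng = np.random.default_rng(9)
        rows = []
        for _ in range(300):
            x, y = sorted(rng.choice(20, size=2, replace=False))
            d = abs(int(mids[y]) - int(mids[x]))
            rows.append((ids[x], ids[y], "chr1", d))
        return anchors, anchored_frame(rows), mids, ids

    def test_z_zero_when_count_equals_mean(self):
        anchors = toy_anchors([10_000, 100_000])
        anchored = anchored_frame([("P000000", "P000001", "chr1", 90_000)] * 4)
        cfg = CallerConfig(seed=0, min_pairs_per_bin=1)
        null = rewire(anchored, anchors, cfg)
        obs = count_pairs(anchored)
        z_obs, _ = local_z(obs, null, anchors, cfg)
        # one-pair universe: mu = 4, sd = 0 -> z = 0
        assert z_obs["z"].iloc[0] == pytest.approx(0.0)

    def test_sd_floor_arithmetic(self):
        # mu = 4 and sd = 0 as above; a pair with 5 PETs would give z = 2 at floor 0.5
        anchors = toy_anchors([10_000, 100_000])
        anchored = anchored_frame([("P000000", "P000001", "chr1", 90_000)] * 4)
        cfg = CallerConfig(seed=0, sd_floor=0.5, min_pairs_per_bin=1)
        null = rewire(anchored, anchors, cfg)
        obs = count_pairs(anchored)
        obs.loc[0, "n_pets"] = 5
        z_obs, _ = local_z(obs, null, anchors, cfg)
        assert z_obs["z"].iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_bin_statistics(self):
        """Z-scores equal a literal re-computation of per-bin mean/SD by
        exhaustive enumeration of same-chromosome pairs (1e-9)."""
        anchors, anchored, mids, ids = self._tiny()
        cfg = CallerConfig(seed=4, min_pairs_per_bin=1, sd_floor=0.5)
        null = rewire(anchored, anchors, cfg)
        obs = count_pairs(anchored)
        z_obs, z_rew = local_z(obs, null, anchors, cfg)
        edges = null.edges

        null_counts = {}
        for _, r in null.pair_counts.iterrows():
            null_counts[(r["anchor1"], r["anchor2"])] = r["n_pets"]
        n = len(ids)
        per_bin_counts = {b: [] for b in range(len(edges) - 1)}
        for x in range(n):
            for y in range(x + 1, n):
                d = abs(int(mids[y]) - int(mids[x]))
                if not edges[0] <= d < edges[-1]:
                    continue  # outside the binning range: in no bin's universe
                b = int(bin_of(np.array([d]), edges)[0])
                per_bin_counts[b].append(null_counts.get((ids[x], ids[y]), 0))

        for _, r in z_obs.iterrows():
            b = int(bin_of(np.array([r["distance"]]), edges)[0])
            vals = np.array(per_bin_counts[b], dtype=float)
            mu, sd = vals.mean(), vals.std()
            expect = (r["n_pets"] - mu) / max(sd, cfg.sd_floor)
            assert r["z"] == pytest.approx(expect, abs=1e-9)

    def test_sparse_bin_pools_neighbours(self):
        anchors, anchored, _, _ = self._tiny()
        cfg = CallerConfig(seed=4, min_pairs_per_bin=10 ** 6)  # force full pooling
        null = rewire(anchored, anchors, cfg)
        z_obs, _ = local_z(count_pairs(anchored), null, anchors, cfg)
        assert np.isfinite(z_obs["z"]).all()


class TestCallAtFdr:
    def test_all_null_below_zero_calls_everything(self):
        z_obs = pd.DataFrame({"z": [5.0] * 10})
        z_rew = pd.DataFrame({"z": [-1.0, 0.0, -2.0]})
        thr, calls = call_at_fdr(z_obs, z_rew, CallerConfig(fdr=0.1))
        assert thr <= 5.0 and calls["passed"].all()

    def test_pure_null_degenerate_zero_calls(self):
        z = pd.DataFrame({"z": np.linspace(-2, 6, 50)})
        thr, calls = call_at_fdr(z, z.copy(), CallerConfig(fdr=0.1, n_rewires=1))
        assert not calls["passed"].any() and thr == float("inf")

    def test_threshold_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        z_obs = pd.DataFrame({"z": np.round(rng.normal(1, 2, 400), 2)})
        z_rew = pd.DataFrame({"z": np.round(rng.normal(0, 2, 400), 2)})
        cfg = CallerConfig(fdr=0.2)
        thr, calls = call_at_fdr(z_obs, z_rew, cfg)

        best = None
        for t in sorted(z_obs["z"].unique()):
            n_o = int((z_obs["z"] >= t).sum())
            n_r = int((z_rew["z"] >= t).sum())
            if n_o and n_r / n_o <= cfg.fdr:
                best = t
                break
        assert thr == pytest.approx(best)
        assert calls["passed"].sum() == int((z_obs["z"] >= best).sum())

    def test_ties_at_threshold_are_called(self):
        z_obs = pd.DataFrame({"z": [3.0, 3.0, 3.0, 1.0]})
        z_rew = pd.DataFrame({"z": [2.0, 2.0, 2.0, 2.0]})
        thr, calls = call_at_fdr(z_obs, z_rew, CallerConfig(fdr=0.1))
        assert thr == pytest.approx(3.0)
        assert calls["passed"].sum() == 3

    def test_raising_fdr_never_loses_calls(self, small_call):
        z_obs = small_call["calls"][["z"]]
        z_rew = small_call["rewired_z"][["z"]]
        n_prev = -1
        for fdr in (0.01, 0.05, 0.1, 0.2, 0.5):
            _, calls = call_at_fdr(z_obs, z_rew, CallerConfig(fdr=fdr))
            n = int(calls["passed"].sum())
            assert n >= n_prev
            n_prev = n


class TestEndToEndFdr:
    def test_empirical_ratio_at_threshold_within_target(self, small_call):
        assert small_call["empirical_fdr"] <= 0.10

    def test_power_on_planted_loops(self, small_call, small_truth):
        calls = small_call["calls"]
        called = set(zip(calls.loc[calls["passed"], "anchor1"],
                         calls.loc[calls["passed"], "anchor2"]))
        tset = set(zip(small_truth["anchor1"], small_truth["anchor2"]))
        assert len(called & tset) / len(tset) >= 0.9


class TestMergeDatasets:
    def _call(self, chrom, s1, e1, s2, e2, n=3, z=5.0):
        return pd.DataFrame([{
            "chrom": chrom, "start1": s1, "end1": e1, "start2": s2, "end2": e2,
            "n_pets": n, "z": z, "passed": True,
            "anchor1": "x", "anchor2": "y",
        }])

    def test_identical_calls_merge_not_specific(self):
        c = self._call("chr1", 100, 200, 5000, 5100)
        merged = merge_datasets({"F1": c, "F2": c.copy()})
        assert len(merged) == 1
        assert merged["n_factors"].iloc[0] == 2
        assert not merged["specific"].iloc[0]

    def test_disjoint_anchors_never_merge(self):
        a = self._call("chr1", 100, 200, 5000, 5100)
        b = self._call("chr1", 300, 400, 9000, 9100)
        merged = merge_datasets({"F1": a, "F2": b})
        assert len(merged) == 2 and merged["specific"].all()

    def test_matches_quadratic_component_oracle(self):
        rng = np.random.default_rng(12)
        factors = {}
        flat = []
        for f in ("F1", "F2", "F3"):
            rows = []
            for _ in range(30):
                s1 = int(rng.integers(0, 50_000))
                s2 = s1 + int(rng.integers(20_000, 80_000))
                row = {"chrom": "chr1", "start1": s1, "end1": s1 + 2000,
                       "start2": s2, "end2": s2 + 2000, "n_pets": 1, "z": 1.0,
                       "passed": True, "anchor1": "a", "anchor2": "b"}
                rows.append(row)
                flat.append(row)
            factors[f] = pd.DataFrame(rows)
        merged = merge_datasets(factors)

        # oracle: quadratic all-vs-all reciprocal-overlap graph components
        n = len(flat)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                a, b = flat[i], flat[j]
                if (min(a["end1"], b["end1"]) > max(a["start1"], b["start1"])
                        and min(a["end2"], b["end2"]) > max(a["start2"], b["start2"])):
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(n)})
        assert len(merged) == n_components
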