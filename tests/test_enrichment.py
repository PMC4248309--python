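"""TF/HOT enrichment and the co-binding SOM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from loopscape.enrichment import (tf_enrichment, hot_enrichment,
                                  categorize_enrichment,
                                  distal_proximal_target_counts)
from loopscape.som import som_fit, som_interaction_enrichment
from statsmodels.stats.multitest import multipletests


def loci(positions, chrom="chr1", width=1000):
    return pd.DataFrame({"chrom": chrom, "start": list(positions),
                         "end": [p + width for p in positions]})


class TestTfEnrichment:
    def test_bound_everywhere_is_none(self):
        all_l = loci(range(0, 100_000, 2000))
        inter = all_l.iloc[:10].reset_index(drop=True)
        peaks = {"TF1": all_l.copy()}
        rec = tf_enrichment(inter, all_l, peaks, seed=1).iloc[0]
        assert rec["log2_obs_exp"] == pytest.approx(0.0)
        assert rec["category"] == "none"

    def test_planted_enrichment_is_high(self):
        rng = np.random.default_rng(8)
        pos = np.arange(0, 400_000, 2000)
        all_l = loci(pos)
        inter = all_l.iloc[:40].reset_index(drop=True)
        # bound at 90% of interacting loci, 10% of the rest
        bound = list(pos[:40][rng.random(40) < 0.9]) + \
            list(pos[40:][rng.random(len(pos) - 40) < 0.1])
        peaks = {"X": loci(sorted(bound))}
        rec = tf_enrichment(inter, all_l, peaks, seed=2).iloc[0]
        assert rec["category"] == "high"
        assert rec["p"] < 0.01

    def test_empty_peakset_gives_none_p1(self):
        all_l = loci(range(0, 20_000, 2000))
        rec = tf_enrichment(all_l.iloc[:3], all_l, {"E": loci([])}, seed=0).iloc[0]
        assert rec["category"] == "none" and rec["p_bonferroni"] == 1.0

    def test_fisher_matches_hypergeometric(self):
        """Fisher p equals the exact hypergeometric tail on random fixtures."""
        rng = np.random.default_rng(3)
        for trial in range(10):
            pos = np.arange(0, 100_000, 2000)
            all_l = loci(pos)
            n_int = int(rng.integers(5, 20))
            inter = all_l.iloc[:n_int].reset_index(drop=True)
            bound = pos[rng.random(len(pos)) < rng.uniform(0.2, 0.8)]
            peaks = {"T": loci(sorted(bound))}
            rec = tf_enrichment(inter, all_l, peaks, seed=trial).iloc[0]
            # reconstruct the same 2x2 the function used
            from loopscape.config import substream
            from loopscape.intervals import any_overlap_df
            r2 = substream(trial, "tf_enrichment")
            draw = all_l.iloc[r2.choice(len(all_l), size=n_int, replace=False)]
            a = int(any_overlap_df(inter, peaks["T"]).sum())
            c = int(any_overlap_df(draw.reset_index(drop=True), peaks["T"]).sum())
            table = [[a, n_int - a], [c, n_int - c]]
            assert rec["p"] == pytest.approx(stats.fisher_exact(table)[1], abs=1e-12)

    @given(p=st.floats(0, 1), ratio=st.floats(-2, 2), pres=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_category_is_pure_function(self, p, ratio, pres):
        cat = categorize_enrichment(p, ratio, pres)
        if p > 0.01:
            assert cat == "none"
        elif ratio > 0.35 and pres >= 0.35:
            assert cat == "high"
        else:
            assert cat == "weak"


class TestHotEnrichment:
    def calls(self, pairs, positions):
        return pd.DataFrame([{
            "chrom": "chr1",
            "start1": positions[i], "end1": positions[i] + 1000,
            "start2": positions[j], "end2": positions[j] + 1000}
            for i, j in pairs])

    def test_zero_hot_degenerate(self):
        all_l = loci(range(0, 20_000, 2000))
        res = hot_enrichment(self.calls([(0, 5)], list(range(0, 20_000, 2000))),
                             all_l.iloc[:2], all_l, loci([]), n_rewires=10)
        assert res["locus_p"] == 1.0 and res["pair_p"] == 1.0

    def test_hot_everywhere_saturates(self):
        pos = list(range(0, 40_000, 2000))
        all_l = loci(pos)
        calls = self.calls([(0, 10), (2, 12), (4, 14)], pos)
        res = hot_enrichment(calls, all_l.iloc[:6], all_l, all_l.copy(),
                             n_rewires=50, seed=1)
        assert res["observed_hot_hot"] == len(calls)
        assert res["expected_hot_hot"] == pytest.approx(len(calls))
        assert res["pair_p"] == 1.0

    def test_rewired_mean_matches_pairing_expectation(self):
        """Mean HOT-HOT count under end re-pairing equals n * h1 * h2-style
        closed form: sum over pairings of P(end1 HOT) x P(end2 HOT)."""
        rng = np.random.default_rng(4)
        pos = list(range(0, 200_000, 2000))
        hot = loci([p for p in pos if rng.random() < 0.3])
        pairs = [(i, i + 30) for i in range(0, 40, 2)]
        calls = self.calls(pairs, pos)
        res = hot_enrichment(calls, loci(pos[:5]), loci(pos), hot,
                             n_rewires=4000, seed=9)
        from loopscape.intervals import any_overlap_df
        e1 = calls[["chrom", "start1", "end1"]].rename(
            columns={"start1": "start", "end1": "end"})
        e2 = calls[["chrom", "start2", "end2"]].rename(
            columns={"start2": "start", "end2": "end"})
        h1 = any_overlap_df(e1, hot).mean()
        h2 = any_overlap_df(e2, hot).mean()
        expected = len(calls) * h1 * h2
        sd = np.std(res["rewired_distribution"], ddof=1)
        assert abs(res["expected_hot_hot"] - expected) < 3 * sd / np.sqrt(4000) + 0.05


class TestSom:
    def test_identical_rows_single_neuron_zero_distance(self):
        mat = pd.DataFrame(np.tile([1, 0, 1, 0], (30, 1)),
                           columns=["a", "b", "c", "d"])
        model = som_fit(mat, grid_dims=(2, 2), n_restarts=2, seed=1)
        assert model.mean_distance == pytest.approx(0.0)
        assert len(set(model.assignment)) == 1

    def test_orthogonal_blocks_separate_on_two_neurons(self):
        block1 = np.tile([1, 1, 0, 0], (20, 1))
        block2 = np.tile([0, 0, 1, 1], (20, 1))
        mat = pd.DataFrame(np.vstack([block1, block2]), columns=list("wxyz"))
        model = som_fit(mat, grid_dims=(2, 1), n_restarts=5, seed=2)
        a = set(model.assignment[:20])
        b = set(model.assignment[20:])
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_returned_model_is_best_restart(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame((rng.random((60, 6)) < 0.4).astype(int))
        mat.columns = [f"tf{i}" for i in range(6)]
        model = som_fit(mat, grid_dims=(3, 3), n_restarts=6, seed=3)
        assert model.mean_distance == pytest.approx(min(model.restart_metrics))
        assert len(model.restart_metrics) == 6

    def test_grid_too_large_errors(self):
        mat = pd.DataFrame(np.zeros((4, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="smaller grid"):
            som_fit(mat, grid_dims=(3, 3))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame((rng.random((40, 5)) < 0.5).astype(int))
        mat.columns = [f"tf{i}" for i in range(5)]
        m1 = som_fit(mat, grid_dims=(2, 2), n_restarts=3, seed=9)
        m2 = som_fit(mat, grid_dims=(2, 2), n_restarts=3, seed=9)
        assert np.array_equal(m1.assignment, m2.assignment)
        assert np.allclose(m1.codebook, m2.codebook)


class TestSomInteractionEnrichment:
    def _model(self, assignment, n_neurons=4):
        from loopscape.som import SOMModel
        return SOMModel(grid_dims=(n_neurons, 1),
                        codebook=np.zeros((n_neurons, 2)),
                        assignment=np.asarray(assignment),
                        mean_distance=0.0, seed=0)

    def test_uniform_flags_nothing_enriched(self):
        rng = np.random.default_rng(2)
        assignment = rng.integers(0, 4, size=200)
        flags = rng.random(200) < 0.3
        res = som_interaction_enrichment(self._model(assignment), flags)
        assert not res["enriched"].any()

    def test_concentrated_flags_enrich_one_neuron(self):
        assignment = np.repeat([0, 1, 2, 3], 50)
        flags = np.zeros(200, dtype=bool)
        flags[:20] = True  # all interacting sites in neuron 0 (10% global)
        res = som_interaction_enrichment(self._model(assignment), flags)
        assert res.loc[res["neuron"] == 0, "enriched"].iloc[0]
        assert res.loc[res["neuron"] == 0, "fold"].iloc[0] == pytest.approx(4.0)
        assert not res.loc[res["neuron"] != 0, "enriched"].any()

    def test_q_values_match_bh_oracle(self):
        rng = np.random.default_rng(7)
        assignment = rng.integers(0, 6, size=300)
        flags = rng.random(300) < 0.25
        model = self._model(assignment, n_neurons=6)
        res = som_interaction_enrichment(model, flags)
        expect = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
        assert np.allclose(res["q"].to_numpy(), expect)


class TestDistalProximalCounts:
    def test_unbound_tf_is_zero_zero(self):
        genes = pd.DataFrame({"gene": ["G1"], "chrom": ["chr1"],
                              "tss": [50_000], "strand": ["+"]})
        calls = pd.DataFrame(columns=["chrom", "start1", "end1", "start2", "end2"])
        res = distal_proximal_target_counts({"TF": loci([])}, genes, calls)
        assert res.iloc[0]["n_proximal_targets"] == 0
        assert res.iloc[0]["n_distal_targets"] == 0

    def test_promoter_only_binding_no_interactions(self):
        genes = pd.DataFrame({"gene": ["G1"], "chrom": ["chr1"],
                              "tss": [50_000], "strand": ["+"]})
        calls = pd.DataFrame(columns=["chrom", "start1", "end1", "start2", "end2"])
        res = distal_proximal_target_counts({"TF": loci([49_000])}, genes, calls)
        assert res.iloc[0]["n_proximal_targets"] == 1
        assert res.iloc[0]["n_distal_targets"] == 0

    def test_consistent_with_network_builders(self, small_tracks, small_call):
        from loopscape.networks import build_proximal, build_distal
        calls = small_call["calls"]
        passed = calls.loc[calls["passed"]].reset_index(drop=True)
        genes = small_tracks["genes"]
        peaks = small_tracks["tf_peaks"]
        res = distal_proximal_target_counts(peaks, genes, passed).set_index("tf")
        prox = build_proximal(peaks, genes)
        dist = build_distal(peaks, passed, genes)
        for tf in peaks:
            assert res.loc[tf, "n_proximal_targets"] == prox.out_degree(tf)
            assert res.loc[tf, "n_distal_targets"] == dist.out_degree(tf)
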