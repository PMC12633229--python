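"""Mean-rank enrichment, permutation NES, leading edges, uniqueness rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import anchoromics as am
from anchoromics.gsea import RankedList, _ranked_from_r, is_unique


def make_ranked(r_values, names=None):
    names = names or [f"g{i}" for i in range(len(r_values))]
    return _ranked_from_r(names, np.asarray(r_values, dtype=float))


class TestRanking:
    def test_ascending_order_simple(self):
        ranked = make_ranked([-0.5, 0.0, 0.5], ["a", "b", "c"])
        assert ranked.feature_ids == ["a", "b", "c"]
        np.testing.assert_allclose(ranked.ranks, [1, 2, 3])

    def test_tie_averaging(self):
        ranked = make_ranked([0.1, 0.9, 0.9], ["a", "b", "c"])
        pos = ranked.rank_of()
        assert pos["a"] == 1
        assert pos["b"] == pos["c"] == 2.5

    def test_rank_sum_invariant(self, rng):
        r = np.round(rng.normal(size=200), 2)  # rounding forces ties
        ranked = make_ranked(r)
        assert ranked.ranks.sum() == pytest.approx(200 * 201 / 2)

    def test_rank_by_anchor_excludes_unscored(self, small_dataset):
        d = small_dataset
        prof = am.anchor_profile(d.rna, d.rna.feature("NPTX2"))
        ranked = am.rank_by_anchor(prof)
        assert ranked.N == len(prof.scored())
        assert ranked.ranks.sum() == pytest.approx(ranked.N * (ranked.N + 1) / 2)


class TestEnrichmentScore:
    def test_full_universe_zero(self):
        ranked = make_ranked([0.1, 0.2, 0.3, 0.4])
        assert am.enrichment_score(ranked, ranked.feature_ids) == pytest.approx(0.0)

    def test_arithmetic_example(self):
        ranked = make_ranked([0.1, 0.2, 0.3, 0.4, 0.5])
        members = [ranked.feature_ids[3], ranked.feature_ids[4]]  # ranks 4, 5
        assert am.enrichment_score(ranked, members) == pytest.approx(1.5)

    def test_complement_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            ranked = make_ranked(rng.normal(size=n))
            k = int(rng.integers(1, n))
            members = list(rng.choice(ranked.feature_ids, size=k, replace=False))
            comp = [g for g in ranked.feature_ids if g not in members]
            es = am.enrichment_score(ranked, members)
            es_c = am.enrichment_score(ranked, comp)
            assert es_c == pytest.approx(-(len(members) / len(comp)) * es, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        r = rng.uniform(-0.9, 0.9, size=40)
        members = [f"g{i}" for i in rng.choice(40, size=8, replace=False)]
        es1 = am.enrichment_score(make_ranked(r), members)
        es2 = am.enrichment_score(make_ranked(np.tanh(3 * r)), members)
        assert es1 == pytest.approx(es2)

    def test_no_members_skipped(self):
        ranked = make_ranked([0.1, 0.2, 0.3])
        assert am.enrichment_score(ranked, ["absent"]) is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=40), st.integers(min_value=0))
    def test_es_bounds(self, n, seed):
        rng = np.random.default_rng(seed % 2**31)
        ranked = make_ranked(rng.normal(size=n))
        members = list(
            rng.choice(ranked.feature_ids, size=int(rng.integers(1, n + 1)),
                       replace=False))
        es = am.enrichment_score(ranked, members)
        assert abs(es) <= (n - 1) / 2 + 1e-12


class TestLeadingEdges:
    def test_truncation_small_set(self):
        ranked = make_ranked([0.9, 0.5, -0.7], ["hi", "mid", "lo"])
        pos5, neg5 = am.leading_edges(ranked, ["hi", "mid", "lo"])
        assert pos5 == ["hi", "mid"]
        assert neg5 == ["lo"]

    def test_ordering_by_magnitude(self):
        r = [0.2, 0.8, 0.5, -0.1, -0.9, -0.4, 0.05, -0.02]
        names = list("abcdefgh")
        ranked = make_ranked(r, names)
        pos5, neg5 = am.leading_edges(ranked, names)
        assert pos5 == ["b", "c", "a", "g"]
        assert neg5 == ["e", "f", "d", "h"]

    def test_planted_module_leading_edge_recovery(self):
        hits = 0
        for seed in range(10):
            cfg = am.SimConfig(seed=seed)
            cfg.n_genes = 500
            cfg.n_per_group = {"Control": 80, "MCI": 0, "AD": 80, "Other": 0}
            d = am.simulate_dataset(cfg)
            prof = am.anchor_profile(d.rna, d.rna.feature("NPTX2"))
            ranked = am.rank_by_anchor(prof)
            module = [g for g in d.rna.feature_ids if g.startswith("PLASTICITY")]
            pos5, _ = am.leading_edges(ranked, module)
            if set(pos5) <= set(module) and len(pos5) == 5:
                hits += 1
        assert hits >= 8


class TestRunningSum:
    def test_set_at_extreme_peaks_at_end(self):
        ranked = make_ranked([0.1, 0.2, 0.3, 0.4, 0.99])
        curve = am.running_sum_curve(ranked, [ranked.feature_ids[-1]])
        assert np.argmax(curve) == len(curve) - 1
        assert curve[:-1].max() < curve[-1]

    def test_returns_to_zero(self, rng):
        ranked = make_ranked(rng.normal(size=50))
        members = list(rng.choice(ranked.feature_ids, size=12, replace=False))
        curve = am.running_sum_curve(ranked, members)
        assert curve[-1] == pytest.approx(0.0, abs=1e-12)

    def test_peak_matches_brute_force(self, rng):
        ranked = make_ranked(rng.normal(size=30))
        members = set(rng.choice(ranked.feature_ids, size=7, replace=False))
        n_hit, n_miss = 7, 23
        acc, best, best_i = 0.0, -np.inf, None
        for i, g in enumerate(ranked.feature_ids):
            acc += 1 / n_hit if g in members else -1 / n_miss
            if acc > best:
                best, best_i = acc, i
        curve = am.running_sum_curve(ranked, members)
        assert np.argmax(curve) == best_i
        assert curve.max() == pytest.approx(best)


def _null_dataset(seed=42, n_genes=600, n_samples=100):
    cfg = am.SimConfig(seed=seed)
    cfg.n_genes = n_genes
    cfg.module_specs = []
    cfg.n_per_group = {"Control": n_samples // 2, "MCI": 0,
                       "AD": n_samples - n_samples // 2, "Other": 0}
    cfg.anchor_group_shift = {"Control": 0.0, "AD": 0.0}
    return am.simulate_dataset(cfg)


class TestPermutationNes:
    def test_seed_determinism_bitwise(self, rng):
        d = _null_dataset()
        sets = am.emit_true_gene_sets(d.truth, n_random_sets=5, set_size=30, seed=1)
        a = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets,
                               n_perm=100, seed=9)
        b = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets,
                               n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets,
                               n_perm=100, seed=10)
        assert not np.allclose(a.table["NES"], c.table["NES"])

    def test_null_moment_stability_doubling_perms(self):
        cfg = am.SimConfig(seed=2)
        cfg.n_genes = 600
        cfg.n_per_group = {"Control": 60, "MCI": 0, "AD": 60, "Other": 0}
        d = am.simulate_dataset(cfg)
        sets = am.emit_true_gene_sets(d.truth, n_random_sets=3, set_size=30, seed=2)
        a = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets,
                               n_perm=500, seed=4)
        b = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets,
                               n_perm=1000, seed=4)
        nes_a = a.table.loc["module:plasticity", "NES"]
        nes_b = b.table.loc["module:plasticity", "NES"]
        assert abs(nes_a - nes_b) < 0.2 * max(abs(nes_a), 1.0)

    def test_planted_module_top_nes(self):
        cfg = am.SimConfig(seed=8)
        cfg.n_genes = 800
        cfg.n_per_group = {"Control": 60, "MCI": 0, "AD": 60, "Other": 0}
        d = am.simulate_dataset(cfg)
        sets = am.emit_true_gene_sets(d.truth, n_random_sets=20, set_size=40, seed=8)
        rep = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets,
                                 n_perm=200, seed=8)
        t = rep.table
        assert t["NES"].idxmax() == "module:plasticity"
        assert t.loc["module:plasticity", "fdr"] < 0.05
        assert t.loc["module:stress_lysosomal", "NES"] < 0  # negative coupling

    def test_zero_sd_set_flagged(self):
        # a set equal to the whole universe has ES identically 0 in every perm
        d = _null_dataset(seed=3, n_genes=50, n_samples=40)
        universe_set = am.GeneSetCollection(
            sets={"all": list(d.rna.feature_ids)}, descriptions={"all": ""})
        rep = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), universe_set,
                                 n_perm=100, seed=0)
        row = rep.table.loc["all"]
        assert row["flagged"]
        assert np.isnan(row["NES"])
        assert row["ES"] == pytest.approx(0.0)

    def test_min_perm_enforced(self, small_dataset):
        d = small_dataset
        sets = am.emit_true_gene_sets(d.truth, 1, 10, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets, n_perm=10)


class TestUniqueness:
    def test_rule_arithmetic(self):
        assert is_unique(12.0, [5.0, 8.0])
        assert not is_unique(9.0, [5.0, 8.0])
        assert is_unique(-12.0, [5.0, 8.0])  # magnitude rule

    def test_background_from_module_blocks_uniqueness(self):
        # if background anchors are themselves planted-module genes, the
        # planted set cannot be unique to the main anchor
        cfg = am.SimConfig(seed=6)
        cfg.n_genes = 400
        cfg.n_per_group = {"Control": 60, "MCI": 0, "AD": 60, "Other": 0}
        d = am.simulate_dataset(cfg)
        sets = am.emit_true_gene_sets(d.truth, n_random_sets=5, set_size=30, seed=6)
        rep = am.permutation_nes(d.rna, d.rna.feature("NPTX2"), sets,
                                 n_perm=150, seed=6)
        module = [g for g in d.rna.feature_ids if g.startswith("PLASTICITY")][:3]
        rep2 = am.background_uniqueness(
            rep, {g: "plasticity" for g in module}, d.rna, sets, n_perm=150)
        assert not rep2.table.loc["module:plasticity", "unique"]
        # but against unrelated background genes it is unique
        bg = [g for g in d.rna.feature_ids if g.startswith("BG_")][:3]
        rep3 = am.background_uniqueness(
            rep, {g: "random" for g in bg}, d.rna, sets, n_perm=150)
        assert rep3.table.loc["module:plasticity", "unique"]
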