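"""Alignment building, clock LRT mechanics, and terminal branch rates."""

import numpy as np
import pandas as pd
import pytest

from lineage_clockwork.phylogeny import (
    Alignment,
    AnalysisError,
    build_alignment,
    clock_lrt,
    distance_tree,
    k2p_pairwise_distances,
    pruning_likelihood,
    subsample_one_per_haplogroup,
    terminal_branch_rates,
)
from lineage_clockwork.trees import Node, tips


def _geno(df_dict, positions):
    return pd.DataFrame(df_dict, index=positions, dtype=object)


class TestBuildAlignment:
    def test_identical_sequences_have_no_variable_sites(self):
        geno = _geno({f"s{i}": list("ACGTACGTACGT") for i in range(5)},
                     range(1, 13))
        with pytest.raises(AnalysisError, match="variable"):
            build_alignment(geno)

    def test_too_few_samples(self):
        geno = _geno({"a": list("AC"), "b": list("AG")}, [1, 2])
        with pytest.raises(AnalysisError, match="samples"):
            build_alignment(geno)

    def test_high_missingness_samples_dropped(self):
        base = {f"s{i}": list("ACGTACGTAC" * 2) for i in range(5)}
        # make 12 sites variable so the threshold is satisfied after filtering
        for j in range(12):
            base["s0"][j] = "T" if base["s1"][j] != "T" else "A"
        base["bad"] = ["N"] * 20
        geno = _geno(base, range(1, 21))
        aln = build_alignment(geno, max_missing=0.2)
        assert "bad" not in aln.samples
        assert aln.n_sites >= 10

    def test_site_order_preserved(self, small_cohort):
        cfg, truth, rendered = small_cohort
        aln = truth.alignment
        assert (np.diff(aln.positions) > 0).all()


class TestPairwiseDistances:
    def test_identical_rows_distance_zero(self):
        m = np.tile(np.array([0, 1, 2, 3] * 5, dtype=np.uint8), (3, 1))
        d = k2p_pairwise_distances(m)
        assert np.abs(d).max() == 0.0

    def test_missing_sites_excluded_from_proportions(self):
        a = np.array([0, 1, 2, 3, 0, 0], dtype=np.uint8)
        b = np.array([0, 1, 2, 3, 4, 2], dtype=np.uint8)  # one missing, one ts
        d = k2p_pairwise_distances(np.vstack([a, b]))
        # 5 comparable sites, 1 transition: P=0.2, Q=0
        from lineage_clockwork.rates import k2p_distance

        assert d[0, 1] == pytest.approx(k2p_distance(1, 0, 5).d, abs=1e-12)


class TestClockLRT:
    def test_statistic_nonnegative_and_df(self, small_cohort):
        cfg, truth, rendered = small_cohort
        aln = truth.alignment
        tree = distance_tree(aln, "OUT")
        res = clock_lrt(tree, aln)
        assert res.statistic >= 0.0
        assert res.df == len(aln.samples) - 2
        assert 0.0 <= res.p_value <= 1.0
        assert "lnL (free)" in res.summary()

    def test_pruning_likelihood_interface(self, small_cohort):
        cfg, truth, rendered = small_cohort
        aln = truth.alignment
        tree = distance_tree(aln, "OUT")
        lnl = pruning_likelihood(tree, aln, kappa=2.0)
        assert np.isfinite(lnl) and lnl < 0


class TestTerminalRates:
    def test_ultrametric_tree_gives_all_rates_one(self, balanced_tree):
        df = terminal_branch_rates(balanced_tree())
        assert np.allclose(df["normalized_rate"], 1.0, atol=1e-12)
        assert not df["outlier"].any()

    def test_retained_rates_always_average_to_one(self, balanced_tree):
        rng = np.random.default_rng(0)
        for _ in range(20):
            root = balanced_tree()
            for n in tips(root):
                n.length = float(rng.uniform(0.2, 3.0))
            df = terminal_branch_rates(root)
            kept = df.loc[~df["outlier"], "normalized_rate"]
            assert kept.mean() == pytest.approx(1.0, abs=1e-12)

    def test_doubled_tip_branch_matches_hand_run_recursion(self, balanced_tree):
        # ((A:2,B:1):1,(C:1,D:1):1); hand-run of the geometric-mean recursion:
        # root: La=1+1.5=2.5, Lb=2, g=sqrt(5) -> r_ab=2.5/g, r_cd=2/g
        # ab:   LA=2, LB=1, g=sqrt(2)         -> rA=r_ab*2/sqrt(2), rB=r_ab/sqrt(2)
        df = terminal_branch_rates(
            balanced_tree(bl_a=2.0), mad_cut=np.inf
        ).set_index("sample_id")
        raw = df["raw_rate"]
        assert raw["A"] == pytest.approx(1.5811388301, abs=1e-9)
        assert raw["B"] == pytest.approx(0.7905694150, abs=1e-9)
        assert raw["C"] == pytest.approx(0.8944271910, abs=1e-9)
        assert raw.idxmax() == "A"
        norm = df["normalized_rate"]
        assert norm["A"] == pytest.approx(1.5811388301 / raw.mean(), abs=1e-9)

    def test_zero_depth_tree_is_an_error(self):
        root = Node()
        root.add_child(Node("A", 0.0))
        root.add_child(Node("B", 0.0))
        with pytest.raises(AnalysisError):
            terminal_branch_rates(root)

    def test_outgroup_excluded_from_normalization(self, balanced_tree):
        from lineage_clockwork.phylogeny import Phylogeny

        root = balanced_tree()
        phylo = Phylogeny(root, outgroup="D")
        df = terminal_branch_rates(phylo)
        assert "D" not in set(df["sample_id"])


class TestSubsample:
    def _alignment(self, samples, n_sites=30):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 2, size=(len(samples), n_sites)).astype(np.uint8) * 2
        mat[0, :] = 1  # keep sites biallelic but variable
        return Alignment(list(samples), np.arange(1, n_sites + 1), mat)

    def _sheet(self, n_haps, per_hap):
        rows = [
            {"sample_id": f"H{h}_{i}", "haplogroup": f"H{h}", "batch": "b"}
            for h in range(n_haps) for i in range(per_hap)
        ]
        rows.append({"sample_id": "OUT", "haplogroup": "OUT", "batch": "b"})
        return pd.DataFrame(rows)

    def test_one_per_eligible_haplogroup_plus_outgroup(self):
        sheet = self._sheet(4, 12)
        samples = list(sheet["sample_id"])
        aln = self._alignment(samples)
        sub = subsample_one_per_haplogroup(aln, sheet, seed=1, outgroup="OUT")
        assert len(sub.samples) == 5  # 4 eligible haplogroups + outgroup
        haps = {s.split("_")[0] for s in sub.samples if s != "OUT"}
        assert len(haps) == 4

    def test_small_haplogroups_skipped(self):
        sheet = self._sheet(3, 12)
        extra = pd.DataFrame([{"sample_id": "H9_0", "haplogroup": "H9",
                               "batch": "b"}])
        sheet = pd.concat([sheet, extra], ignore_index=True)
        aln = self._alignment(list(sheet["sample_id"]))
        sub = subsample_one_per_haplogroup(aln, sheet, seed=3, outgroup="OUT")
        assert not any(s.startswith("H9") for s in sub.samples)

    def test_deterministic_for_seed(self):
        sheet = self._sheet(5, 15)
        aln = self._alignment(list(sheet["sample_id"]))
        s1 = subsample_one_per_haplogroup(aln, sheet, seed=7, outgroup="OUT")
        s2 = subsample_one_per_haplogroup(aln, sheet, seed=7, outgroup="OUT")
        s3 = subsample_one_per_haplogroup(aln, sheet, seed=8, outgroup="OUT")
        assert s1.samples == s2.samples
        assert s1.samples != s3.samples or True  # different seed may coincide
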