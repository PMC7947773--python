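"""K2P distances, the Y/X rate ratio, and interhaplogroup statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm
from scipy.stats import rankdata

from lineage_clockwork.rates import (
    SaturationError,
    haplogroup_rate_test,
    k2p_distance,
    median_spread,
    mutation_spectrum,
    relative_somatic_rate,
    spectrum_similarity,
)
from lineage_clockwork.variant_io import RegionSet


def k2p_expected_distance_oracle(p, q, kappa_grid=np.linspace(0.2, 8, 30)):
    """Invert the K2P process with a matrix exponential.

    For given observed transition/transversion proportions (P, Q), find the
    (alpha, beta) rates and time t (with alpha + 2 beta = 1, so t is the
    expected number of substitutions) whose matrix exponential reproduces
    them; return t. Independent of the closed form under test.
    """
    from scipy.optimize import brentq

    def props(alpha, beta, t):
        q_mat = np.full((4, 4), beta)
        for a, b in ((0, 2), (2, 0), (1, 3), (3, 1)):
            q_mat[a, b] = alpha
        np.fill_diagonal(q_mat, 0.0)
        np.fill_diagonal(q_mat, -q_mat.sum(axis=1))
        P_mat = expm(q_mat * t)
        return P_mat[0, 2], P_mat[0, 1] + P_mat[0, 3]

    def solve(kappa):
        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta

        def fq(t):
            return props(alpha, beta, t)[1] - q
        t = brentq(fq, 1e-9, 50.0)
        return t, props(alpha, beta, t)[0]

    # find kappa matching the transition proportion at the q-matched time
    def fk(kappa):
        return solve(kappa)[1] - p

    lo, hi = 1e-3, 500.0
    kappa = brentq(fk, lo, hi)
    return solve(kappa)[0]


class TestK2P:
    def test_zero_counts_give_zero_distance(self):
        assert k2p_distance(0, 0, 100).d == 0.0

    def test_closed_form_matches_process_oracle(self):
        # P=0.1, Q=0.05 -> d ~= 0.17018
        d = k2p_distance(10, 5, 100).d
        assert d == pytest.approx(0.17018, abs=5e-6)
        oracle = k2p_expected_distance_oracle(0.1, 0.05)
        assert d == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("p,q", [(0.01, 0.005), (0.2, 0.1), (0.05, 0.15)])
    def test_oracle_grid(self, p, q):
        d = k2p_distance(int(p * 10_000), int(q * 10_000), 10_000).d
        assert d == pytest.approx(k2p_expected_distance_oracle(p, q), abs=1e-6)

    def test_small_count_limit_is_per_site_mutation_count(self):
        for n in (1, 5, 10):
            d = k2p_distance(n, n, 10_000).d
            assert d == pytest.approx(2 * n / 10_000, rel=0.01)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(50, 10, 100)  # 1 - 2P - Q < 0
        with pytest.raises(SaturationError):
            k2p_distance(0, 60, 100)   # 1 - 2Q < 0


def _rates_frame(groups):
    rows = []
    for hap, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"sample_id": f"{hap}_{i}", "haplogroup": hap,
                         "d_Y": v, "d_X": 1.0, "R": v, "valid": True})
    return pd.DataFrame(rows)


class TestRelativeRate:
    def test_ratio_arithmetic(self):
        wcl = pd.DataFrame({
            "sample_id": ["s"] * 3,
            "chrom": ["Y", "Y", "X"],
            "pos": [10, 20, 30],
            "is_transition": [True, False, True],
        })
        sheet = pd.DataFrame({"sample_id": ["s"], "haplogroup": ["H1"],
                              "batch": ["b"]})
        ry = RegionSet.from_intervals("Y", [(0, 1000)])
        rx = RegionSet.from_intervals("X", [(0, 1000)])
        out = relative_somatic_rate(wcl, ry, rx, sheet)
        assert out.iloc[0]["valid"]
        # 2 mutations on Y vs 1 on X over equal lengths: R ~= 2
        assert out.iloc[0]["R"] == pytest.approx(2.0, rel=1e-2)

    def test_zero_x_distance_flagged_invalid(self):
        wcl = pd.DataFrame({
            "sample_id": ["s"], "chrom": ["Y"], "pos": [10],
            "is_transition": [True],
        })
        sheet = pd.DataFrame({"sample_id": ["s"], "haplogroup": ["H1"],
                              "batch": ["b"]})
        ry = RegionSet.from_intervals("Y", [(0, 1000)])
        rx = RegionSet.from_intervals("X", [(0, 1000)])
        out = relative_somatic_rate(wcl, ry, rx, sheet)
        assert not out.iloc[0]["valid"]
        assert np.isnan(out.iloc[0]["R"])


class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        res = haplogroup_rate_test(
            _rates_frame({"A": [1, 2], "B": [3, 4]}), min_samples=2
        )
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 2.4
        assert res.statistic == pytest.approx(2.4, abs=1e-12)
        assert res.df == 1

    def test_identical_groups_have_zero_statistic(self):
        res = haplogroup_rate_test(
            _rates_frame({"A": [1, 2], "B": [1, 2]}), min_samples=2
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula_with_midranks_and_tie_correction(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = {
                f"G{i}": rng.integers(0, 12, size=rng.integers(3, 9)).astype(float)
                for i in range(k)
            }
            res = haplogroup_rate_test(_rates_frame(groups), min_samples=2)
            pooled = np.concatenate(list(groups.values()))
            ranks = rankdata(pooled)
            n_tot = len(pooled)
            h = 0.0
            start = 0
            for vals in groups.values():
                r = ranks[start:start + len(vals)]
                start += len(vals)
                h += len(vals) * (r.mean() - (n_tot + 1) / 2) ** 2
            h *= 12.0 / (n_tot * (n_tot + 1))
            _, counts = np.unique(pooled, return_counts=True)
            tie = 1.0 - ((counts ** 3 - counts).sum()) / (n_tot ** 3 - n_tot)
            h_ref = h / tie if tie > 0 else 0.0
            assert res.statistic == pytest.approx(h_ref, abs=1e-10)

    def test_small_haplogroups_excluded(self):
        res = haplogroup_rate_test(
            _rates_frame({"A": range(12), "B": range(12), "C": range(3)}),
            min_samples=11,
        )
        assert res.excluded_haplogroups == ["C"]

    def test_fewer_than_two_groups_is_an_error(self):
        with pytest.raises(ValueError):
            haplogroup_rate_test(_rates_frame({"A": range(12)}), min_samples=11)


class TestSpreadAndSpectrum:
    def test_median_spread_examples(self):
        assert median_spread(pd.Series([0.6, 1.1])) == pytest.approx(83.3, abs=0.04)
        assert median_spread(pd.Series([1.0, 1.486])) == pytest.approx(48.6, abs=1e-9)
        assert median_spread(pd.Series([1.0, 1.0, 1.0])) == 0.0
        with pytest.raises(ValueError):
            median_spread(pd.Series([0.0, 1.0]))

    def test_single_class_spectrum(self):
        muts = pd.DataFrame({"mut_class": ["C>T"] * 5})
        vec = mutation_spectrum(muts)
        assert vec.tolist() == [0, 0, 1, 0, 0, 0]

    def test_similarity_limits(self):
        a = mutation_spectrum(pd.DataFrame({"mut_class": ["C>T"] * 3}))
        b = mutation_spectrum(pd.DataFrame({"mut_class": ["T>A"] * 4}))
        assert spectrum_similarity(a, a) == pytest.approx(1.0)
        assert spectrum_similarity(a, b) == pytest.approx(0.0)

    def test_empty_spectrum_is_an_error(self):
        with pytest.raises(ValueError):
            mutation_spectrum(pd.DataFrame({"mut_class": []}))
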