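"""Generator contracts: determinism, placement laws, rendering statistics."""

import numpy as np
import pandas as pd
import pytest

from lineage_clockwork import CohortConfig, render_sequencing, simulate_cohort
from lineage_clockwork.synthetic import ConfigurationError, write_cohort
from lineage_clockwork.trees import is_ultrametric, postorder, tips


def small(seed=0, **kw):
    base = dict(
        n_haplogroups=3, samples_per_haplogroup=4, master_seed=seed,
        l_y=300_000, l_x=300_000, window_size=5_000, n_sites=6_000,
        base_somatic_burden=15.0,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"n_haplogroups": 0},
        {"germline_rate_multiplier": (1.0, 1.0)},       # wrong arity
        {"somatic_multiplier_y": (1.0, -1.0, 1.0)},
        {"timing_amplitude": 1.0},
        {"seq_error_rate": 0.5},
        {"l_y": 1_000},                                  # < window_size
        {"cell_fraction_params": (0.0, 2.0)},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small(**kw)


class TestSimulate:
    def test_zero_burden_means_no_somatic_mutations(self):
        truth = simulate_cohort(small(base_somatic_burden=0.0))
        assert truth.somatic.empty

    def test_identical_seed_reproduces_cohort_and_files(self, tmp_path):
        cfg_a, cfg_b = small(seed=5), small(seed=5)
        ta, tb = simulate_cohort(cfg_a), simulate_cohort(cfg_b)
        assert np.array_equal(ta.alignment.matrix, tb.alignment.matrix)
        assert np.array_equal(ta.latent_timing, tb.latent_timing)
        pd.testing.assert_frame_equal(ta.somatic, tb.somatic)
        assert ta.newick() == tb.newick()
        ra = render_sequencing(ta, cfg_a, outdir=tmp_path / "a")
        rb = render_sequencing(tb, cfg_b, outdir=tmp_path / "b")
        pd.testing.assert_frame_equal(ra.calls, rb.calls)
        for rel in ("vcf/H01_S01.vcf", "depth_Y.tsv", "truth_somatic.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == \
                   (tmp_path / "b" / rel).read_bytes()

    def test_different_seeds_differ(self):
        ta = simulate_cohort(small(seed=1))
        tb = simulate_cohort(small(seed=2))
        assert not np.array_equal(ta.latent_timing, tb.latent_timing)

    def test_tree_is_ultrametric_with_monophyletic_haplogroups(self):
        truth = simulate_cohort(small())
        assert is_ultrametric(truth.tree, rel_tol=1e-6)
        hap = truth.haplogroup
        names = {t.name for t in tips(truth.tree)}
        assert len(names) == 13  # 3x4 + outgroup
        # each haplogroup's samples must form a clade: some node's tip set
        # equals exactly that haplogroup
        tip_sets = [frozenset(t.name for t in tips(n))
                    for n in postorder(truth.tree) if n.children]
        for h in ("H01", "H02", "H03"):
            members = frozenset(hap[hap == h].index)
            assert members in tip_sets

    def test_latent_timing_spans_minus_one_to_one(self):
        truth = simulate_cohort(small())
        lat = truth.latent_timing
        assert lat.min() == pytest.approx(-1.0)
        assert lat.max() == pytest.approx(1.0)
        assert len(lat) == small().n_windows

    def test_target_variable_sites_hits_expectation(self):
        cfg = small(target_variable_sites=500, n_sites=20_000)
        truth = simulate_cohort(cfg)
        assert 350 <= truth.alignment.n_sites <= 650  # Poisson-ish around 500

    def test_somatic_placement_coupled_to_timing_is_anticorrelated(self):
        # aggregate over several replicate cohorts: per-window somatic counts
        # correlate negatively with the latent timing curve
        rs = []
        for seed in range(6):
            cfg = small(seed=seed, samples_per_haplogroup=8,
                        base_somatic_burden=60.0, placement_coupling=0.8)
            truth = simulate_cohort(cfg)
            y = truth.somatic[truth.somatic["chrom"] == "Y"]
            counts, _ = np.histogram(
                y["pos"] - 1, bins=np.arange(0, cfg.l_y + 1, cfg.window_size)
            )
            rs.append(np.corrcoef(counts, truth.latent_timing)[0, 1])
        assert np.mean(rs) < -0.3


class TestRender:
    def test_zero_amplitude_gives_flat_expected_depth(self):
        cfg = small(timing_amplitude=0.0, gc_amplitude=0.0)
        truth = simulate_cohort(cfg)
        rendered = render_sequencing(truth, cfg)
        per_window = rendered.depth.groupby("start")["depth"].mean()
        # all windows share one Poisson mean; sample means stay within CLT bounds
        se = np.sqrt(cfg.mean_depth / rendered.sample_sheet.shape[0])
        assert per_window.std() < 3 * se

    def test_error_free_somatic_free_render_has_no_partial_af_calls(self):
        cfg = small(seq_error_rate=0.0, base_somatic_burden=0.0)
        truth = simulate_cohort(cfg)
        rendered = render_sequencing(truth, cfg)
        af = rendered.calls["alt_reads"] / rendered.calls["depth"]
        assert ((af == 1.0) | (af == 0.0)).all()

    def test_binomial_alt_sampling_at_somatic_sites(self):
        # across many somatic sites with cell fraction near 0.5 and expected
        # depth 30, the mean alt count matches depth * fraction
        cfg = small(samples_per_haplogroup=10, base_somatic_burden=80.0,
                    cell_fraction_params=(20.0, 20.0), seq_error_rate=0.0)
        truth = simulate_cohort(cfg)
        rendered = render_sequencing(truth, cfg)
        merged = rendered.calls.merge(
            truth.somatic, on=["sample_id", "chrom", "pos"], how="inner",
            suffixes=("", "_t"),
        )
        assert len(merged) > 1000
        expected = (merged["depth"] * merged["cell_fraction"]).mean()
        assert merged["alt_reads"].mean() == pytest.approx(expected, rel=0.03)

    def test_rendered_somatic_records_never_exceed_truth(self):
        cfg = small(seq_error_rate=0.0)
        truth = simulate_cohort(cfg)
        rendered = render_sequencing(truth, cfg)
        partial = rendered.calls[
            rendered.calls["alt_reads"] < rendered.calls["depth"]
        ]
        key_r = set(map(tuple, partial[["sample_id", "chrom", "pos"]].values))
        key_t = set(map(tuple, truth.somatic[["sample_id", "chrom", "pos"]].values))
        assert key_r <= key_t  # only loss (zero alt draws), never invention

    def test_truth_files_written(self, small_cohort, tmp_path):
        cfg, truth, rendered = small_cohort
        write_cohort(rendered, truth, tmp_path)
        for name in ("samples.tsv", "callable_Y.bed", "callable_X.bed",
                     "depth_Y.tsv", "windows_Y.tsv", "truth_somatic.tsv",
                     "truth_timing.tsv", "truth_tree.nwk",
                     "truth_multipliers.tsv"):
            assert (tmp_path / name).exists()
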