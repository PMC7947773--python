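"""Per-haplogroup association of somatic rates with branch rates, and the
end-to-end pipeline driver.

The headline question: do haplogroups with faster-evolving terminal branches
also accumulate within-cell-line Y mutations faster? Both quantities are
summarized per haplogroup by their median (over valid samples) and compared
by Spearman rank correlation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .detection import DetectionConfig, detect_wcl
from .phylogeny import (
    build_alignment,
    clock_lrt,
    distance_tree,
    genotypes_from_calls,
    ml_branch_lengths,
    subsample_one_per_haplogroup,
    terminal_branch_rates,
)
from .rates import (
    haplogroup_rate_test,
    median_spread,
    mutation_spectrum,
    relative_somatic_rate,
    spectrum_similarity,
)
from .synthetic import CohortConfig, render_sequencing, simulate_cohort
from .timing import (
    TimingConfig,
    bin_timing_vs_mutations,
    consensus_profile,
    depth_to_profile,
    mutations_per_window,
)
from .trees import newick

__all__ = [
    "haplogroup_summaries",
    "SpearmanResult",
    "spearman",
    "correlate_rate_vs_branch",
    "PipelineResult",
    "run_pipeline",
]


def haplogroup_summaries(
    rates: pd.DataFrame,
    branch_rates: pd.DataFrame,
    min_samples: int = 11,
    exclude: tuple[str, ...] = ("OUT",),
) -> pd.DataFrame:
    """Join per-haplogroup median somatic rate R and median branch rate.

    Haplogroups need more than ten samples (``min_samples=11``) to be
    ``included``; medians are over valid (non-outlier) samples only.
    """
    r = rates[rates["valid"] & ~rates["haplogroup"].isin(exclude)]
    b = branch_rates[~branch_rates["outlier"]
                     & ~branch_rates["haplogroup"].isin(exclude)]
    rows = []
    for hap in sorted(set(r["haplogroup"]) | set(b["haplogroup"])):
        rr = r.loc[r["haplogroup"] == hap, "R"]
        bb = b.loc[b["haplogroup"] == hap, "normalized_rate"]
        n = int(min(len(rr), len(bb)))
        rows.append({
            "haplogroup": hap,
            "n_samples": n,
            "median_R": rr.median() if len(rr) else np.nan,
            "median_branch_rate": bb.median() if len(bb) else np.nan,
            "included": n >= min_samples,
        })
    return pd.DataFrame(rows)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    exact: bool


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with midrank ties.

    The p-value is exact (full permutation enumeration) for n <= 9 and uses
    the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rho, p_t = stats.spearmanr(x, y)
    if n > 9:
        return SpearmanResult(float(rho), float(p_t), n, False)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]                       # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rho_null = (ry_c @ rx_c) / np.where(denom > 0, denom, np.inf)
    p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    return SpearmanResult(float(rho), p, n, True)


def correlate_rate_vs_branch(summaries: pd.DataFrame) -> SpearmanResult:
    """Spearman correlation of per-haplogroup median R vs median branch rate."""
    inc = summaries[summaries["included"]].dropna(
        subset=["median_R", "median_branch_rate"]
    )
    if len(inc) < 5:
        raise ValueError(
            f"need >=5 included haplogroups for the correlation, got {len(inc)}"
        )
    return spearman(inc["median_R"], inc["median_branch_rate"])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    manifest: dict
    wcl: pd.DataFrame
    rates: pd.DataFrame
    rate_test: object
    spread_percent: float
    lrt: object
    branch_rates: pd.DataFrame
    summaries: pd.DataFrame
    correlation: SpearmanResult | None
    profile: object
    wcl_trend: object
    germline_trend: object
    spectrum_cosine: float


def run_pipeline(
    config: CohortConfig,
    outdir=None,
    rendered=None,
    truth=None,
    wcl: pd.DataFrame | None = None,
    detection: DetectionConfig | None = None,
    timing_cfg: TimingConfig | None = None,
    lrt_on_subsample: bool = True,
    min_samples: int = 11,
    n_permutations: int = 0,
    make_plots: bool = False,
    ml_opts: dict | None = None,
) -> PipelineResult:
    """Run the full analysis on a (simulated) cohort.

    Stages: simulate & render -> detect within-cell-line mutations ->
    relative somatic rates + Kruskal-Wallis -> phylogeny (NJ + ML branch
    lengths), clock LRT on a one-per-haplogroup subsample, terminal branch
    rates -> replication timing + mutation-density trends -> haplogroup
    summaries and the rate-vs-branch-rate correlation.

    ``rendered``/``truth``/``wcl`` may be passed to resume from a cached
    stage; the pipeline is a pure function of its inputs.
    """
    detection = detection or DetectionConfig()
    timing_cfg = timing_cfg or TimingConfig()
    if truth is None:
        truth = simulate_cohort(config)
    if rendered is None:
        rendered = render_sequencing(truth, config)
    callable_regions = {"Y": rendered.callable_y, "X": rendered.callable_x}

    if wcl is None:
        wcl, rejects = detect_wcl(rendered.calls, detection, callable_regions)
    else:
        rejects = None

    rates = relative_somatic_rate(
        wcl, rendered.callable_y, rendered.callable_x, rendered.sample_sheet
    )
    rate_test = haplogroup_rate_test(rates, min_samples=min_samples)
    spread = median_spread(rate_test.medians)

    # phylogeny from rendered germline genotypes
    sample_ids = list(rendered.sample_sheet["sample_id"])
    geno = genotypes_from_calls(rendered.calls, sample_ids)
    alignment = build_alignment(geno)
    outgroup = config.outgroup_name or alignment.samples[0]
    phylo = distance_tree(alignment, outgroup)
    if lrt_on_subsample:
        sub = subsample_one_per_haplogroup(
            alignment, rendered.sample_sheet, seed=config.master_seed,
            outgroup=outgroup, min_samples=min_samples,
        )
        sub_tree = distance_tree(sub, outgroup)
        lrt = clock_lrt(sub_tree, sub)
    else:
        lrt = clock_lrt(phylo, alignment)
    ml_tree, kappa_hat, _ = ml_branch_lengths(phylo, alignment, **(ml_opts or {}))
    hap = truth.haplogroup
    branch_rates = terminal_branch_rates(ml_tree, haplogroups=hap,
                                         exclude=[outgroup])

    # replication timing
    profile = depth_to_profile(rendered.depth, rendered.windows, timing_cfg)
    profile = consensus_profile(profile)
    wcl_y = wcl[wcl["chrom"] == "Y"]
    wcl_counts = mutations_per_window(wcl_y["pos"], rendered.windows)
    germ_counts = mutations_per_window(alignment.positions, rendered.windows)
    rng = np.random.default_rng(np.random.SeedSequence((config.master_seed, 7)))
    wcl_trend = bin_timing_vs_mutations(
        profile.consensus, wcl_counts, n_permutations=n_permutations, rng=rng
    )
    germ_trend = bin_timing_vs_mutations(
        profile.consensus, germ_counts, n_permutations=n_permutations, rng=rng
    )

    # spectra: germline (fixed differences) vs within-cell-line
    from .detection import mutation_class

    germ_cls = pd.DataFrame({
        "mut_class": [
            mutation_class(truth.germline_ref[int(p)],
                           a)[0]
            for p, a in _germline_derived(truth)
        ]
    })
    cosine = (
        spectrum_similarity(mutation_spectrum(wcl), mutation_spectrum(germ_cls))
        if len(wcl) and len(germ_cls) else np.nan
    )

    summaries = haplogroup_summaries(rates, branch_rates, min_samples=min_samples)
    try:
        correlation = correlate_rate_vs_branch(summaries)
    except ValueError:
        correlation = None

    manifest = {
        "version": __version__,
        "seed": config.master_seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "config": _config_dict(config),
        "counts": {
            "samples": len(sample_ids),
            "calls": int(len(rendered.calls)),
            "wcl": int(len(wcl)),
            "invalid_rate_samples": int((~rates["valid"]).sum()),
            "alignment_sites": int(alignment.n_sites),
            "branch_rate_outliers": int(branch_rates["outlier"].sum()),
        },
    }
    result = PipelineResult(
        manifest, wcl, rates, rate_test, spread, lrt, branch_rates,
        summaries, correlation, profile, wcl_trend, germ_trend, cosine,
    )
    if outdir is not None:
        _write_outputs(result, ml_tree, rejects, outdir, make_plots)
    return result


def _germline_derived(truth):
    """(position, derived base) pairs over all germline variable sites."""
    from .likelihood import BASES

    mat = truth.alignment.matrix
    out = []
    for j, pos in enumerate(truth.alignment.positions):
        ref = truth.germline_ref[int(pos)]
        alleles = {BASES[c] for c in np.unique(mat[:, j])}
        for a in sorted(alleles - {ref}):
            out.append((pos, a))
    return out


def _config_dict(config: CohortConfig) -> dict:
    import dataclasses

    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _write_outputs(result: PipelineResult, ml_tree, rejects, outdir, make_plots):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.wcl.to_csv(outdir / "wcl_mutations.tsv", sep="\t", index=False)
    if rejects is not None:
        rejects.to_csv(outdir / "wcl_rejects.tsv", sep="\t", index=False)
    result.rates.to_csv(outdir / "relative_rates.tsv", sep="\t", index=False,
                        float_format="%.8g")
    result.branch_rates.to_csv(outdir / "branch_rates.tsv", sep="\t", index=False,
                               float_format="%.8g")
    result.summaries.to_csv(outdir / "haplogroup_summaries.tsv", sep="\t",
                            index=False, float_format="%.8g")
    with open(outdir / "tree_ml.nwk", "w") as fh:
        fh.write(newick(ml_tree) + "\n")
    stats_out = {
        "kruskal_wallis_H": result.rate_test.statistic,
        "kruskal_wallis_p": result.rate_test.p_value,
        "median_spread_percent": result.spread_percent,
        "clock_lrt_statistic": result.lrt.statistic,
        "clock_lrt_df": result.lrt.df,
        "clock_lrt_p": result.lrt.p_value,
        "rate_branch_rho": result.correlation.rho if result.correlation else None,
        "rate_branch_p": result.correlation.p_value if result.correlation else None,
        "wcl_timing_slope": result.wcl_trend.slope,
        "germline_timing_slope": result.germline_trend.slope,
        "spectrum_cosine": result.spectrum_cosine,
    }
    with open(outdir / "headline_stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    if make_plots:
        from . import plotting

        plotting.plot_rate_by_haplogroup(result.rates,
                                         outdir / "rates_by_haplogroup.png")
        plotting.plot_timing_profile(result.profile, outdir / "timing_profile.png")
        plotting.plot_timing_bins(result.wcl_trend, outdir / "timing_bins.png")
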