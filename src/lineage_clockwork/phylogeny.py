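"""Y-chromosome phylogeny construction and branch-rate heterogeneity.

The analysis chain mirrors how branch-length heterogeneity is quantified on
male-specific haploid data:

1. build a haploid alignment of biallelic variable sites;
2. neighbor-joining topology on pairwise K2P distances, rooted on a
   designated outgroup sample, branch lengths then re-optimized by maximum
   likelihood under K2P;
3. a molecular-clock likelihood-ratio test (free branch lengths vs an
   ultrametric constraint, kappa profiled in both models);
4. RelTime-style normalized terminal-branch relative evolutionary rates.

Because the alignments contain variable sites only, likelihood fits condition
on site variability (ascertainment correction); the raw pruning likelihood is
also exposed uncorrected for oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .likelihood import (
    BASE_CODE,
    MISSING,
    LikelihoodEngine,
    TreeArrays,
    compress_patterns,
    pruning_loglik,
    tree_to_arrays,
)
from .trees import Node, neighbor_joining, postorder, tips

__all__ = [
    "Alignment",
    "Phylogeny",
    "AnalysisError",
    "build_alignment",
    "genotypes_from_calls",
    "k2p_pairwise_distances",
    "distance_tree",
    "pruning_likelihood",
    "ml_branch_lengths",
    "ClockLRTResult",
    "clock_lrt",
    "terminal_branch_rates",
    "subsample_one_per_haplogroup",
]


class AnalysisError(ValueError):
    """Raised when an analysis precondition is violated (too few samples/sites)."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Haploid allele matrix over biallelic variable sites.

    ``matrix`` is ``(n_samples, n_sites)`` uint8 with A=0, C=1, G=2, T=3 and
    4 for missing; rows follow ``samples``.
    """

    samples: list[str]
    positions: np.ndarray
    matrix: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def subset(self, keep: list[str]) -> "Alignment":
        idx = [self.samples.index(s) for s in keep]
        sub = self.matrix[idx]
        # re-filter: sites may become invariant in the subset
        var = _variable_biallelic_mask(sub)
        return Alignment(list(keep), self.positions[var], sub[:, var])

    def row_order(self, names: list[str]) -> np.ndarray:
        return self.matrix[[self.samples.index(n) for n in names]]


def _variable_biallelic_mask(matrix: np.ndarray) -> np.ndarray:
    m = matrix.shape[1]
    mask = np.zeros(m, dtype=bool)
    for j in range(m):
        col = matrix[:, j]
        alleles = np.unique(col[col != MISSING])
        mask[j] = len(alleles) == 2
    return mask


def build_alignment(
    genotypes: pd.DataFrame,
    callable_regions=None,
    max_missing: float = 0.2,
) -> Alignment:
    """Build a biallelic variable-site alignment from a site x sample table.

    Parameters
    ----------
    genotypes : DataFrame
        Index = 1-based positions, columns = sample ids, values = single
        bases in ACGT or one of ``{'N', '.', ''}`` for missing.
    callable_regions : RegionSet, optional
        If given, sites outside it are dropped.
    max_missing : float
        Samples whose missing fraction exceeds this are dropped (logged via
        the returned object's sample list).
    """
    positions = genotypes.index.to_numpy()
    samples = list(genotypes.columns)
    mat = np.full((len(samples), len(positions)), MISSING, dtype=np.uint8)
    vals = genotypes.to_numpy(dtype=object)
    for b, code in BASE_CODE.items():
        mat[(vals == b).T] = code
    if callable_regions is not None:
        inside = callable_regions.contains(positions - 1)  # to 0-based
        mat = mat[:, inside]
        positions = positions[inside]
    # drop high-missingness samples
    miss = (mat == MISSING).mean(axis=1) if mat.shape[1] else np.zeros(len(samples))
    keep = miss <= max_missing
    mat = mat[keep]
    samples = [s for s, k in zip(samples, keep) if k]
    if len(samples) < 4:
        raise AnalysisError(f"need >=4 samples after filtering, got {len(samples)}")
    var = _variable_biallelic_mask(mat)
    mat = mat[:, var]
    positions = positions[var]
    if mat.shape[1] < 10:
        raise AnalysisError(f"need >=10 variable sites, got {mat.shape[1]}")
    return Alignment(samples, np.asarray(positions), mat)


def genotypes_from_calls(
    calls: pd.DataFrame,
    samples: list[str],
    ref_by_pos: dict[int, str] | None = None,
    min_af_hom: float = 0.9,
    min_depth: int = 4,
    chrom: str = "Y",
) -> pd.DataFrame:
    """Derive a haploid site x sample genotype table from variant calls.

    A sample is assigned the alternative base at a site when its alternative
    allele fraction is at least ``min_af_hom`` (a fixed difference on a
    haploid chromosome); a site record with lower AF leaves the sample at the
    reference base; samples without a record are reference (VCFs are sparse);
    records with depth below ``min_depth`` become missing.
    """
    sub = calls[calls["chrom"] == chrom]
    hom = sub[sub["alt_reads"] >= min_af_hom * sub["depth"]]
    sites = np.sort(hom["pos"].unique())
    pos_idx = {p: i for i, p in enumerate(sites)}
    smp_idx = {s: i for i, s in enumerate(samples)}
    ref_series = hom.groupby("pos")["ref"].first()
    if ref_by_pos is not None:
        ref = np.array([ref_by_pos[p] for p in sites], dtype=object)
    else:
        ref = ref_series.reindex(sites).to_numpy(dtype=object)
    mat = np.tile(ref[:, None], (1, len(samples)))
    keep = hom["sample_id"].isin(smp_idx)
    ri = hom.loc[keep, "pos"].map(pos_idx).to_numpy()
    ci = hom.loc[keep, "sample_id"].map(smp_idx).to_numpy()
    mat[ri, ci] = hom.loc[keep, "alt"].to_numpy(dtype=object)
    low = sub[(sub["depth"] < min_depth) & sub["pos"].isin(pos_idx)
              & sub["sample_id"].isin(smp_idx)]
    if len(low):
        mat[low["pos"].map(pos_idx).to_numpy(),
            low["sample_id"].map(smp_idx).to_numpy()] = "N"
    return pd.DataFrame(mat, index=sites, columns=samples)


# ---------------------------------------------------------------------------
# Distances and topology
# ---------------------------------------------------------------------------

def k2p_pairwise_distances(matrix: np.ndarray, saturation_value: float = 5.0) -> np.ndarray:
    """Pairwise K2P distances between alignment rows.

    Proportions are computed over sites non-missing in both sequences.
    Saturated pairs (log arguments <= 0) get ``saturation_value``.
    """
    valid = (matrix != MISSING)
    ind = [((matrix == b) & valid).astype(float) for b in range(4)]
    vf = valid.astype(float)
    n_valid = vf @ vf.T
    same = sum(i @ i.T for i in ind)
    ts = ind[0] @ ind[2].T + ind[2] @ ind[0].T + ind[1] @ ind[3].T + ind[3] @ ind[1].T
    mismatch = n_valid - same
    tv = mismatch - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_valid > 0, ts / n_valid, 0.0)
        Q = np.where(n_valid > 0, tv / n_valid, 0.0)
        a1 = 1.0 - 2.0 * P - Q
        a2 = 1.0 - 2.0 * Q
        d = np.where(
            (a1 > 0) & (a2 > 0),
            -0.5 * np.log(np.maximum(a1, 1e-300) * np.sqrt(np.maximum(a2, 1e-300))),
            saturation_value,
        )
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Phylogeny:
    """Rooted binary tree with branch lengths in substitutions/site."""

    root: Node
    outgroup: str

    def tip_names(self) -> list[str]:
        return [t.name for t in tips(self.root)]


def distance_tree(alignment: Alignment, outgroup: str) -> Phylogeny:
    """Neighbor-joining topology on K2P distances, rooted on ``outgroup``.

    Negative NJ branch lengths are clamped to zero; Q-matrix ties are broken
    toward the lowest-index pair (see :func:`lineage_clockwork.trees.neighbor_joining`).
    """
    if len(alignment.samples) < 4:
        raise AnalysisError("neighbor joining needs >=4 samples")
    if outgroup not in alignment.samples:
        raise AnalysisError(f"outgroup {outgroup!r} not in alignment")
    d = k2p_pairwise_distances(alignment.matrix)
    unrooted = neighbor_joining(d, alignment.samples)
    return Phylogeny(unrooted.root_on(outgroup), outgroup)


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def pruning_likelihood(
    tree: Phylogeny | Node,
    alignment: Alignment,
    kappa: float,
    ascertainment: bool = False,
) -> float:
    """Felsenstein-pruning log-likelihood of the alignment on the tree (K2P).

    Missing bases are marginalized. With ``ascertainment=True`` the
    likelihood conditions on sites being variable.
    """
    root = tree.root if isinstance(tree, Phylogeny) else tree
    arr = tree_to_arrays(root)
    matrix = alignment.row_order(arr.tip_names)
    return pruning_loglik(arr, matrix, kappa, ascertainment=ascertainment)


def _node_index_map(root: Node, arr: TreeArrays) -> dict[int, int]:
    name_to_idx = {n: i for i, n in enumerate(arr.tip_names)}
    idx: dict[int, int] = {}
    k = 0
    for n in postorder(root):
        if n.is_tip:
            idx[id(n)] = name_to_idx[n.name]
        else:
            idx[id(n)] = arr.n_tips + k
            k += 1
    return idx


def _fit_free(
    engine: LikelihoodEngine,
    bl0: np.ndarray,
    kappa0: float,
    profile_kappa: bool,
    rounds: int = 2,
    **opt_kwargs,
) -> tuple[np.ndarray, float, float]:
    bl, kappa = bl0.copy(), kappa0
    lnl = -np.inf
    for r in range(rounds):
        bl, lnl = engine.optimize_free(bl, kappa, **opt_kwargs)
        if profile_kappa:
            kappa = engine.optimize_kappa(bl, kappa)
            lnl = engine.loglik(bl, kappa)
    return bl, kappa, lnl


def _fit_clock(
    engine: LikelihoodEngine,
    h0: np.ndarray,
    kappa0: float,
    profile_kappa: bool,
    rounds: int = 2,
) -> tuple[np.ndarray, float, float]:
    h, kappa = h0.copy(), kappa0
    lnl = -np.inf
    for r in range(rounds):
        h, lnl = engine.optimize_clock(h, kappa)
        if profile_kappa:
            kappa = engine.optimize_kappa(engine.arr.blens_from_heights(h), kappa)
            lnl = engine.loglik(engine.arr.blens_from_heights(h), kappa)
    return h, kappa, lnl


def ml_branch_lengths(
    tree: Phylogeny | Node,
    alignment: Alignment,
    kappa0: float = 2.0,
    profile_kappa: bool = True,
    ascertainment: bool = True,
    rounds: int = 2,
    **opt_kwargs,
) -> tuple[Node, float, float]:
    """Re-optimize branch lengths of a rooted tree by maximum likelihood.

    Returns a deep-copied tree with updated branch lengths, the profiled
    kappa, and the final log-likelihood. ``rounds`` and ``opt_kwargs``
    (``max_sweeps``, ``tol``) trade precision for speed on large trees.
    """
    root = tree.root if isinstance(tree, Phylogeny) else tree
    arr = tree_to_arrays(root)
    matrix = alignment.row_order(arr.tip_names)
    patterns, counts = compress_patterns(matrix)
    engine = LikelihoodEngine(arr, patterns, counts, ascertainment=ascertainment)
    bl, kappa, lnl = _fit_free(engine, arr.blen, kappa0, profile_kappa,
                               rounds=rounds, **opt_kwargs)
    idx = _node_index_map(root, arr)
    import copy

    new_root = copy.deepcopy(root)
    for old, new in zip(postorder(root), postorder(new_root)):
        new.length = float(bl[idx[id(old)]]) if new.parent is not None else 0.0
    return new_root, kappa, lnl


@dataclass
class ClockLRTResult:
    """Molecular-clock likelihood-ratio test result.

    ``statistic = 2 (lnL_free - lnL_clock)`` compared to chi-square with
    ``df = n_tips - 2`` (2n-3 identifiable free branch lengths vs n-1 node
    heights).
    """

    lnl_free: float
    lnl_clock: float
    statistic: float
    df: int
    p_value: float
    kappa_free: float
    kappa_clock: float
    n_tips: int
    converged: bool = True

    def summary(self) -> str:
        return (
            "Molecular clock likelihood-ratio test (K2P)\n"
            f"  tips                {self.n_tips}\n"
            f"  lnL (free)          {self.lnl_free:.4f}   kappa = {self.kappa_free:.3f}\n"
            f"  lnL (clock)         {self.lnl_clock:.4f}   kappa = {self.kappa_clock:.3f}\n"
            f"  2*dlnL              {self.statistic:.4f}\n"
            f"  df                  {self.df}\n"
            f"  P (chi-square)      {self.p_value:.3e}\n"
        )


def clock_lrt(
    tree: Phylogeny | Node,
    alignment: Alignment,
    kappa0: float = 2.0,
    profile_kappa: bool = True,
    ascertainment: bool = True,
) -> ClockLRTResult:
    """Likelihood-ratio test of rate homogeneity (molecular clock).

    Branch lengths are optimized by coordinate ascent under the free model
    and under the ultrametric constraint; kappa is profiled jointly in each.
    """
    root = tree.root if isinstance(tree, Phylogeny) else tree
    arr = tree_to_arrays(root)
    n = arr.n_tips
    if n < 4:
        raise AnalysisError("clock LRT needs >=4 tips")
    matrix = alignment.row_order(arr.tip_names)
    patterns, counts = compress_patterns(matrix)
    engine = LikelihoodEngine(arr, patterns, counts, ascertainment=ascertainment)

    bl_free, kappa_free, lnl_free = _fit_free(
        engine, np.clip(arr.blen, 0.0, 5.0), kappa0, profile_kappa
    )
    arr.blen = bl_free  # heights init from the free fit
    h0 = arr.heights_from_blens()
    h, kappa_clock, lnl_clock = _fit_clock(engine, h0, kappa_free, profile_kappa)

    converged = True
    if lnl_free < lnl_clock:
        # free model must dominate its nested submodel: restart from the
        # clock solution and re-optimize
        bl_free, kappa_free, lnl2 = _fit_free(
            engine, arr.blens_from_heights(h), kappa_clock, profile_kappa
        )
        if lnl2 >= lnl_free:
            lnl_free = lnl2
        converged = lnl_free >= lnl_clock - 1e-6

    statistic = max(0.0, 2.0 * (lnl_free - lnl_clock))
    df = n - 2
    p = float(chi2.sf(statistic, df))
    return ClockLRTResult(
        lnl_free, lnl_clock, statistic, df, p, kappa_free, kappa_clock, n, converged
    )


# ---------------------------------------------------------------------------
# RelTime-style terminal branch rates
# ---------------------------------------------------------------------------

def _mean_tip_path(root: Node) -> tuple[dict[int, float], dict[int, int]]:
    mean_path: dict[int, float] = {}
    n_below: dict[int, int] = {}
    for node in postorder(root):
        if node.is_tip:
            mean_path[id(node)] = 0.0
            n_below[id(node)] = 1
        else:
            tot, cnt = 0.0, 0
            for c in node.children:
                nc = n_below[id(c)]
                tot += nc * (c.length + mean_path[id(c)])
                cnt += nc
            mean_path[id(node)] = tot / cnt
            n_below[id(node)] = cnt
    return mean_path, n_below


def terminal_branch_rates(
    tree: Phylogeny | Node,
    haplogroups: pd.Series | None = None,
    exclude: list[str] | None = None,
    mad_cut: float = 5.0,
) -> pd.DataFrame:
    """Relative evolutionary rate of each terminal branch, normalized to mean 1.

    Uses a RelTime-style recursion: at every internal node the relative rates
    of the two descendant lineages are proportional to the mean node-to-tip
    path length within each subtree (their geometric mean is the local
    reference), and lineage rates propagate multiplicatively from the root.
    Rates are normalized to mean 1 over retained samples; samples whose
    normalized rate deviates from 1 by more than ``mad_cut`` scaled median
    absolute deviations are flagged as outliers, removed, and the remainder
    re-normalized (again to mean exactly 1).

    Returns a DataFrame with columns ``sample_id, haplogroup, raw_rate,
    normalized_rate, outlier``; ``normalized_rate`` is NaN for outliers.
    """
    root = tree.root if isinstance(tree, Phylogeny) else tree
    if isinstance(tree, Phylogeny) and exclude is None:
        exclude = [tree.outgroup]
    exclude = set(exclude or [])
    mean_path, _ = _mean_tip_path(root)
    depth_total = max(c.length + mean_path[id(c)] for c in root.children) if root.children else 0.0
    if depth_total <= 0:
        raise AnalysisError("tree has zero depth; rates undefined")
    # floor lineage depths at a small fraction of the tree depth so that
    # zero-length cherries (no mutations sampled on a branch) do not send
    # their sibling's relative rate to infinity
    floor = 1e-3 * depth_total

    rate: dict[int, float] = {id(root): 1.0}
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_tip:
            continue
        lens = [max(c.length + mean_path[id(c)], floor) for c in node.children]
        g = float(np.exp(np.mean(np.log(lens))))
        for c, L in zip(node.children, lens):
            rate[id(c)] = rate[id(node)] * L / g
            stack.append(c)

    rows = []
    for t in tips(root):
        if t.name in exclude:
            continue
        hap = haplogroups.get(t.name) if haplogroups is not None else None
        rows.append((t.name, hap, rate[id(t)]))
    df = pd.DataFrame(rows, columns=["sample_id", "haplogroup", "raw_rate"])
    norm = df["raw_rate"] / df["raw_rate"].mean()
    # robust cut centered on the median: a single fast tip drags the mean,
    # so deviation from the median (not from 1) identifies it cleanly
    med = norm.median()
    mad = 1.4826 * (norm - med).abs().median()
    if mad > 0 and np.isfinite(mad_cut):
        outlier = (norm - med).abs() > mad_cut * mad
    else:
        outlier = pd.Series(False, index=df.index)
    # the cut is meant to drop a handful of aberrant samples; on small or
    # heavy-tailed trees a raw MAD rule can flag most of the cohort, so cap
    # removal at 20% of samples (otherwise keep everyone)
    if outlier.mean() > 0.2:
        outlier = pd.Series(False, index=df.index)
    retained = norm[~outlier]
    df["outlier"] = outlier
    df["normalized_rate"] = np.nan
    df.loc[~outlier, "normalized_rate"] = retained / retained.mean()
    return df


def subsample_one_per_haplogroup(
    alignment: Alignment,
    sample_sheet: pd.DataFrame,
    seed: int,
    outgroup: str | None = None,
    min_samples: int = 11,
) -> Alignment:
    """One uniformly chosen sample per eligible haplogroup (plus outgroup).

    Haplogroups with fewer than ``min_samples`` samples (default: more than
    ten required) are excluded. Deterministic for a given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sheet = sample_sheet[sample_sheet["sample_id"].isin(alignment.samples)]
    chosen: list[str] = []
    for hap, grp in sheet.groupby("haplogroup", sort=True):
        ids = sorted(grp["sample_id"])
        if outgroup in ids:
            ids.remove(outgroup)
        if len(ids) >= min_samples:
            chosen.append(ids[int(rng.integers(len(ids)))])
    if outgroup is not None and outgroup in alignment.samples:
        chosen.append(outgroup)
    return alignment.subset(chosen)
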