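"""Synthetic cohort generator with known ground truth.

Emulates the structure of a male LCL sequencing cohort on the haploid
(non-pseudoautosomal) sex chromosomes:

* a rooted ultrametric coalescent-shaped tree with haplogroup-monophyletic
  clades, an optional deeper-diverging outgroup sample, and per-branch
  germline rate multipliers (a haplogroup's multiplier applies to every
  branch private to its clade, including the stem);
* germline haplotypes simulated site-by-site under K2P along that tree;
* per-sample clonal somatic mutations on X and Y (Poisson burdens, Y burden
  scaled by a haplogroup-specific multiplier) carried by a Beta-distributed
  fraction of cells, with Y placement optionally coupled to replication
  timing;
* a latent replication-timing curve (sum of low-frequency sinusoids,
  rescaled to [-1, 1], higher = earlier) that modulates read depth along Y;
* rendered allele-depth evidence: Poisson window/site depths, binomial
  alternative-allele sampling at somatic sites, near-fixed alternative
  alleles at germline sites, and per-base sequencing errors.

Everything is a deterministic function of ``master_seed``; the seed spawns
named substreams (tree, germline, somatic, timing, depth, errors) so stages
can be re-rendered independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import BASES, k2p_transition_matrices
from .phylogeny import Alignment
from .trees import Node, newick, postorder, tips
from .variant_io import (
    CALL_COLUMNS,
    RegionSet,
    write_depth_table,
    write_regions,
    write_sample_sheet,
    write_vcf,
)

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "RenderedCohort",
    "ConfigurationError",
    "simulate_cohort",
    "render_sequencing",
    "write_cohort",
    "reference_base",
]

_STREAMS = ("tree", "germline", "somatic", "timing", "depth", "errors")


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Lengths are in bases, depths in reads, rates per base per read. Germline
    branch lengths are in expected substitutions per site at multiplier 1.
    """

    n_haplogroups: int = 6
    samples_per_haplogroup: int = 20
    germline_rate_multiplier: tuple[float, ...] | None = None
    somatic_multiplier_y: tuple[float, ...] | None = None
    base_somatic_burden: float = 40.0
    l_y: int = 2_000_000
    l_x: int = 2_000_000
    window_size: int = 10_000
    mean_depth: float = 30.0
    seq_error_rate: float = 1e-4
    timing_amplitude: float = 0.3
    cell_fraction_params: tuple[float, float] = (2.0, 4.0)
    placement_coupling: float = 0.5
    n_sites: int = 50_000
    tree_height: float = 0.01
    target_variable_sites: int | None = None
    kappa: float = 2.0
    gc_amplitude: float = 0.1
    include_outgroup: bool = True
    outgroup_depth_factor: float = 1.4
    within_haplogroup_fraction: float = 0.5
    batch: str = "sim"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplogroups < 1 or self.samples_per_haplogroup < 1:
            raise ConfigurationError("counts must be positive")
        if self.germline_rate_multiplier is None:
            self.germline_rate_multiplier = (1.0,) * self.n_haplogroups
        if self.somatic_multiplier_y is None:
            self.somatic_multiplier_y = (1.0,) * self.n_haplogroups
        self.germline_rate_multiplier = tuple(self.germline_rate_multiplier)
        self.somatic_multiplier_y = tuple(self.somatic_multiplier_y)
        for name in ("germline_rate_multiplier", "somatic_multiplier_y"):
            vals = getattr(self, name)
            if len(vals) != self.n_haplogroups:
                raise ConfigurationError(f"{name} needs {self.n_haplogroups} values")
            if any(v <= 0 for v in vals):
                raise ConfigurationError(f"{name} values must be > 0")
        if self.base_somatic_burden < 0:
            raise ConfigurationError("base_somatic_burden must be >= 0")
        if self.l_y <= self.window_size or self.l_x <= self.window_size:
            raise ConfigurationError("callable lengths must exceed window_size")
        if not 0.0 <= self.timing_amplitude < 1.0:
            raise ConfigurationError("timing_amplitude must be in [0, 1)")
        if not 0.0 <= self.seq_error_rate <= 0.1:
            raise ConfigurationError("seq_error_rate must be in [0, 0.1]")
        if any(p <= 0 for p in self.cell_fraction_params):
            raise ConfigurationError("cell_fraction_params must be positive")
        if self.tree_height <= 0 or self.n_sites < 1:
            raise ConfigurationError("tree_height and n_sites must be positive")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.master_seed).spawn(len(_STREAMS))
        return {n: np.random.default_rng(c) for n, c in zip(_STREAMS, children)}

    @property
    def n_windows(self) -> int:
        return self.l_y // self.window_size

    @property
    def outgroup_name(self) -> str | None:
        return "OUT" if self.include_outgroup else None


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    config: CohortConfig
    tree: Node                                  # ultrametric, time-scaled
    branch_mult: dict[int, float]               # id(node) -> germline multiplier
    alignment: Alignment                        # true germline variable sites
    haplogroup: pd.Series                       # sample_id -> haplogroup
    sample_sheet: pd.DataFrame
    latent_timing: np.ndarray                   # per Y window, in [-1, 1]
    windows: pd.DataFrame                       # chrom, start, end, gc_fraction
    somatic: pd.DataFrame                       # sample_id, chrom, pos, ref, alt, cell_fraction
    germline_ref: dict[int, str]                # Y pos -> ancestral base

    def newick(self) -> str:
        return newick(self.tree)


@dataclass
class RenderedCohort:
    """Allele-depth evidence rendered from a :class:`CohortTruth`."""

    calls: pd.DataFrame
    depth: pd.DataFrame
    windows: pd.DataFrame
    sample_sheet: pd.DataFrame
    callable_y: RegionSet
    callable_x: RegionSet


def reference_base(pos) -> np.ndarray:
    """Deterministic pseudo-reference base for a position (Knuth hash).

    Gives every genomic site a fixed reference base without storing a genome,
    so independently rendered samples agree on REF at error/somatic sites.
    """
    pos = np.asarray(pos, dtype=np.uint64)
    idx = (pos * np.uint64(2654435761)) >> np.uint64(7)
    return np.array(list(BASES))[idx % 4]


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _coalesce(
    items: list[tuple[Node, float]],
    rng: np.random.Generator,
    scale: float,
    t_start: float,
) -> tuple[Node, float]:
    """Kingman-style pairwise coalescence of (node, height) lineages."""
    items = list(items)
    t = t_start
    while len(items) > 1:
        k = len(items)
        t += rng.exponential(scale * 2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = items[i], items[j]
        parent = Node()
        na.length = t - ha
        nb.length = t - hb
        parent.add_child(na)
        parent.add_child(nb)
        items = [items[x] for x in range(k) if x not in (i, j)] + [(parent, t)]
    return items[0]


def _simulate_tree(cfg: CohortConfig, rng: np.random.Generator):
    hap_names = [f"H{i + 1:02d}" for i in range(cfg.n_haplogroups)]
    clades: list[tuple[Node, float]] = []
    clade_nodes: dict[str, list[Node]] = {}
    for hap in hap_names:
        tips_ = [Node(f"{hap}_S{j + 1:02d}") for j in range(cfg.samples_per_haplogroup)]
        if len(tips_) == 1:
            mrca, h = tips_[0], 0.0
        else:
            mrca, h = _coalesce(
                [(t, 0.0) for t in tips_], rng, cfg.within_haplogroup_fraction, 0.0
            )
        clades.append((mrca, h))
        clade_nodes[hap] = list(postorder(mrca))
    t_start = max(h for _, h in clades)
    root, h_root = _coalesce(clades, rng, 1.0, t_start)
    if cfg.include_outgroup:
        out_h = h_root * cfg.outgroup_depth_factor
        new_root = Node()
        root.length = out_h - h_root
        out_tip = Node("OUT", out_h)
        new_root.add_child(root)
        new_root.add_child(out_tip)
        root, h_root = new_root, out_h

    branch_mult: dict[int, float] = {id(n): 1.0 for n in postorder(root)}
    for hap, mult in zip(hap_names, cfg.germline_rate_multiplier):
        for n in clade_nodes[hap]:  # clade branches including the stem
            branch_mult[id(n)] = float(mult)

    # rescale: either to the requested root height, or (when a variable-site
    # target is set) so the expected number of germline mutations hits it
    if cfg.target_variable_sites is not None:
        wlen = sum(n.length * branch_mult[id(n)] for n in postorder(root))
        scale = cfg.target_variable_sites / (cfg.n_sites * wlen)
    else:
        scale = cfg.tree_height / h_root
    for n in postorder(root):
        n.length *= scale

    haplogroup = pd.Series(
        {f"{hap}_S{j + 1:02d}": hap
         for hap in hap_names for j in range(cfg.samples_per_haplogroup)}
    )
    if cfg.include_outgroup:
        haplogroup["OUT"] = "OUT"
    return root, branch_mult, haplogroup


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def _evolve_sequences(
    root: Node, branch_mult: dict[int, float], cfg: CohortConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Site-by-site K2P simulation along the tree; returns tip states + root."""
    root_seq = rng.integers(0, 4, size=cfg.n_sites).astype(np.uint8)
    seqs: dict[int, np.ndarray] = {id(root): root_seq}
    tip_seqs: dict[str, np.ndarray] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        parent_seq = seqs.pop(id(node))
        if node.is_tip:
            tip_seqs[node.name] = parent_seq
            continue
        for child in node.children:
            t = child.length * branch_mult[id(child)]
            P = k2p_transition_matrices(np.array(t), cfg.kappa)
            cum = P.cumsum(axis=1)
            u = rng.random(cfg.n_sites)
            child_seq = np.empty(cfg.n_sites, dtype=np.uint8)
            for s in range(4):
                mask = parent_seq == s
                child_seq[mask] = np.searchsorted(cum[s], u[mask], side="right")
            seqs[id(child)] = np.minimum(child_seq, 3)
            stack.append(child)
    return tip_seqs, root_seq


def _latent_timing(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth band-limited curve over Y windows, rescaled to [-1, 1]."""
    n = cfg.n_windows
    n_waves = int(rng.integers(3, 7))
    x = np.arange(n, dtype=float)
    curve = np.zeros(n)
    for _ in range(n_waves):
        period = rng.uniform(20.0, max(n, 21))
        amp = rng.uniform(0.3, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        curve += amp * np.sin(2 * np.pi * x / period + phase)
    lo, hi = curve.min(), curve.max()
    if hi - lo < 1e-12:
        return np.zeros(n)
    return 2.0 * (curve - lo) / (hi - lo) - 1.0


def _gc_track(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Window GC content: mostly fine-scale variation with a mild wave.

    GC varies window to window (local sequence composition), unlike the
    band-limited timing curve, so the two tracks are essentially orthogonal.
    """
    n = cfg.n_windows
    x = np.arange(n, dtype=float)
    curve = rng.normal(0.0, 1.0, size=n)
    for _ in range(3):
        period = rng.uniform(4.0, 15.0)
        curve += rng.uniform(0.2, 0.5) * np.sin(2 * np.pi * x / period + rng.uniform(0, 2 * np.pi))
    curve = (curve - curve.mean()) / max(curve.std(), 1e-12)
    return np.clip(0.45 + 0.06 * curve, 0.25, 0.65)


def _weighted_positions(
    n: int, cfg: CohortConfig, weights: np.ndarray, rng: np.random.Generator,
    unique: bool = True,
) -> np.ndarray:
    """Draw 1-based Y positions with window probabilities ``weights``."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    p = weights / weights.sum()
    draw = max(n, int(n * 1.2) + 8)
    while True:
        w = rng.choice(cfg.n_windows, size=draw, p=p)
        off = rng.integers(0, cfg.window_size, size=draw)
        pos = w.astype(np.int64) * cfg.window_size + off + 1
        if not unique:
            return pos[:n]
        pos = pd.unique(pos)
        if len(pos) >= n:
            return pos[:n]
        draw *= 2


def _mutate_bases(ref_codes: np.ndarray, kappa: float, rng: np.random.Generator):
    """Draw alternative alleles with transition probability kappa/(kappa+2)."""
    ts = rng.random(len(ref_codes)) < kappa / (kappa + 2.0)
    partner = np.array([2, 3, 0, 1])
    alt = np.where(ts, partner[ref_codes], 0)
    tv_choice = rng.integers(0, 2, size=len(ref_codes))
    # the two transversion targets of base b are the two bases not in {b, ts(b)}
    tv_targets = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
    alt = np.where(ts, alt, tv_targets[ref_codes, tv_choice])
    return alt.astype(np.uint8)


# ---------------------------------------------------------------------------
# simulate_cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> CohortTruth:
    """Generate the full ground truth for one cohort (see module docstring)."""
    rngs = config.rngs()
    root, branch_mult, haplogroup = _simulate_tree(config, rngs["tree"])
    latent = _latent_timing(config, rngs["timing"])
    gc = _gc_track(config, rngs["timing"])
    windows = pd.DataFrame(
        {
            "chrom": "Y",
            "start": np.arange(config.n_windows) * config.window_size,
            "end": (np.arange(config.n_windows) + 1) * config.window_size,
            "gc_fraction": gc,
        }
    )

    # germline haplotypes
    tip_seqs, root_seq = _evolve_sequences(root, branch_mult, config, rngs["germline"])
    sample_ids = [t.name for t in tips(root)]
    mat = np.stack([tip_seqs[s] for s in sample_ids])
    var_mask = np.zeros(config.n_sites, dtype=bool)
    for j in range(config.n_sites):
        col = mat[:, j]
        if len(np.unique(col)) == 2:
            var_mask[j] = True
    mat = mat[:, var_mask]
    root_var = root_seq[var_mask]
    g_weights = np.maximum(1.0 - config.placement_coupling * latent, 1e-9)
    g_pos = np.sort(
        _weighted_positions(mat.shape[1], config, g_weights, rngs["germline"])
    )
    alignment = Alignment(sample_ids, g_pos, mat)
    germline_ref = {int(p): BASES[b] for p, b in zip(g_pos, root_var)}

    # clonal somatic mutations
    rng_s = rngs["somatic"]
    hap_mult = dict(zip([f"H{i + 1:02d}" for i in range(config.n_haplogroups)],
                        config.somatic_multiplier_y))
    rows = []
    w_soma = np.maximum(1.0 - config.placement_coupling * latent, 1e-9)
    for sid in sample_ids:
        mult_y = hap_mult.get(haplogroup[sid], 1.0)
        n_y = rng_s.poisson(config.base_somatic_burden * mult_y)
        n_x = rng_s.poisson(config.base_somatic_burden)
        pos_y = _weighted_positions(n_y, config, w_soma, rng_s)
        pos_x = (rng_s.integers(0, config.l_x, size=n_x) + 1).astype(np.int64)
        for chrom, pos in (("Y", pos_y), ("X", pos_x)):
            if len(pos) == 0:
                continue
            ref = reference_base(pos - 1)
            ref_codes = np.array([BASES.index(b) for b in ref], dtype=np.uint8)
            alt_codes = _mutate_bases(ref_codes, config.kappa, rng_s)
            frac = rng_s.beta(*config.cell_fraction_params, size=len(pos))
            for p, rb, ab, f in zip(pos, ref_codes, alt_codes, frac):
                rows.append((sid, chrom, int(p), BASES[rb], BASES[ab], float(f)))
    somatic = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "cell_fraction"]
    )

    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "haplogroup": [haplogroup[s] for s in sample_ids],
            "batch": config.batch,
        }
    )
    return CohortTruth(
        config, root, branch_mult, alignment, haplogroup, sheet,
        latent, windows, somatic, germline_ref,
    )


# ---------------------------------------------------------------------------
# render_sequencing
# ---------------------------------------------------------------------------

def _window_expected_depth(cfg: CohortConfig, latent, gc) -> np.ndarray:
    z_gc = (gc - gc.mean()) / max(gc.std(), 1e-12)
    exp = cfg.mean_depth * (1.0 + cfg.timing_amplitude * latent)
    return exp * (1.0 + cfg.gc_amplitude * z_gc)


def render_sequencing(
    truth: CohortTruth, config: CohortConfig, outdir=None
) -> RenderedCohort:
    """Render allele-depth evidence (variant calls + window depths) from truth.

    Per-window Y depth is Poisson around ``mean_depth`` modulated by the
    latent timing curve (and mildly by GC); at somatic sites the alternative
    read count is Binomial(site depth, cell fraction); germline derived
    alleles render at alternative fraction ~1; sequencing errors add spurious
    alternative reads at ``seq_error_rate`` per base per read. Records enter
    the call table only when at least one alternative read was sampled.
    """
    if truth.config != config:
        raise ConfigurationError("truth was generated from a different config")
    if config.n_windows * config.window_size > config.l_y:
        raise ConfigurationError("window grid exceeds the callable region")
    rngs = config.rngs()
    rng_d, rng_e = rngs["depth"], rngs["errors"]
    latent, gc = truth.latent_timing, truth.windows["gc_fraction"].to_numpy()
    exp_w = _window_expected_depth(config, latent, gc)
    sample_ids = list(truth.alignment.samples)
    n_w = config.n_windows

    # window depth table (Y)
    depth_mat = rng_d.poisson(np.tile(exp_w, (len(sample_ids), 1)))
    depth_df = pd.DataFrame(
        {
            "chrom": "Y",
            "start": np.tile(truth.windows["start"].to_numpy(), len(sample_ids)),
            "end": np.tile(truth.windows["end"].to_numpy(), len(sample_ids)),
            "sample_id": np.repeat(sample_ids, n_w),
            "depth": depth_mat.ravel(),
        }
    )

    def site_expected(chrom: str, pos: np.ndarray) -> np.ndarray:
        if chrom == "Y":
            w = np.minimum((pos - 1) // config.window_size, n_w - 1)
            return exp_w[w]
        return np.full(len(pos), config.mean_depth)

    frames: list[pd.DataFrame] = []

    # --- germline variable sites ---
    mat = truth.alignment.matrix
    g_pos = truth.alignment.positions
    root_codes = np.array(
        [BASES.index(truth.germline_ref[int(p)]) for p in g_pos], dtype=np.uint8
    )
    exp_g = site_expected("Y", g_pos)
    for si, sid in enumerate(sample_ids):
        carrier = mat[si] != root_codes
        if not carrier.any():
            continue
        pos = g_pos[carrier]
        depth = rng_d.poisson(exp_g[carrier])
        err = rng_e.binomial(depth, min(config.seq_error_rate, 1.0))
        alt_reads = np.maximum(depth - err, 0)
        keep = (depth > 0) & (alt_reads > 0)
        frames.append(pd.DataFrame({
            "sample_id": sid,
            "chrom": "Y",
            "pos": pos[keep],
            "ref": [BASES[c] for c in root_codes[carrier][keep]],
            "alt": [BASES[c] for c in mat[si][carrier][keep]],
            "ref_reads": (depth - alt_reads)[keep],
            "alt_reads": alt_reads[keep],
            "depth": depth[keep],
        }))

    # --- somatic sites ---
    if len(truth.somatic):
        for (sid, chrom), grp in truth.somatic.groupby(["sample_id", "chrom"], sort=True):
            pos = grp["pos"].to_numpy()
            depth = rng_d.poisson(site_expected(chrom, pos))
            alt = rng_d.binomial(depth, grp["cell_fraction"].to_numpy())
            keep = alt >= 1
            if not keep.any():
                continue
            frames.append(pd.DataFrame({
                "sample_id": sid,
                "chrom": chrom,
                "pos": pos[keep],
                "ref": grp["ref"].to_numpy()[keep],
                "alt": grp["alt"].to_numpy()[keep],
                "ref_reads": (depth - alt)[keep],
                "alt_reads": alt[keep],
                "depth": depth[keep],
            }))

    # --- sequencing errors (spurious alternative reads) ---
    if config.seq_error_rate > 0:
        total_y = float((exp_w * config.window_size).sum())
        total_x = config.mean_depth * config.l_x
        w_err = exp_w * config.window_size
        germ_pos_set = set(g_pos.tolist())
        soma_by_sample = {
            (sid, chrom): set(grp["pos"].tolist())
            for (sid, chrom), grp in truth.somatic.groupby(["sample_id", "chrom"])
        } if len(truth.somatic) else {}
        for sid in sample_ids:
            for chrom, total in (("Y", total_y), ("X", total_x)):
                n_err = rng_e.poisson(total * config.seq_error_rate)
                if n_err == 0:
                    continue
                if chrom == "Y":
                    pos = _weighted_positions(n_err, config, w_err, rng_e, unique=False)
                else:
                    pos = (rng_e.integers(0, config.l_x, size=n_err) + 1).astype(np.int64)
                pos, alt_counts = np.unique(pos, return_counts=True)
                occupied = soma_by_sample.get((sid, chrom), set())
                if chrom == "Y":
                    occupied = occupied | germ_pos_set
                if occupied:
                    free = ~np.isin(pos, np.fromiter(occupied, dtype=np.int64,
                                                     count=len(occupied)))
                    pos, alt_counts = pos[free], alt_counts[free]
                if len(pos) == 0:
                    continue
                depth = np.maximum(rng_e.poisson(site_expected(chrom, pos)), alt_counts)
                ref = reference_base(pos - 1)
                ref_codes = np.array([BASES.index(b) for b in ref], dtype=np.uint8)
                shift = rng_e.integers(1, 4, size=len(pos)).astype(np.uint8)
                alt_codes = (ref_codes + shift) % 4
                frames.append(pd.DataFrame({
                    "sample_id": sid,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": np.array(list(BASES))[alt_codes],
                    "ref_reads": depth - alt_counts,
                    "alt_reads": alt_counts,
                    "depth": depth,
                }))

    if frames:
        calls = pd.concat(frames, ignore_index=True)
        calls = calls.sort_values(["sample_id", "chrom", "pos"], kind="mergesort")
        calls = calls.reset_index(drop=True)
    else:
        calls = pd.DataFrame(columns=CALL_COLUMNS)
    calls = calls.astype({"pos": np.int64, "ref_reads": np.int64,
                          "alt_reads": np.int64, "depth": np.int64})

    rendered = RenderedCohort(
        calls=calls,
        depth=depth_df,
        windows=truth.windows,
        sample_sheet=truth.sample_sheet,
        callable_y=RegionSet.from_intervals("Y", [(0, config.l_y)]),
        callable_x=RegionSet.from_intervals("X", [(0, config.l_x)]),
    )
    if outdir is not None:
        write_cohort(rendered, truth, outdir)
    return rendered


def write_cohort(rendered: RenderedCohort, truth: CohortTruth, outdir) -> None:
    """Write the rendered cohort (VCFs, BEDs, TSVs, truth tables) to disk."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    contigs = {"X": cfg.l_x, "Y": cfg.l_y}
    for sid in rendered.sample_sheet["sample_id"]:
        write_vcf(rendered.calls, outdir / "vcf" / f"{sid}.vcf", sid, contigs)
    write_regions(rendered.callable_y, outdir / "callable_Y.bed")
    write_regions(rendered.callable_x, outdir / "callable_X.bed")
    write_sample_sheet(rendered.sample_sheet, outdir / "samples.tsv")
    write_depth_table(rendered.depth, outdir / "depth_Y.tsv")
    rendered.windows.to_csv(outdir / "windows_Y.tsv", sep="\t", index=False,
                            float_format="%.6f")
    truth.somatic.to_csv(outdir / "truth_somatic.tsv", sep="\t", index=False,
                         float_format="%.8f")
    pd.DataFrame({
        "window": np.arange(len(truth.latent_timing)),
        "latent_timing": truth.latent_timing,
    }).to_csv(outdir / "truth_timing.tsv", sep="\t", index=False,
              float_format="%.8f")
    with open(outdir / "truth_tree.nwk", "w") as fh:
        fh.write(truth.newick() + "\n")
    mult = pd.DataFrame({
        "haplogroup": [f"H{i + 1:02d}" for i in range(cfg.n_haplogroups)],
        "germline_rate_multiplier": cfg.germline_rate_multiplier,
        "somatic_multiplier_y": cfg.somatic_multiplier_y,
    })
    mult.to_csv(outdir / "truth_multipliers.tsv", sep="\t", index=False)
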