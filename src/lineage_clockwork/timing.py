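"""Replication-timing inference from windowed read depth.

In proliferating cells an unsynchronized population contains more copies of
early-replicating than late-replicating loci, so average sequencing depth
along a chromosome carries a replication-timing signal. Per sample the
pipeline: (1) normalizes window depth by the sample mean; (2) masks outlier
windows (3 scaled MADs from the median); (3) removes GC bias as the residual
of a local (lowess) regression on window GC content; (4) smooths with a
Gaussian kernel; (5) standardizes to mean 0, variance 1. The sign convention
is "above-average depth = earlier replication" (higher value = earlier). A
consensus profile is the per-window mean across samples.

The timing-mutation relationship is summarized by ranking windows on the
consensus, splitting them into equal-size quantile bins (default 25),
averaging timing and mutation counts per bin, and reporting the least-squares
slope across bins plus a Spearman correlation across windows. Because both
tracks are autocorrelated along the chromosome, significance is assessed by
a circular-shift permutation of the mutation track rather than an analytic
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "TimingConfig",
    "ReplicationProfile",
    "ProfileError",
    "depth_to_profile",
    "consensus_profile",
    "mutations_per_window",
    "bin_timing_vs_mutations",
    "TimingTrend",
]


class ProfileError(ValueError):
    """Raised when a replication profile cannot be computed."""


@dataclass
class TimingConfig:
    outlier_mads: float = 3.0
    lowess_frac: float = 0.3
    smooth_bandwidth: float = 3.0   # Gaussian kernel SD, in windows; 0 = off
    min_windows: int = 20
    gc_correct: bool = True


@dataclass
class ReplicationProfile:
    """Per-sample standardized timing values over a fixed window grid."""

    windows: pd.DataFrame                  # chrom, start, end, gc_fraction
    samples: list[str]
    values: np.ndarray                     # (n_samples, n_windows), NaN = missing
    flat_samples: list[str] = field(default_factory=list)
    consensus: np.ndarray | None = None
    n_samples_per_window: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def _nan_gaussian_smooth(v: np.ndarray, bw: float) -> np.ndarray:
    if bw <= 0:
        return v
    half = int(np.ceil(4 * bw))
    x = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (x / bw) ** 2)
    mask = np.isfinite(v).astype(float)
    filled = np.where(np.isfinite(v), v, 0.0)
    num = np.convolve(filled, kern, mode="same")
    den = np.convolve(mask, kern, mode="same")
    out = np.full_like(v, np.nan)
    ok = (den > 1e-12) & np.isfinite(v)  # masked windows stay missing
    out[ok] = num[ok] / den[ok]
    return out


def depth_to_profile(
    depth: pd.DataFrame,
    windows: pd.DataFrame,
    cfg: TimingConfig | None = None,
) -> ReplicationProfile:
    """Per-sample standardized replication-timing profiles from window depth.

    ``depth`` has columns chrom, start, end, sample_id, depth; ``windows``
    defines the grid (chrom, start, end, gc_fraction). Samples with fewer
    than ``cfg.min_windows`` usable windows, or with zero depth variance
    (flat profile), are flagged in ``flat_samples`` and carry all-NaN values.
    """
    cfg = cfg or TimingConfig()
    key = windows.set_index(["chrom", "start"]).index
    samples = sorted(depth["sample_id"].unique())
    n_w = len(windows)
    values = np.full((len(samples), n_w), np.nan)
    flat: list[str] = []
    gc = windows["gc_fraction"].to_numpy()
    for si, sid in enumerate(samples):
        sub = depth[depth["sample_id"] == sid]
        v = np.full(n_w, np.nan)
        idx = key.get_indexer(pd.MultiIndex.from_frame(sub[["chrom", "start"]]))
        ok = idx >= 0
        v[idx[ok]] = sub["depth"].to_numpy(dtype=float)[ok]
        mean = np.nanmean(v) if np.isfinite(v).any() else np.nan
        if not np.isfinite(mean) or mean <= 0:
            flat.append(sid)
            continue
        v = v / mean
        med = np.nanmedian(v)
        mad = 1.4826 * np.nanmedian(np.abs(v - med))
        if mad > 0:
            v[np.abs(v - med) > cfg.outlier_mads * mad] = np.nan
        usable = np.isfinite(v)
        if usable.sum() < cfg.min_windows:
            flat.append(sid)
            continue
        if cfg.gc_correct and np.nanstd(gc[usable]) > 0:
            fit = lowess(v[usable], gc[usable], frac=cfg.lowess_frac,
                         return_sorted=False)
            v[usable] = v[usable] - fit
        v = _nan_gaussian_smooth(v, cfg.smooth_bandwidth)
        usable = np.isfinite(v)
        sd = np.nanstd(v)
        if sd < 1e-12:
            flat.append(sid)
            continue
        values[si] = (v - np.nanmean(v)) / sd
    return ReplicationProfile(windows, samples, values, flat)


def consensus_profile(
    profile: ReplicationProfile, min_fraction: float = 0.5
) -> ReplicationProfile:
    """Average profiles across samples into a consensus track.

    Windows covered by fewer than ``min_fraction`` of contributing samples
    are masked. Requires at least two non-flat samples.
    """
    good = [s for s in profile.samples if s not in profile.flat_samples]
    if len(good) < 2:
        raise ProfileError("consensus needs >=2 usable samples")
    vals = profile.values[[profile.samples.index(s) for s in good]]
    n_per = np.isfinite(vals).sum(axis=0)
    if n_per.max() == 0:
        raise ProfileError("no overlapping windows across samples")
    with np.errstate(invalid="ignore"):
        cons = np.nanmean(vals, axis=0)
    cons[n_per < min_fraction * len(good)] = np.nan
    profile.consensus = cons
    profile.n_samples_per_window = n_per
    return profile


def mutations_per_window(positions, windows: pd.DataFrame) -> np.ndarray:
    """Count 1-based mutation positions per window of the grid."""
    edges = np.append(windows["start"].to_numpy(), windows["end"].to_numpy()[-1])
    counts, _ = np.histogram(np.asarray(positions, dtype=np.int64) - 1, bins=edges)
    return counts.astype(float)


@dataclass
class TimingTrend:
    bins: pd.DataFrame             # bin, mean_timing, mean_mutations, n_windows
    slope: float                   # least-squares slope across bin means
    spearman_rho: float            # across windows
    spearman_p: float
    permutation_p: float | None = None
    permutation_interval: tuple[float, float] | None = None


def bin_timing_vs_mutations(
    consensus: np.ndarray,
    mutation_counts: np.ndarray,
    n_bins: int = 25,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> TimingTrend:
    """Quantile-bin the consensus timing and regress mutation counts on it.

    Windows with a defined consensus value are ranked by timing and split
    into ``n_bins`` equal-size bins (sizes differ by at most one window).
    The trend is the least-squares slope of per-bin mean mutation count on
    per-bin mean timing; a window-level Spearman correlation is reported
    alongside. With ``n_permutations`` > 0, a circular-shift permutation of
    the mutation track yields a two-sided p-value and the central 95%
    interval of null slopes (the track's autocorrelation makes analytic
    p-values unreliable).
    """
    ok = np.isfinite(consensus)
    timing = consensus[ok]
    counts = np.asarray(mutation_counts, dtype=float)[ok]
    if n_bins > len(timing):
        raise ValueError(f"n_bins={n_bins} exceeds {len(timing)} usable windows")

    def _slope(c: np.ndarray) -> tuple[float, pd.DataFrame]:
        order = np.argsort(timing, kind="stable")
        chunks = np.array_split(order, n_bins)
        rows = [
            (i + 1, timing[ch].mean(), c[ch].mean(), len(ch))
            for i, ch in enumerate(chunks)
        ]
        bins = pd.DataFrame(rows, columns=["bin", "mean_timing", "mean_mutations",
                                           "n_windows"])
        sl = np.polyfit(bins["mean_timing"], bins["mean_mutations"], 1)[0]
        return float(sl), bins

    slope, bins = _slope(counts)
    if np.ptp(counts) == 0 or np.ptp(timing) == 0:
        rho, rho_p = np.nan, np.nan
    else:
        rho, rho_p = stats.spearmanr(timing, counts)

    perm_p = None
    interval = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        n = len(counts)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            shift = int(rng.integers(1, n))
            null[i] = _slope(np.roll(counts, shift))[0]
        perm_p = float((np.sum(np.abs(null) >= abs(slope)) + 1) / (n_permutations + 1))
        interval = (float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975)))
    return TimingTrend(bins, slope, float(rho), float(rho_p), perm_p, interval)
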