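"""Relative Y-chromosome somatic mutation rate and interhaplogroup tests.

Per-sample within-cell-line mutation counts are converted to Kimura
two-parameter genetic distances per chromosome,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions per callable site.
The relative Y somatic mutation rate is R = d_Y / d_X; dividing by the X
distance cancels sample-level factors (donor age, culture time, coverage)
that affect both chromosomes, leaving a Y-specific rate proxy. R is compared
across haplogroups with a Kruskal-Wallis rank-sum test, and the spread is
summarized as the percent difference between the highest and lowest
haplogroup medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detection import PYRIMIDINE_CLASSES
from .variant_io import RegionSet

__all__ = [
    "GeneticDistance",
    "SaturationError",
    "k2p_distance",
    "relative_somatic_rate",
    "HaplogroupRateTest",
    "haplogroup_rate_test",
    "median_spread",
    "mutation_spectrum",
    "spectrum_similarity",
]


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions beyond saturation."""


@dataclass
class GeneticDistance:
    chrom: str
    n_transitions: int
    n_transversions: int
    length: int
    p: float
    q: float
    d: float


def k2p_distance(n_ts: int, n_tv: int, length: int, chrom: str = "") -> GeneticDistance:
    """Kimura two-parameter distance from transition/transversion counts.

    Raises :class:`SaturationError` when ``1 - 2P - Q <= 0`` or
    ``1 - 2Q <= 0``.
    """
    if length <= 0:
        raise ValueError("callable length must be positive")
    p = n_ts / length
    q = n_tv / length
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0 or a2 <= 0:
        raise SaturationError(
            f"K2P saturated (P={p:.4g}, Q={q:.4g}); distance undefined"
        )
    d = -0.5 * np.log(a1 * np.sqrt(a2)) + 0.0  # +0.0 avoids -0.0
    return GeneticDistance(chrom, int(n_ts), int(n_tv), int(length), p, q, float(d))


def relative_somatic_rate(
    wcl: pd.DataFrame,
    callable_y: RegionSet,
    callable_x: RegionSet,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample relative Y somatic mutation rate R = d_Y / d_X.

    Samples with d_X = 0 are flagged invalid (``valid=False``, R = NaN) and
    are excluded from downstream tests; the exclusion count is available as
    ``(~result.valid).sum()``.
    """
    l_y, l_x = callable_y.total_length, callable_x.total_length
    hap = sample_sheet.set_index("sample_id")["haplogroup"]
    counts = (
        wcl.groupby(["sample_id", "chrom"])["is_transition"]
        .agg(n_ts="sum", n="count")
        .reset_index()
    ) if len(wcl) else pd.DataFrame(columns=["sample_id", "chrom", "n_ts", "n"])
    rows = []
    for sid in sample_sheet["sample_id"]:
        rec = {"sample_id": sid, "haplogroup": hap.get(sid)}
        for chrom, length in (("Y", l_y), ("X", l_x)):
            sub = counts[(counts["sample_id"] == sid) & (counts["chrom"] == chrom)]
            n_ts = int(sub["n_ts"].iloc[0]) if len(sub) else 0
            n_tv = int(sub["n"].iloc[0] - sub["n_ts"].iloc[0]) if len(sub) else 0
            rec[f"d_{chrom}"] = k2p_distance(n_ts, n_tv, length, chrom).d
        rec["valid"] = rec["d_X"] > 0
        rec["R"] = rec["d_Y"] / rec["d_X"] if rec["valid"] else np.nan
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["sample_id", "haplogroup", "d_Y", "d_X", "R", "valid"]]


@dataclass
class HaplogroupRateTest:
    statistic: float
    p_value: float
    df: int
    medians: pd.Series
    group_sizes: pd.Series
    excluded_haplogroups: list[str]

    def summary(self) -> str:
        lines = [
            "Kruskal-Wallis test of R across haplogroups",
            f"  H = {self.statistic:.4f}  df = {self.df}  P = {self.p_value:.3e}",
            "  per-haplogroup medians:",
        ]
        for h, m in self.medians.items():
            lines.append(f"    {h}: median R = {m:.4f} (n = {self.group_sizes[h]})")
        return "\n".join(lines)


def haplogroup_rate_test(
    rates: pd.DataFrame, min_samples: int = 11, exclude: tuple[str, ...] = ("OUT",)
) -> HaplogroupRateTest:
    """Kruskal-Wallis rank-sum test of R across haplogroups.

    Haplogroups with fewer than ``min_samples`` valid samples (default: more
    than ten required) are excluded and listed in the result. H is computed
    on midranks with the standard tie correction; P comes from the
    chi-square distribution with k-1 degrees of freedom.
    """
    valid = rates[rates["valid"] & ~rates["haplogroup"].isin(exclude)]
    sizes = valid.groupby("haplogroup")["R"].count()
    eligible = sizes[sizes >= min_samples].index
    excluded = sorted(set(sizes.index) - set(eligible))
    groups = [valid.loc[valid["haplogroup"] == h, "R"].to_numpy() for h in eligible]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >=2 eligible haplogroups")
    if all(np.all(g == groups[0][0]) for g in groups):
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = stats.kruskal(*groups)
    medians = valid[valid["haplogroup"].isin(eligible)].groupby("haplogroup")["R"].median()
    return HaplogroupRateTest(
        float(h_stat), float(p), len(groups) - 1, medians,
        sizes[eligible], excluded,
    )


def median_spread(medians: pd.Series | np.ndarray) -> float:
    """Percent difference between the highest and lowest haplogroup median.

    ``100 * (max - min) / min``; raises if the minimum is not positive.
    """
    m = np.asarray(medians, dtype=float)
    if len(m) < 2:
        raise ValueError("need medians from >=2 haplogroups")
    lo, hi = m.min(), m.max()
    if lo <= 0:
        raise ValueError("median spread undefined: minimum median <= 0")
    return float(100.0 * (hi - lo) / lo)


def mutation_spectrum(mutations: pd.DataFrame) -> pd.Series:
    """Six-class pyrimidine-strand mutation spectrum (proportions sum to 1)."""
    if mutations.empty:
        raise ValueError("spectrum undefined for empty mutation table")
    counts = mutations["mut_class"].value_counts()
    vec = pd.Series(0.0, index=list(PYRIMIDINE_CLASSES))
    vec.update(counts / counts.sum())
    return vec


def spectrum_similarity(a: pd.Series, b: pd.Series) -> float:
    """Cosine similarity between two spectra (in [0, 1] for proportions)."""
    av = a.reindex(PYRIMIDINE_CLASSES).fillna(0.0).to_numpy()
    bv = b.reindex(PYRIMIDINE_CLASSES).fillna(0.0).to_numpy()
    denom = np.linalg.norm(av) * np.linalg.norm(bv)
    if denom == 0:
        raise ValueError("spectrum similarity undefined for zero vectors")
    return float(av @ bv / denom)


def spectrum_homogeneity_test(counts_a: pd.Series, counts_b: pd.Series):
    """Chi-square homogeneity test on 6-class mutation counts.

    Classes empty in both spectra are dropped. Returns (statistic, p).
    """
    tab = pd.DataFrame({
        "a": counts_a.reindex(PYRIMIDINE_CLASSES).fillna(0),
        "b": counts_b.reindex(PYRIMIDINE_CLASSES).fillna(0),
    })
    tab = tab[tab.sum(axis=1) > 0]
    stat, p, _, _ = stats.chi2_contingency(tab.to_numpy().T)
    return float(stat), float(p)
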