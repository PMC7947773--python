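"""Within-cell-line mutation detection.

A within-cell-line mutation is a site that is polymorphic inside a single
cell line on the male non-pseudoautosomal X or Y: both reference and
alternative reads present. Because these chromosomes are haploid in males, a
true germline allele is fixed (allele fraction ~1), so partial allele
fractions indicate a somatic or in-vitro mutation carried by a subset of
cells.

The core read-support rule requires at least ``min_alt_reads`` (default 3)
reads supporting the alternative allele; additional filters (minimum depth,
allele-fraction window, callable/mask regions, and a cross-sample recurrence
filter that removes mapping artifacts recurrently "polymorphic" in many
samples) control false positives. Every rejection is assigned an enumerated
reason and returned in a reject log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import RegionSet

__all__ = [
    "DetectionConfig",
    "classify_site",
    "detect_wcl",
    "mutation_class",
    "PYRIMIDINE_CLASSES",
]

PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITIONS = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}

REJECT_REASONS = (
    "no_coverage",
    "not_callable",
    "masked",
    "min_depth",
    "min_alt_reads",
    "af_min",
    "af_max",
    "recurrent_artifact",
)


@dataclass
class DetectionConfig:
    """Thresholds for within-cell-line mutation calling.

    ``af_max`` below 1 separates partial-cell-fraction somatic alleles from
    fixed germline alleles on haploid chromosomes; ``recurrence_max_fraction``
    removes sites called in implausibly many independent cell lines.
    """

    min_alt_reads: int = 3
    min_depth: int = 6
    af_min: float = 0.05
    af_max: float = 0.8
    recurrence_max_fraction: float = 0.02
    masks: list[RegionSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.af_min < self.af_max < 1:
            raise ValueError("need 0 < af_min < af_max < 1")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be >= 1")


def mutation_class(ref: str, alt: str) -> tuple[str, bool]:
    """Collapse a substitution to the pyrimidine strand; returns (class, is_transition)."""
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}", (ref, alt) in _TRANSITIONS


def _mask_hits(cfg: DetectionConfig, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
    hit = np.zeros(len(pos0), dtype=bool)
    for mask in cfg.masks:
        sel = chrom == mask.chrom
        if sel.any():
            hit[sel] |= mask.contains(pos0[sel])
    return hit


def _classify_frame(
    calls: pd.DataFrame,
    cfg: DetectionConfig,
    callable_regions: dict[str, RegionSet],
) -> pd.Series:
    """Vectorized reject reason per call ('' = accepted)."""
    n = len(calls)
    reason = np.full(n, "", dtype=object)
    chrom = calls["chrom"].to_numpy()
    pos0 = calls["pos"].to_numpy() - 1
    depth = calls["depth"].to_numpy()
    alt = calls["alt_reads"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)

    inside = np.zeros(n, dtype=bool)
    for c, rs in callable_regions.items():
        sel = chrom == c
        if sel.any():
            inside[sel] = rs.contains(pos0[sel])
    masked = _mask_hits(cfg, chrom, pos0)

    # later assignments win: order from weakest to strongest precedence
    reason[af > cfg.af_max] = "af_max"
    reason[af < cfg.af_min] = "af_min"
    reason[alt < cfg.min_alt_reads] = "min_alt_reads"
    reason[depth < cfg.min_depth] = "min_depth"
    reason[masked] = "masked"
    reason[~inside] = "not_callable"
    reason[depth == 0] = "no_coverage"
    return pd.Series(reason, index=calls.index)


def classify_site(
    call, cfg: DetectionConfig, callable_regions: dict[str, RegionSet] | RegionSet
):
    """Classify a single variant call; returns ``(accepted, reason)``.

    ``reason`` is ``None`` when accepted. A zero-depth record is rejected
    with ``no_coverage``, never an exception.
    """
    if isinstance(callable_regions, RegionSet):
        callable_regions = {callable_regions.chrom: callable_regions}
    df = pd.DataFrame([{
        "chrom": call["chrom"], "pos": call["pos"], "depth": call["depth"],
        "alt_reads": call["alt_reads"],
    }])
    reason = _classify_frame(df, cfg, callable_regions).iloc[0]
    return (reason == "", reason or None)


def detect_wcl(
    calls: pd.DataFrame,
    cfg: DetectionConfig,
    callable_regions: dict[str, RegionSet] | RegionSet,
    n_cohort_samples: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect within-cell-line mutations across a cohort.

    Applies the per-site filters, annotates the six pyrimidine-strand
    mutation classes, then removes any site accepted in more than
    ``recurrence_max_fraction`` of cohort samples (from every sample,
    flagged ``recurrent_artifact``).

    Returns
    -------
    wcl : DataFrame
        Accepted mutations: sample_id, chrom, pos, ref, alt, alt_reads,
        depth, allele_fraction, mut_class, is_transition.
    rejects : DataFrame
        sample_id, chrom, pos, reason for every rejected call.
    """
    if isinstance(callable_regions, RegionSet):
        callable_regions = {callable_regions.chrom: callable_regions}
    if calls.empty:
        empty = pd.DataFrame(columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "alt_reads", "depth",
            "allele_fraction", "mut_class", "is_transition",
        ])
        return empty, pd.DataFrame(columns=["sample_id", "chrom", "pos", "reason"])

    reason = _classify_frame(calls, cfg, callable_regions)
    accepted = calls[reason == ""].copy()
    rejects = calls.loc[reason != "", ["sample_id", "chrom", "pos"]].copy()
    rejects["reason"] = reason[reason != ""]

    if n_cohort_samples is None:
        n_cohort_samples = calls["sample_id"].nunique()
    if len(accepted):
        per_site = accepted.groupby(["chrom", "pos"])["sample_id"].nunique()
        # a site private to one sample cannot be "recurrent", whatever the
        # cohort size; the fraction rule applies on top of >=2 carriers
        recurrent = per_site[
            (per_site >= 2)
            & (per_site / n_cohort_samples > cfg.recurrence_max_fraction)
        ]
        if len(recurrent):
            key = pd.MultiIndex.from_frame(accepted[["chrom", "pos"]])
            is_rec = key.isin(recurrent.index)
            rec_rows = accepted[is_rec]
            rej_extra = rec_rows[["sample_id", "chrom", "pos"]].copy()
            rej_extra["reason"] = "recurrent_artifact"
            rejects = pd.concat([rejects, rej_extra], ignore_index=True)
            accepted = accepted[~is_rec]

    cls = [mutation_class(r, a) for r, a in zip(accepted["ref"], accepted["alt"])]
    accepted["allele_fraction"] = accepted["alt_reads"] / accepted["depth"]
    accepted["mut_class"] = [c[0] for c in cls] if cls else []
    accepted["is_transition"] = [c[1] for c in cls] if cls else []
    wcl = accepted[[
        "sample_id", "chrom", "pos", "ref", "alt", "alt_reads", "depth",
        "allele_fraction", "mut_class", "is_transition",
    ]].reset_index(drop=True)
    return wcl, rejects.reset_index(drop=True)
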