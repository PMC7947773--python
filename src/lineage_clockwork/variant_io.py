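"""Reading and writing the pipeline's file formats.

All internal coordinates are 0-based half-open; the conversion to and from
VCF's 1-based positions happens only here, at the I/O boundary. Chromosome
names are normalized to ``{X, Y}`` on read (accepting the ``chrX``/``chrY``
dialect). Only single-nucleotide variants enter the pipeline; indels and MNVs
are counted and dropped. Gzipped inputs are accepted everywhere.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads", "depth",
]

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for malformed input files (with file/record context)."""


def normalize_chrom(name: str) -> str:
    name = name[3:] if name.lower().startswith("chr") else name
    return name.upper()


# ---------------------------------------------------------------------------
# Regions (BED)
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Sorted, merged 0-based half-open intervals on one chromosome."""

    chrom: str
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @classmethod
    def from_intervals(cls, chrom: str, intervals) -> "RegionSet":
        ivals = sorted((int(s), int(e)) for s, e in intervals)
        merged: list[list[int]] = []
        for s, e in ivals:
            if s >= e:
                raise FormatError(f"interval start {s} >= end {e}")
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged], dtype=np.int64)
        ends = np.array([m[1] for m in merged], dtype=np.int64)
        return cls(normalize_chrom(chrom), starts, ends)

    @property
    def total_length(self) -> int:
        return int((self.ends - self.starts).sum())

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    def contains(self, pos0) -> np.ndarray:
        """Membership of 0-based positions."""
        pos0 = np.atleast_1d(np.asarray(pos0, dtype=np.int64))
        if len(self.starts) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(self.starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos0.shape, dtype=bool)
        out[ok] = pos0[ok] < self.ends[idx[ok]]
        return out


def read_regions(path) -> dict[str, RegionSet]:
    """Read a BED3 file into one merged :class:`RegionSet` per chromosome."""
    opener = gzip.open if str(path).endswith(".gz") else open
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = normalize_chrom(parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            per_chrom.setdefault(chrom, []).append((start, end))
    return {c: RegionSet.from_intervals(c, iv) for c, iv in per_chrom.items()}


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for s, e in regions.intervals:
            fh.write(f"{regions.chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variant_calls(path, sample_sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read per-allele read depths from a VCF with DP and AD FORMAT fields.

    One row is emitted per biallelic SNV genotype with AD present;
    multiallelic records are split into one row per alternative allele;
    indels/MNVs are skipped with a logged count. Samples absent from
    ``sample_sheet`` (when given) raise :class:`FormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_sheet is not None:
        known = set(sample_sheet["sample_id"])
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise FormatError(f"{path}: samples not in sample sheet: {unknown}")
    rows: list[tuple] = []
    n_indel = 0
    for rec in vcf:
        chrom = normalize_chrom(rec.CHROM)
        ref = rec.REF.upper()
        alts = [a.upper() for a in (rec.ALT or [])]
        snv_alts = [
            (k, a) for k, a in enumerate(alts)
            if len(a) == 1 and len(ref) == 1 and a in _VALID_BASES
        ]
        if len(ref) != 1 or (alts and not snv_alts):
            n_indel += 1
            continue
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} {ref}>{','.join(alts)}: missing AD"
            )
        ad = np.asarray(ad)
        if ad.ndim != 2 or ad.shape[1] != 1 + len(alts):
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS}: AD has wrong arity "
                f"(expected {1 + len(alts)} values per sample)"
            )
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        for si, sample in enumerate(samples):
            sample_ad = ad[si]
            if (sample_ad < 0).all():  # missing genotype in this sample
                continue
            ref_reads = max(int(sample_ad[0]), 0)
            for k, alt in snv_alts:
                alt_reads = max(int(sample_ad[1 + k]), 0)
                depth = (
                    int(dp[si][0]) if dp is not None and int(dp[si][0]) >= 0
                    else ref_reads + alt_reads
                )
                if depth < ref_reads + alt_reads:
                    raise FormatError(
                        f"{path}: record {rec.CHROM}:{rec.POS} sample {sample}: "
                        f"DP {depth} < AD sum {ref_reads + alt_reads}"
                    )
                rows.append((sample, chrom, rec.POS, ref, alt, ref_reads, alt_reads, depth))
        if len(alts) > 1 and len(snv_alts) < len(alts):
            n_indel += 1  # mixed records: non-SNV alleles dropped
    if n_indel:
        logger.info("%s: skipped %d non-SNV records/alleles", path, n_indel)
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.astype({"pos": np.int64, "ref_reads": np.int64,
                      "alt_reads": np.int64, "depth": np.int64})


def write_vcf(
    calls: pd.DataFrame,
    path,
    sample_id: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write one sample's variant calls to a minimal VCF 4.2 with DP and AD."""
    sub = calls[calls["sample_id"] == sample_id].sort_values(["chrom", "pos"])
    contig_lengths = contig_lengths or {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(sub["chrom"].unique()):
            ln = contig_lengths.get(chrom)
            if ln:
                fh.write(f"##contig=<ID={chrom},length={ln}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for row in sub.itertuples():
            gt = "1" if row.alt_reads >= row.ref_reads else "0"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"GT:DP:AD\t{gt}:{row.depth}:{row.ref_reads},{row.alt_reads}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "haplogroup", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df[["sample_id", "haplogroup", "batch"]].to_csv(path, sep="\t", index=False)


def read_depth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "sample_id", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: depth table missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def write_depth_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
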