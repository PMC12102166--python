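"""Readers and writers for the tabular formats the pipeline exchanges.

Conventions: mutations are 1-based (VCF), intervals 0-based half-open
(BED); TSV files are tab-separated with a header row. The minimal VCF
dialect uses only CHROM/POS/REF/ALT plus the first sample's AD/DP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import SBS96_LABELS, SignatureSet

log = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "RunConfig",
    "read_mutations",
    "write_mutations",
    "read_signature_matrix",
    "read_bed",
    "write_bed",
    "read_expression",
    "read_gmt",
]

LESION_TYPES = ("primary", "hepatic_met", "lymph_met", "peritoneal_met", "control")

MUTATION_COLUMNS = ("chrom", "pos", "ref", "alt", "depth", "alt_count")


@dataclass
class SampleMeta:
    """Per-sample metadata: identity, lesion type, purity."""

    sample_id: str
    patient_id: str
    lesion_type: str
    tcc: float
    mean_coverage: float | None = None

    def __post_init__(self):
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"lesion_type must be one of {LESION_TYPES}")
        if not 0.0 < self.tcc <= 1.0:
            raise ValueError(f"tcc must be in (0, 1], got {self.tcc}")


@dataclass
class RunConfig:
    """Parameters of every pipeline stage; defaults are the published values."""

    clonality_threshold: float = 0.5
    cov_min: int = 20
    cov_max: int = 250
    cluster_min_size: int = 100
    clonality_mode: str = "model_consistent"
    hvg_n: int = 1000
    ica_k: int = 7
    nmf_k: int = 4
    nmf_l1_ratio: float = 0.0
    nmf_alpha: float = 1e-3
    gsea_n_perm: int = 1000
    marker_top_n: int = 10
    marker_min_lfc: float = 2.0
    ase_min_depth: int = 10
    ase_max_other: int = 3
    kataegis_min_snvs: int = 6
    kataegis_max_mean_imd: float = 1000.0
    seed: int = 0

    def log_parameters(self, stage: str) -> None:
        log.info("%s parameters: %s", stage, self.__dict__)


def _error(path, line_no, msg):
    raise ValueError(f"{path}, line {line_no}: {msg}")


def read_mutations(path, format: str | None = None) -> pd.DataFrame:
    """Read somatic mutations from a TSV or minimal VCF.

    TSV needs a header with chrom, pos, ref, alt, depth, alt_count
    (extra columns pass through); VCF needs per-sample AD and DP, and the
    first sample is used. Output is sorted by (chrom, pos) with a ``vaf``
    column (alt_count/depth; NaN and flagged where depth is 0).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz") else "tsv"
    if format == "vcf":
        df = _read_vcf(path)
    elif format == "tsv":
        df = _read_mutation_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(df) == 0:
        log.warning("no mutations in %s", path)
        return df
    zero = df["depth"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["vaf"] = np.where(zero, np.nan, df["alt_count"] / df["depth"].replace(0, 1))
    df["zero_depth"] = zero
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _read_mutation_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("pos", "depth", "alt_count"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            _error(path, int(bad.idxmax()) + 2, f"non-numeric value in column {col!r}")
        if converted.isna().any():
            _error(path, int(converted.isna().idxmax()) + 2, f"missing value in column {col!r}")
        df[col] = converted.astype(np.int64)
    if (df["alt_count"] > df["depth"]).any():
        _error(path, int((df["alt_count"] > df["depth"]).idxmax()) + 2,
               "alt_count exceeds depth")
    return df


def _read_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional dependency, VCF input only

    rows = []
    for v in VCF(str(path)):
        ad = v.format("AD")
        dp = v.format("DP")
        if ad is None or dp is None:
            raise ValueError(f"{path}: record {v.CHROM}:{v.POS} lacks AD/DP")
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "depth": int(dp[0][0]) if np.ndim(dp) > 1 else int(dp[0]),
                "alt_count": int(ad[0][1]),
            }
        )
    return pd.DataFrame(rows, columns=list(MUTATION_COLUMNS))


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path, cutoff_path=None) -> SignatureSet:
    """Read a COSMIC-layout signature TSV (96 context rows x K columns).

    Rows may be in any order if labeled (first column, e.g. ``A[C>A]A``);
    they are reordered to the canonical channel order. Columns are
    renormalized (with a warning) if they do not sum to 1 within 1e-6.
    ``cutoff_path`` is an optional two-column TSV signature -> cutoff.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"{path}: expected 96 rows, found {df.shape[0]}")
    if set(df.index) != set(SBS96_LABELS):
        raise ValueError(f"{path}: row labels are not the 96 canonical channels")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative signature entries")
    cutoffs = None
    if cutoff_path is not None:
        cut = pd.read_csv(cutoff_path, sep="\t", index_col=0).iloc[:, 0]
        cutoffs = cut.reindex(df.columns).fillna(0.0)
    return SignatureSet(matrix=df.reindex(list(SBS96_LABELS)), cutoffs=cutoffs)


def write_signature_matrix(sigset: SignatureSet, path) -> None:
    sigset.matrix.to_csv(path, sep="\t", index_label="Type")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into per-chromosome sorted interval lists (0-based half-open)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _error(path, line_no, "fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                _error(path, line_no, f"start {start} >= end {end}")
            intervals.setdefault(chrom, []).append((start, end))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


def write_bed(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicated gene labels, e.g. {dupes}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (set name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                _error(path, line_no, "GMT line needs name, description, >=1 gene")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
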