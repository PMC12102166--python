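"""Allele-specific expression filtering and loss-of-imprinting calls.

Imprinted genes such as IGF2 are normally expressed from a single parental
allele, so RNA-seq reads over heterozygous SNPs should be strongly skewed
toward one allele. Loss of imprinting (LOI) re-activates the silenced
allele and pulls the major-allele ratio toward 0.5. Site-level read
counts (refCount / altCount / otherBases per het SNP) are quality-filtered
and aggregated per gene by averaging the major-allele expression ratio
counts_allele / counts_total across sites; the gene-level ratio is then
thresholded into monoallelic / biallelic / indeterminate calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["GeneASE", "filter_sites", "gene_ratio", "call_loi"]

SITE_COLUMNS = ("gene", "refCount", "altCount", "otherBases")


@dataclass
class GeneASE:
    """Aggregated allele-specific expression of one gene."""

    gene: str
    n_sites_used: int
    major_ratio: float  # mean over sites of max(ref, alt)/(ref+alt+other)
    call: str = "indeterminate"


def filter_sites(
    sites: pd.DataFrame,
    min_depth: int = 10,
    max_other: int = 3,
    other_vs_alleles: str = "and",
    hla_genes: Iterable[str] | None = None,
    coverage_band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Quality filters for ASE site counts.

    A site survives iff all of:

    * depth (ref + alt + other) >= ``min_depth``
    * otherBases <= ``max_other``
    * otherBases does not exceed the allelic counts — with
      ``other_vs_alleles='and'`` a site is removed only when otherBases
      exceeds *both* refCount and altCount; with ``'or'`` exceeding either
      removes it
    * gene not in ``hla_genes`` (HLA loci misalign and fake allelic skew)
    * if ``coverage_band=(mean, fold)`` is given, depth within
      [mean/fold, mean*fold] (het-SNP preselection near average coverage)
    """
    if other_vs_alleles not in ("and", "or"):
        raise ValueError(f"other_vs_alleles must be 'and' or 'or', got {other_vs_alleles!r}")
    ref = sites["refCount"].to_numpy(dtype=float)
    alt = sites["altCount"].to_numpy(dtype=float)
    other = sites["otherBases"].to_numpy(dtype=float)
    depth = ref + alt + other

    keep = (depth >= min_depth) & (other <= max_other)
    if other_vs_alleles == "and":
        keep &= ~((other > ref) & (other > alt))
    else:
        keep &= ~((other > ref) | (other > alt))
    if hla_genes is not None:
        hla = set(hla_genes)
        keep &= ~sites["gene"].isin(hla).to_numpy()
    if coverage_band is not None:
        mean, fold = coverage_band
        keep &= (depth >= mean / fold) & (depth <= mean * fold)
    return sites[keep].copy()


def gene_ratio(sites: pd.DataFrame) -> pd.DataFrame:
    """Aggregate filtered sites to per-gene major-allele ratios.

    Per site the ratio is max(refCount, altCount) / (refCount + altCount +
    otherBases); the gene value is the arithmetic mean over its sites.
    Returns a frame with columns gene, n_sites_used, major_ratio.
    """
    if len(sites) == 0:
        return pd.DataFrame(columns=["gene", "n_sites_used", "major_ratio"])
    ref = sites["refCount"].to_numpy(dtype=float)
    alt = sites["altCount"].to_numpy(dtype=float)
    other = sites["otherBases"].to_numpy(dtype=float)
    total = ref + alt + other
    if (total <= 0).any():
        raise ValueError("site with zero total count")
    ratio = np.maximum(ref, alt) / total
    df = pd.DataFrame({"gene": sites["gene"].to_numpy(), "ratio": ratio})
    agg = (
        df.groupby("gene", sort=True)["ratio"]
        .agg(n_sites_used="size", major_ratio="mean")
        .reset_index()
    )
    agg["n_sites_used"] = agg["n_sites_used"].astype(int)
    return agg


def call_loi(
    gene_ase: pd.DataFrame,
    biallelic_max: float = 0.65,
    monoallelic_min: float = 0.85,
) -> pd.DataFrame:
    """Threshold per-gene major ratios into imprinting-status calls.

    ``biallelic`` (major ratio <= biallelic_max) supports LOI for an
    imprinted gene; ``monoallelic`` (>= monoallelic_min) supports intact
    imprinting; ratios in between are ``indeterminate``. Both bounds are
    explicit configuration, echoed in the output for provenance.
    """
    if not 0.5 <= biallelic_max < monoallelic_min <= 1.0:
        raise ValueError("require 0.5 <= biallelic_max < monoallelic_min <= 1")
    out = gene_ase.copy()
    r = out["major_ratio"].to_numpy(dtype=float)
    out["call"] = np.where(
        r <= biallelic_max, "biallelic", np.where(r >= monoallelic_min, "monoallelic", "indeterminate")
    )
    out.loc[out["n_sites_used"] < 1, "call"] = "indeterminate"
    out.attrs["biallelic_max"] = biallelic_max
    out.attrs["monoallelic_min"] = monoallelic_min
    return out
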