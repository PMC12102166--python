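"""Mutation copy number and paired-lesion clonality classification.

Bulk tumor sequencing mixes tumor and normal cells. For a somatic SNV the
variant allele fraction (VAF) observed in reads depends on the number of
mutated allele copies per tumor cell (m), the local total copy number (CN)
of the tumor cells, and the tumor cell content (tcc, purity) of the sample:

    E[VAF] = m * tcc / (CN * tcc + 2 * (1 - tcc))

Inverting this relation yields the mutation copy number, the estimated
number of mutated alleles per tumor cell. Two variants of the correction
are provided (see :func:`mutated_alleles`). Given a primary/metastasis
sample pair, thresholding the mutation copy number in each sample splits
mutations into shared and lesion-specific clone clusters, which can then be
dated by refitting mutational signatures per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "mutated_alleles",
    "expected_vaf",
    "classify_pair",
    "extract_clusters",
    "annotate_copy_number",
    "PairClassification",
    "LABELS",
]

#: classification labels, exhaustive and mutually exclusive
LABELS = (
    "shared",
    "primary_specific",
    "metastasis_specific",
    "subthreshold",
    "coverage_filtered",
)


def mutated_alleles(vaf, cn, tcc, mode: str = "model_consistent"):
    """Predicted number of mutated alleles per tumor cell.

    Parameters
    ----------
    vaf : float or array
        Variant allele fraction in [0, 1].
    cn : float or array
        Local total copy number of the tumor (>= 0).
    tcc : float
        Tumor cell content (purity), in (0, 1].
    mode : {"model_consistent", "printed"}
        ``model_consistent`` returns ``vaf * (cn*tcc + 2*(1-tcc)) / tcc``,
        the exact algebraic inverse of the expected-VAF mixing model.
        ``printed`` returns ``vaf * (cn*tcc) / (cn*tcc + 2*(1-tcc)) * cn``,
        the literal published form of the correction. The two agree at
        tcc = 1 for cn = 2 and differ otherwise; ``model_consistent`` is
        the default because it reproduces the mutation-copy-number concept
        (a clonal heterozygous mutation maps to 1.0 at any purity).

    Returns
    -------
    float or ndarray
        Real-valued mutated-allele count (not rounded).
    """
    vaf = np.asarray(vaf, dtype=float)
    cn = np.asarray(cn, dtype=float)
    tcc = float(tcc)
    if not 0.0 < tcc <= 1.0:
        raise ValueError(f"tcc must be in (0, 1], got {tcc}")
    if np.any(vaf < 0) or np.any(vaf > 1):
        raise ValueError("vaf must lie in [0, 1]")
    if np.any(cn < 0):
        raise ValueError("cn must be >= 0")
    denom = cn * tcc + 2.0 * (1.0 - tcc)
    if mode == "model_consistent":
        out = vaf * denom / tcc
    elif mode == "printed":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom > 0, vaf * (cn * tcc) / np.where(denom > 0, denom, 1.0) * cn, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out.item() if out.ndim == 0 else out


def expected_vaf(m, cn, tcc):
    """Expected VAF of a mutation present on ``m`` alleles per tumor cell.

    ``E[VAF] = m*tcc / (cn*tcc + 2*(1-tcc))`` — tumor cells contribute
    ``cn`` allele copies (``m`` of them mutated) at proportion ``tcc``,
    admixed normal cells contribute 2 unmutated copies.
    """
    m = np.asarray(m, dtype=float)
    cn = np.asarray(cn, dtype=float)
    tcc = float(tcc)
    if not 0.0 < tcc <= 1.0:
        raise ValueError(f"tcc must be in (0, 1], got {tcc}")
    if np.any(m < 0) or np.any(m > cn):
        raise ValueError("require 0 <= m <= cn")
    out = m * tcc / (cn * tcc + 2.0 * (1.0 - tcc))
    return out.item() if out.ndim == 0 else out


@dataclass
class PairClassification:
    """Per-mutation mutated-allele counts and labels for a sample pair."""

    table: pd.DataFrame  # columns: m_primary, m_metastasis, label (+ inputs)
    threshold: float = 0.5
    cov_min: int = 20
    cov_max: int = 250
    mode: str = "model_consistent"

    def counts(self) -> pd.Series:
        """Number of mutations per label (all five labels present)."""
        return self.table["label"].value_counts().reindex(LABELS, fill_value=0)


def classify_pair(
    pair: pd.DataFrame,
    tcc_primary: float,
    tcc_metastasis: float,
    threshold: float = 0.5,
    cov_min: int = 20,
    cov_max: int = 250,
    mode: str = "model_consistent",
) -> PairClassification:
    """Split merged-pileup mutations of a sample pair into clone labels.

    ``pair`` holds one row per mutation with per-sample read support from a
    merged pileup (both samples evaluated at every position):
    ``depth_primary``, ``alt_primary``, ``cn_primary``, ``depth_metastasis``,
    ``alt_metastasis``, ``cn_metastasis`` (any extra columns pass through).

    Rules, applied in order:

    1. Coverage filter: a mutation is ``coverage_filtered`` unless
       ``cov_min <= depth <= cov_max`` in *both* samples (inclusive).
    2. Mutated alleles m computed per sample from VAF, CN, tcc; sites on
       CN=0 segments get m = 0 (undefined dilution).
    3. ``shared`` if m >= threshold in both samples; ``primary_specific`` /
       ``metastasis_specific`` if only in one; ``subthreshold`` otherwise.
       Ties at exactly the threshold count as >=.
    """
    required = [
        "depth_primary", "alt_primary", "cn_primary",
        "depth_metastasis", "alt_metastasis", "cn_metastasis",
    ]
    missing = [c for c in required if c not in pair.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    for name, tcc in (("tcc_primary", tcc_primary), ("tcc_metastasis", tcc_metastasis)):
        if tcc is None or not 0.0 < float(tcc) <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {tcc}")

    out = pair.copy()
    m = {}
    for side, tcc in (("primary", tcc_primary), ("metastasis", tcc_metastasis)):
        depth = out[f"depth_{side}"].to_numpy(dtype=float)
        alt = out[f"alt_{side}"].to_numpy(dtype=float)
        cn = out[f"cn_{side}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(depth > 0, alt / np.where(depth > 0, depth, 1.0), 0.0)
        mi = np.asarray(mutated_alleles(vaf, cn, tcc, mode=mode), dtype=float)
        mi = np.where(cn == 0, 0.0, mi)
        m[side] = mi
        out[f"m_{side}"] = mi

    cov_ok = np.ones(len(out), dtype=bool)
    for side in ("primary", "metastasis"):
        depth = out[f"depth_{side}"].to_numpy(dtype=float)
        cov_ok &= (depth >= cov_min) & (depth <= cov_max)

    above_p = m["primary"] >= threshold
    above_m = m["metastasis"] >= threshold
    label = np.where(
        above_p & above_m, "shared",
        np.where(above_p, "primary_specific",
                 np.where(above_m, "metastasis_specific", "subthreshold")),
    )
    label = np.where(cov_ok, label, "coverage_filtered")
    out["label"] = pd.Categorical(label, categories=list(LABELS))
    return PairClassification(
        table=out, threshold=threshold, cov_min=cov_min, cov_max=cov_max, mode=mode
    )


def extract_clusters(
    classification: PairClassification, min_size: int = 100
) -> dict[str, pd.DataFrame]:
    """Clone clusters passing the minimum-size filter.

    Only the three clone labels (shared / primary_specific /
    metastasis_specific) form clusters; subthreshold and coverage-filtered
    mutations never do. Clusters smaller than ``min_size`` are dropped to
    avoid noisy signature deconvolution; counts for all labels remain
    available via ``classification.counts()``.
    """
    clusters: dict[str, pd.DataFrame] = {}
    for lab in ("shared", "primary_specific", "metastasis_specific"):
        sub = classification.table[classification.table["label"] == lab]
        if len(sub) >= min_size:
            clusters[lab] = sub.copy()
    return clusters


def annotate_copy_number(
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    column: str = "cn",
    default: float = np.nan,
) -> pd.DataFrame:
    """Attach the total copy number of the overlapping segment to each mutation.

    ``segments`` is BED-like: columns chrom, start (0-based), end
    (half-open), cn. Mutation positions are 1-based; position p overlaps
    [start, end) iff start < p <= end. Mutations in no segment get
    ``default``.
    """
    out = mutations.copy()
    cn = np.full(len(out), default, dtype=float)
    for chrom, seg in segments.groupby("chrom"):
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy(dtype=np.int64)
        ends = seg["end"].to_numpy(dtype=np.int64)
        vals = seg["cn"].to_numpy(dtype=float)
        mask = (out["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos0 = out.loc[mask, "pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        idx = np.searchsorted(starts, pos0, side="right") - 1
        hit = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        vals_out = np.where(hit, vals[np.clip(idx, 0, len(vals) - 1)], default)
        cn[mask] = vals_out
    out[column] = cn
    return out
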