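"""SBS-96 mutational catalogs and signature refitting.

Single-base substitutions are classified into 96 channels: 6
pyrimidine-centered substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases. Mutations
reported on the purine strand are reverse-complemented first. A sample's
(or clone cluster's) catalog — the 96-vector of channel counts — is then
expressed as a non-negative combination of fixed reference signatures by
non-negative least squares (refitting; no de-novo extraction). Signatures
whose normalized exposure falls below a per-signature cutoff are removed
and the remainder refitted, iterating to convergence, which suppresses
spurious low-level attributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "SBS96_LABELS",
    "sbs96_channel",
    "MutationalCatalog",
    "SignatureSet",
    "ExposureResult",
    "build_catalog",
    "fit_exposures",
    "apply_cutoffs",
    "compare_cluster_exposures",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: canonical COSMIC channel order: A[C>A]A, A[C>A]C, ..., T[T>G]T
SBS96_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def sbs96_channel(ref: str, alt: str, triplet: str) -> int:
    """Channel index (0–95) of an SNV given its reference trinucleotide.

    ``triplet`` is the reference sequence at positions pos-1..pos+1; its
    middle base must equal ``ref``. Purine-strand mutations are
    reverse-complemented into the pyrimidine-centered convention.
    """
    ref, alt, triplet = ref.upper(), alt.upper(), triplet.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(triplet) != 3 or triplet[1] != ref:
        raise ValueError(f"triplet {triplet!r} does not center on ref base {ref!r}")
    if ref in "GA":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
        triplet = triplet.translate(_COMPLEMENT)[::-1]
    return _LABEL_INDEX[f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"]


@dataclass
class MutationalCatalog:
    """96-channel SNV counts for one entity (sample or clone cluster)."""

    entity_id: str
    counts: pd.Series  # indexed by SBS96_LABELS, non-negative ints

    def __post_init__(self):
        counts = self.counts.reindex(list(SBS96_LABELS))
        if counts.isna().any():
            raise ValueError("catalog must cover all 96 channels")
        if (counts < 0).any():
            raise ValueError("catalog counts must be non-negative")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SignatureSet:
    """Fixed reference signatures: 96 x K probability matrix plus cutoffs.

    Each column sums to 1. ``cutoffs`` are minimal normalized-exposure
    fractions per signature (0 = no cutoff), applied by
    :func:`apply_cutoffs`.
    """

    matrix: pd.DataFrame  # 96 x K, rows in canonical order
    cutoffs: pd.Series | None = None

    def __post_init__(self):
        mat = self.matrix
        if set(mat.index) != set(SBS96_LABELS):
            raise ValueError("signature matrix must have the 96 canonical channel rows")
        mat = mat.reindex(list(SBS96_LABELS))
        if (mat.to_numpy() < 0).any():
            raise ValueError("signature matrix entries must be non-negative")
        sums = mat.sum(axis=0)
        if (np.abs(sums - 1.0) > 1e-6).any():
            warnings.warn("signature columns do not sum to 1; renormalizing", stacklevel=2)
            mat = mat / sums
        self.matrix = mat
        if self.cutoffs is None:
            self.cutoffs = pd.Series(0.0, index=mat.columns)
        else:
            self.cutoffs = self.cutoffs.reindex(mat.columns).fillna(0.0)
            if ((self.cutoffs < 0) | (self.cutoffs >= 1)).any():
                raise ValueError("cutoffs must lie in [0, 1)")

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ExposureResult:
    """NNLS signature attribution for one catalog.

    ``raw`` holds mutation counts attributed per signature; ``normalized``
    is raw scaled to sum to 1 (all-zero when nothing is attributed);
    ``residual`` is the Euclidean norm of catalog − S·exposure. The
    catalog is kept so cutoffs can be applied by refitting.
    """

    raw: pd.Series
    normalized: pd.Series
    residual: float
    catalog: MutationalCatalog | None = None


def build_catalog(
    mutations: pd.DataFrame,
    reference=None,
    entity_id: str = "sample",
) -> MutationalCatalog:
    """Count SNVs into the 96 channels.

    Context resolution, in order of preference: a ``context96`` column of
    precomputed channel indices; a ``triplet`` column of reference
    trinucleotides; else ``reference`` (a pyfaidx.Fasta or any mapping of
    chromosome name to sequence) is consulted at pos-1..pos+1. The
    reference base at each site must match the mutation's ref allele.
    Indels (multi-base ref or alt) are skipped; their count is logged.
    """
    is_snv = (mutations["ref"].str.len() == 1) & (mutations["alt"].str.len() == 1)
    n_indel = int((~is_snv).sum())
    if n_indel:
        log.info("build_catalog: skipping %d indels", n_indel)
    snvs = mutations[is_snv]
    counts = np.zeros(96, dtype=np.int64)

    if "context96" in snvs.columns and snvs["context96"].notna().all():
        chans = snvs["context96"].to_numpy(dtype=np.int64)
        if ((chans < 0) | (chans > 95)).any():
            raise ValueError("context96 values must be channel indices 0-95")
        np.add.at(counts, chans, 1)
    else:
        for row in snvs.itertuples(index=False):
            if "triplet" in snvs.columns and isinstance(getattr(row, "triplet", None), str):
                triplet = row.triplet
            elif reference is not None:
                seq = reference[row.chrom]
                triplet = str(seq[row.pos - 2 : row.pos + 1]).upper()
            else:
                raise ValueError(
                    "no context available: provide context96/triplet columns or a reference"
                )
            if triplet[1] != row.ref.upper():
                raise ValueError(
                    f"reference base mismatch at {row.chrom}:{row.pos}: "
                    f"reference has {triplet[1]!r}, mutation ref is {row.ref!r}"
                )
            counts[sbs96_channel(row.ref, row.alt, triplet)] += 1

    return MutationalCatalog(
        entity_id=entity_id, counts=pd.Series(counts, index=list(SBS96_LABELS))
    )


def fit_exposures(catalog: MutationalCatalog, signatures: SignatureSet) -> ExposureResult:
    """Refit a catalog against fixed signatures by non-negative least squares.

    Solves min ||c − S e||_2 subject to e >= 0 (Lawson–Hanson active set,
    deterministic). A zero catalog yields all-zero exposures with a warning.
    """
    c = catalog.counts.to_numpy(dtype=float)
    names = signatures.names
    if catalog.total == 0:
        warnings.warn(f"catalog {catalog.entity_id!r} is empty; zero exposures", stacklevel=2)
        zero = pd.Series(0.0, index=names)
        return ExposureResult(raw=zero, normalized=zero.copy(), residual=0.0, catalog=catalog)
    e, resid = scipy.optimize.nnls(signatures.matrix.to_numpy(), c)
    raw = pd.Series(e, index=names)
    total = raw.sum()
    normalized = raw / total if total > 0 else raw.copy()
    return ExposureResult(raw=raw, normalized=normalized, residual=float(resid), catalog=catalog)


def apply_cutoffs(
    result: ExposureResult,
    signatures: SignatureSet,
    mode: str = "all_at_once",
) -> ExposureResult:
    """Zero out below-cutoff signatures and refit until stable.

    Each round, signatures whose normalized exposure is below their cutoff
    leave the active set and NNLS is re-run on the survivors; iteration
    stops when every surviving normalized exposure meets its cutoff.
    ``mode='all_at_once'`` removes every offender per round;
    ``mode='one_at_a_time'`` removes only the smallest. Removed signatures
    report exposure exactly 0.
    """
    if result.catalog is None:
        raise ValueError("ExposureResult has no catalog; cannot refit")
    if mode not in ("all_at_once", "one_at_a_time"):
        raise ValueError(f"unknown mode {mode!r}")
    names = signatures.names
    cutoffs = signatures.cutoffs
    active = list(names)
    c = result.catalog.counts.to_numpy(dtype=float)

    raw = result.raw.reindex(names).fillna(0.0)
    resid = result.residual
    while True:
        total = raw[active].sum()
        if total <= 0:
            warnings.warn("all signatures removed by cutoffs; zero result", stacklevel=2)
            zero = pd.Series(0.0, index=names)
            return ExposureResult(zero, zero.copy(), float(np.linalg.norm(c)), result.catalog)
        norm_active = raw[active] / total
        below = [n for n in active if norm_active[n] < cutoffs[n]]
        if not below:
            break
        if mode == "one_at_a_time":
            below = [min(below, key=lambda n: norm_active[n])]
        active = [n for n in active if n not in below]
        if not active:
            warnings.warn("all signatures removed by cutoffs; zero result", stacklevel=2)
            zero = pd.Series(0.0, index=names)
            return ExposureResult(zero, zero.copy(), float(np.linalg.norm(c)), result.catalog)
        e, resid = scipy.optimize.nnls(signatures.matrix[active].to_numpy(), c)
        raw = pd.Series(0.0, index=names)
        raw[active] = e

    total = raw.sum()
    normalized = raw / total if total > 0 else raw.copy()
    return ExposureResult(raw=raw, normalized=normalized, residual=float(resid), catalog=result.catalog)


def compare_cluster_exposures(exposures: pd.DataFrame) -> pd.DataFrame:
    """Kruskal–Wallis test of normalized exposure differences between clusters.

    ``exposures`` is long-format with columns ``signature``, ``group``
    (cluster label), ``value`` (normalized exposure, one observation per
    patient x cluster). Per signature, values are compared across groups
    with the tie-corrected Kruskal–Wallis rank statistic (chi-squared
    approximation, groups−1 df); Benjamini–Hochberg adjustment is applied
    across signatures. Signatures with an empty group are skipped.
    """
    rows = []
    for sig, sub in exposures.groupby("signature", sort=True):
        groups = [g["value"].to_numpy(dtype=float) for _, g in sub.groupby("group")]
        if len(groups) < 2 or any(len(g) == 0 for g in groups):
            warnings.warn(f"signature {sig!r}: fewer than 2 non-empty groups; skipped",
                          stacklevel=2)
            continue
        if all(np.all(g == groups[0][0]) for g in groups):
            h, p = 0.0, 1.0  # constant data: no rank variation
        else:
            h, p = scipy.stats.kruskal(*groups)
        rows.append({"signature": sig, "H": float(h), "p": float(p)})
    out = pd.DataFrame(rows, columns=["signature", "H", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out
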