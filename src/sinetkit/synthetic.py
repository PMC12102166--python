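"""Synthetic data with the statistical structure the pipeline assumes.

The study cohort's raw sequencing data is access-protected, so every
downstream stage is exercised on simulated inputs that invert the
pipeline's own models:

* paired tumors — clones with per-lesion clonality; expected VAF follows
  the purity/copy-number mixing model, reads are Poisson depth + binomial
  alt counts;
* mutation contexts — 96-channel labels drawn from a clone's signature
  mixture (multinomial; no reference genome needed);
* telomere content — exact purity-weighted linear mixing;
* bulk expression — non-negative cell-type mixtures plus Gaussian noise,
  with purity tied to the enteroendocrine fraction;
* single-cell reference — Poisson backgrounds with planted fold-change
  markers;
* ASE counts — binomial allele sampling at 0.99 (monoallelic) or 0.5
  (biallelic) major-allele probability.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonality import expected_vaf
from .signatures import SBS96_LABELS, SignatureSet

__all__ = [
    "CloneSpec",
    "example_signature_set",
    "simulate_paired_tumor",
    "simulate_catalog",
    "simulate_telomere",
    "simulate_bulk_mixture",
    "simulate_sc_reference",
    "simulate_ase",
]

CLONE_LABELS = ("shared", "primary_private", "metastasis_private", "met_seeding_subclone")


@dataclass
class CloneSpec:
    """One clone of a paired primary/metastasis tumor.

    ``clonality`` is the fraction of tumor cells in a lesion carrying the
    clone's mutations (1 = fully clonal there, 0 = absent).
    """

    label: str
    n_mutations: int
    clonality_primary: float
    clonality_metastasis: float
    signature_exposure: np.ndarray | None = None  # K fractions summing to 1

    def __post_init__(self):
        if self.label not in CLONE_LABELS:
            raise ValueError(f"label must be one of {CLONE_LABELS}, got {self.label!r}")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")
        for c in (self.clonality_primary, self.clonality_metastasis):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"clonality must lie in [0, 1], got {c}")
        if self.signature_exposure is not None:
            e = np.asarray(self.signature_exposure, dtype=float)
            if (e < 0).any() or not np.isclose(e.sum(), 1.0, atol=1e-6):
                raise ValueError("signature_exposure must be non-negative and sum to 1")
            self.signature_exposure = e / e.sum()


def example_signature_set() -> SignatureSet:
    """A deterministic 3-signature reference set for simulations.

    Stands in for a fixed reference catalog (constructed, not sampled):

    * ``SBS1like`` — 80% of mass on the four N[C>T]G channels (CpG
      deamination spike), remainder uniform;
    * ``SBS5like`` — flat across all 96 channels (clock-like);
    * ``SBS3like`` — uniform over the 16 C>G channels, a flat-ish but
      linearly well-separated stand-in for the HR-deficiency signature.
    """
    idx = list(SBS96_LABELS)
    s1 = np.full(96, 0.2 / 92)
    cpg = [i for i, lab in enumerate(idx) if lab[2:5] == "C>T" and lab[6] == "G"]
    s1[cpg] = 0.8 / len(cpg)
    s5 = np.full(96, 1.0 / 96)
    s3 = np.zeros(96)
    cg = [i for i, lab in enumerate(idx) if lab[2:5] == "C>G"]
    s3[cg] = 1.0 / len(cg)
    mat = pd.DataFrame({"SBS1like": s1, "SBS5like": s5, "SBS3like": s3}, index=idx)
    return SignatureSet(matrix=mat)


def _expected_pair_label(m_primary: float, m_metastasis: float, threshold: float = 0.5) -> str:
    if m_primary >= threshold and m_metastasis >= threshold:
        return "shared"
    if m_primary >= threshold:
        return "primary_specific"
    if m_metastasis >= threshold:
        return "metastasis_specific"
    return "subthreshold"


def simulate_paired_tumor(
    clones: list[CloneSpec],
    tcc_primary: float,
    tcc_metastasis: float,
    mean_depth: float = 80.0,
    signatures: SignatureSet | None = None,
    cn: int = 2,
    m: int = 1,
    chrom: str = "chr1",
    chrom_length: int = 240_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate merged-pileup read counts for a primary/metastasis pair.

    For each mutation of each clone and each sample, the expected VAF is
    ``m * clonality * tcc / (cn*tcc + 2*(1-tcc))``; observed depth is
    Poisson(``mean_depth``) and alt reads Binomial(depth, expected VAF).
    Trinucleotide channels are drawn from the clone's signature mixture
    when ``signatures`` is given. Returns ``(pair_table, truth_table)``;
    the truth table records the generating clone, the noiseless
    mutated-allele count per sample, the channel, and the classification
    label implied by the noiseless counts at the 0.5 threshold.
    """
    for name, tcc in (("tcc_primary", tcc_primary), ("tcc_metastasis", tcc_metastasis)):
        if not 0.0 < tcc <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)

    rows, truth = [], []
    pos_pool = rng.choice(
        np.arange(1_000, chrom_length, dtype=np.int64),
        size=sum(c.n_mutations for c in clones),
        replace=False,
    )
    pos_iter = iter(np.sort(pos_pool))
    bases = np.array(list("ACGT"))
    for clone in clones:
        probs = None
        if signatures is not None:
            expo = clone.signature_exposure
            if expo is None:
                expo = np.full(signatures.k, 1.0 / signatures.k)
            probs = signatures.matrix.to_numpy() @ expo
        for _ in range(clone.n_mutations):
            pos = int(next(pos_iter))
            channel = int(rng.choice(96, p=probs)) if probs is not None else -1
            if channel >= 0:
                sub = SBS96_LABELS[channel][2:5]
                ref, alt = sub[0], sub[2]
            else:
                ref, alt = rng.choice(bases, size=2, replace=False)
            row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
            tr = {"chrom": chrom, "pos": pos, "clone": clone.label, "context96": channel}
            for side, tcc, clonality in (
                ("primary", tcc_primary, clone.clonality_primary),
                ("metastasis", tcc_metastasis, clone.clonality_metastasis),
            ):
                evaf = expected_vaf(m * clonality, cn, tcc)
                depth = int(rng.poisson(mean_depth))
                altc = int(rng.binomial(depth, evaf)) if depth > 0 else 0
                row[f"depth_{side}"] = depth
                row[f"alt_{side}"] = altc
                row[f"cn_{side}"] = cn
                tr[f"m_true_{side}"] = m * clonality
            tr["expected_label"] = _expected_pair_label(
                tr["m_true_primary"], tr["m_true_metastasis"]
            )
            if channel >= 0:
                row["context96"] = channel
            rows.append(row)
            truth.append(tr)

    pair = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth_df = pd.DataFrame(truth).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return pair, truth_df


def simulate_catalog(
    signatures: SignatureSet, exposure, seed: int = 0
) -> pd.Series:
    """Draw a 96-channel catalog from a signature mixture.

    ``exposure`` gives mutation counts per signature; channel counts are
    multinomial with probabilities S @ (exposure / sum). The output always
    sums to sum(exposure).
    """
    e = np.asarray(exposure, dtype=float)
    if (e < 0).any():
        raise ValueError("exposure counts must be >= 0")
    n = int(round(e.sum()))
    if n == 0:
        warnings.warn("all-zero exposure; returning empty catalog", stacklevel=2)
        return pd.Series(np.zeros(96, dtype=int), index=list(SBS96_LABELS))
    rng = np.random.default_rng(seed)
    p = signatures.matrix.to_numpy() @ (e / e.sum())
    counts = rng.multinomial(n, p / p.sum())
    return pd.Series(counts, index=list(SBS96_LABELS))


def simulate_telomere(t_true: float, c: float, tcc: float) -> float:
    """Observed bulk telomere content under linear purity mixing (exact)."""
    if t_true < 0 or c < 0:
        raise ValueError("telomere contents must be >= 0")
    if not 0.0 < tcc <= 1.0:
        raise ValueError(f"tcc must be in (0, 1], got {tcc}")
    return tcc * t_true + (1.0 - tcc) * c


def simulate_bulk_mixture(
    celltype_signatures: pd.DataFrame,
    compositions: pd.DataFrame,
    noise_sd: float = 0.0,
    purity_celltype: str = "enteroendocrine",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mix cell-type expression signatures into bulk samples.

    ``celltype_signatures`` is genes x cell-types (mean expression);
    ``compositions`` is samples x cell-types with rows summing to 1.
    Expression = signatures @ compositions.T + Gaussian noise, clipped at
    0. Returns ``(expression genes x samples, tcc)`` where the reported
    tumor-cell-content covariate equals the ``purity_celltype``
    composition column (tumor cells descend from that lineage, so purity
    tracks its fraction by construction).
    """
    comp = compositions[celltype_signatures.columns]
    sums = comp.sum(axis=1).to_numpy()
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("composition rows must sum to 1")
    rng = np.random.default_rng(seed)
    expr = celltype_signatures.to_numpy() @ comp.to_numpy().T
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    expr = np.clip(expr, 0.0, None)
    expr_df = pd.DataFrame(
        expr, index=celltype_signatures.index, columns=compositions.index
    )
    if purity_celltype not in comp.columns:
        raise ValueError(f"purity cell type {purity_celltype!r} not in compositions")
    tcc = comp[purity_celltype].copy()
    tcc.name = "tcc"
    return expr_df, tcc


def simulate_sc_reference(
    n_cells_per_type: dict[str, int],
    n_genes: int,
    planted_markers: dict[str, tuple[str, float]] | None = None,
    base_rate: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labeled single-cell reference with planted marker genes.

    Background genes share a LogNormal baseline rate across cell types
    (cells are Poisson draws), so they carry no type information.
    ``planted_markers`` maps gene name -> (cell type, fold change > 1);
    the marker's rate is multiplied by the fold in its type only. Marker
    names not among the ``g0..g{n-1}`` background names are appended.
    Returns ``(expression genes x cells, labels per cell)``.
    """
    if planted_markers:
        for gene, (ctype, fold) in planted_markers.items():
            if ctype not in n_cells_per_type:
                raise ValueError(f"marker {gene!r} planted for unknown type {ctype!r}")
            if fold <= 1:
                raise ValueError(f"marker {gene!r} fold change must be > 1")
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    extra = [g for g in (planted_markers or {}) if g not in genes]
    genes = genes + extra
    baseline = rng.lognormal(mean=np.log(base_rate), sigma=0.4, size=len(genes))
    gene_idx = {g: i for i, g in enumerate(genes)}

    blocks, labels = [], []
    for ctype, n_cells in n_cells_per_type.items():
        rate = baseline.copy()
        for gene, (mtype, fold) in (planted_markers or {}).items():
            if mtype == ctype:
                rate[gene_idx[gene]] *= fold
        blocks.append(rng.poisson(rate[:, None], size=(len(genes), n_cells)))
        labels += [ctype] * n_cells
    expr = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=genes,
        columns=[f"cell{i}" for i in range(len(labels))],
    )
    return expr, pd.Series(labels, index=expr.columns, name="cell_type")


def simulate_ase(
    status: str,
    n_sites: int,
    depth: int,
    gene: str = "IGF2",
    p_major: float = 0.99,
    p_other: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ASE read counts at het SNPs of one gene.

    ``monoallelic`` sites draw the major allele at probability ``p_major``
    (residual counts are sequencing error); ``biallelic`` at 0.5.
    otherBases are Binomial(depth, ``p_other``) and the ref/alt split is
    drawn from the remaining reads, so counts always sum to depth.
    """
    if status not in ("monoallelic", "biallelic"):
        raise ValueError(f"status must be monoallelic or biallelic, got {status!r}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    p = p_major if status == "monoallelic" else 0.5
    other = rng.binomial(depth, p_other, size=n_sites)
    remaining = depth - other
    ref = rng.binomial(remaining, p)
    return pd.DataFrame(
        {
            "gene": gene,
            "chrom": "chr11",
            "pos": np.arange(1, n_sites + 1) * 100,
            "refCount": ref,
            "altCount": remaining - ref,
            "otherBases": other,
        }
    )
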