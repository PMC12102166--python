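"""Bulk expression deconvolution: ICA, preranked GSEA, and NMF cell-of-origin.

Bulk tumor RNA-seq superimposes tumor-cell programs on stromal and
epithelial backgrounds. Two matrix decompositions separate them:

* ICA on the variance-stabilized top-variance genes yields statistically
  independent expression programs; correlating each component's sample
  scores with tumor cell content identifies the tumor program, and
  preranked GSEA on its gene weights (weighted Kolmogorov–Smirnov running
  sum, gene-label permutation null) characterizes it.
* NMF on cell-type marker genes factorizes samples into non-negative
  programs that are matched to cell-type-averaged single-cell signatures
  by cosine similarity — the factor tracking purity names the cell of
  origin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import NMF, FastICA
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ComponentSet",
    "vst_normalize",
    "select_hvg",
    "run_ica",
    "correlate_scores",
    "enrichment_score",
    "preranked_gsea",
    "select_markers",
    "nmf_deconvolve",
    "assign_factors",
]


@dataclass
class ComponentSet:
    """Latent factors of a bulk expression matrix."""

    gene_weights: pd.DataFrame  # genes x k
    sample_scores: pd.DataFrame  # samples x k
    method: str  # "ica" | "nmf"
    reconstruction_error: float | None = None


def vst_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing normalization of a genes x samples count matrix.

    Median-of-ratios size factors (median over genes with nonzero
    geometric mean of count / geometric mean) followed by
    log2(count / size_factor + 1). Removes sequencing-depth effects and
    compresses the variance–mean relation, which is what the rank- and
    correlation-based downstream steps require.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (x.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    with np.errstate(divide="ignore"):
        loggeo = np.log(x).mean(axis=1)  # -inf for genes with any zero
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError("no gene has a nonzero geometric mean")
    ratios = np.log(x[usable]) - loggeo[usable, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    out = np.log2(x / size_factors[None, :] + 1.0)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def select_hvg(matrix: pd.DataFrame, n: int = 1000) -> pd.DataFrame:
    """Restrict to the ``n`` most variable genes.

    Variance across samples of the (transformed) values; ties broken by
    gene label, lexicographic, for determinism.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > matrix.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {matrix.shape[0]}")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], str(g)))
    return matrix.loc[order[:n]]


def run_ica(matrix: pd.DataFrame, k: int = 7, seed: int = 0, max_iter: int = 2000,
            tol: float = 1e-6) -> ComponentSet:
    """Independent component analysis of a genes x samples matrix.

    FastICA (fixed-point negentropy maximization after whitening) with the
    genes as observations, so each component is a gene-weight vector with
    a matching sample-score (mixing) vector. The rotation ambiguity is
    fixed by: unit-norm gene weights, sign flipped so each weight vector
    has positive skewness, components ordered by descending sample-score
    variance.
    """
    if matrix.shape[1] < k:
        raise ValueError(f"need at least k={k} samples, have {matrix.shape[1]}")
    ica = FastICA(n_components=k, random_state=seed, max_iter=max_iter, tol=tol,
                  whiten="unit-variance")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(matrix.to_numpy())  # genes x k
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"FastICA did not converge within {max_iter} iterations"
            ) from exc
    mixing = ica.mixing_  # samples x k

    skew = scipy.stats.skew(sources, axis=0)
    flip = np.where(skew < 0, -1.0, 1.0)
    sources = sources * flip
    mixing = mixing * flip
    norms = np.linalg.norm(sources, axis=0)
    norms[norms == 0] = 1.0
    sources = sources / norms
    mixing = mixing * norms

    order = np.argsort(-mixing.var(axis=0), kind="stable")
    comp_names = [f"IC{i + 1}" for i in range(k)]
    return ComponentSet(
        gene_weights=pd.DataFrame(sources[:, order], index=matrix.index, columns=comp_names),
        sample_scores=pd.DataFrame(mixing[:, order], index=matrix.columns, columns=comp_names),
        method="ica",
    )


def correlate_scores(
    sample_scores: pd.DataFrame, covariate: pd.Series, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate each component's sample scores with a per-sample covariate.

    Returns per-component r and two-sided p (Pearson by default, Spearman
    via ``method='spearman'``) — e.g. against tumor cell content to find
    the purity-tracking component.
    """
    cov = covariate.reindex(sample_scores.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some samples")
    if np.ptp(cov.to_numpy(dtype=float)) == 0:
        raise ValueError("covariate has zero variance")
    fn = scipy.stats.pearsonr if method == "pearson" else scipy.stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for comp in sample_scores.columns:
        r, p = fn(sample_scores[comp].to_numpy(dtype=float), cov.to_numpy(dtype=float))
        rows.append({"component": comp, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def enrichment_score(
    weights: np.ndarray, hit_mask: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """Weighted Kolmogorov–Smirnov enrichment score of one gene set.

    ``weights`` must already be sorted in ranking order (descending
    metric). The running sum gains |w|^exponent (normalized over hits) at
    each set member and loses 1/(N - Nh) at each non-member; the ES is the
    running-sum value of largest magnitude.
    """
    n = len(weights)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(weights) ** weight_exponent
    hit_total = w[hit_mask].sum()
    steps = np.where(hit_mask, (w / hit_total if hit_total > 0 else 1.0 / nh), -1.0 / (n - nh))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _null_es(
    sorted_w: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """Vectorized gene-label permutation null for one set size."""
    n = len(sorted_w)
    w = np.abs(sorted_w) ** weight_exponent
    miss = -1.0 / (n - set_size)
    es = np.empty(n_perm)
    # sample hit positions per permutation; cumsum per row
    for start in range(0, n_perm, 256):
        block = min(256, n_perm - start)
        pos = np.argsort(rng.random((block, n)), axis=1)[:, :set_size]
        steps = np.full((block, n), miss)
        hit_w = w[pos]
        hit_w = hit_w / np.where(hit_w.sum(axis=1, keepdims=True) > 0,
                                 hit_w.sum(axis=1, keepdims=True), set_size)
        np.put_along_axis(steps, pos, hit_w, axis=1)
        running = np.cumsum(steps, axis=1)
        idx = np.argmax(np.abs(running), axis=1)
        es[start:start + block] = running[np.arange(block), idx]
    return es


def preranked_gsea(
    gene_weights: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA on a gene-level ranking metric (e.g. ICA weights).

    Genes are ranked by descending metric; each set's ES is the weighted
    KS running-sum extremum. The null is gene-label permutation (random
    same-size sets drawn from the universe; nulls are shared between sets
    of equal size), and the signed ES is compared against same-sign null
    values. BH adjustment is applied across the reported sets.
    """
    ranked = gene_weights.sort_values(ascending=False, kind="stable")
    universe = ranked.index
    w_sorted = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in gene_sets.items():
        hit_mask = np.asarray(universe.isin(set(members)))
        size = int(hit_mask.sum())
        if size < min_size:
            warnings.warn(f"gene set {name!r}: only {size} members in universe; skipped",
                          stacklevel=2)
            continue
        if size == len(universe):
            warnings.warn(f"gene set {name!r} equals the universe; ES degenerate; skipped",
                          stacklevel=2)
            continue
        es = enrichment_score(w_sorted, hit_mask, weight_exponent)
        if size not in null_cache:
            null_cache[size] = _null_es(w_sorted, size, n_perm, rng, weight_exponent)
        null = null_cache[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        more_extreme = int((np.abs(same_sign) >= abs(es)).sum())
        p = (1 + more_extreme) / (1 + len(same_sign))
        rows.append({"set": name, "size": size, "es": es, "p": p})
    out = pd.DataFrame(rows, columns=["set", "size", "es", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def select_markers(
    sc_matrix: pd.DataFrame,
    cell_labels: pd.Series,
    top_n: int = 10,
    min_lfc: float = 2.0,
    pseudocount: float = 1e-9,
) -> dict[str, list[str]]:
    """Top marker genes per cell type by Wilcoxon rank-sum (type vs rest).

    Genes are ranked per type by the tie-corrected rank-sum z-score,
    filtered to log2 fold change of arithmetic means >= ``min_lfc``
    (pseudocount added), truncated to ``top_n``. Types with fewer than 2
    cells are skipped.
    """
    labels = cell_labels.reindex(sc_matrix.columns)
    types = labels.dropna().unique()
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    x = sc_matrix.to_numpy(dtype=float)
    n_cells = x.shape[1]
    ranks = scipy.stats.rankdata(x, axis=1)

    # tie correction term per gene: sum(t^3 - t) over tied groups
    tie_term = np.zeros(x.shape[0])
    for g in range(x.shape[0]):
        _, counts = np.unique(x[g], return_counts=True)
        tie_term[g] = ((counts**3 - counts).sum())

    markers: dict[str, list[str]] = {}
    for ctype in types:
        in_type = (labels == ctype).to_numpy()
        n1 = int(in_type.sum())
        n2 = n_cells - n1
        if n1 < 2:
            warnings.warn(f"cell type {ctype!r} has {n1} cell(s); skipped", stacklevel=2)
            continue
        rank_sum = ranks[:, in_type].sum(axis=1)
        mu = n1 * (n_cells + 1) / 2.0
        var = (n1 * n2 / 12.0) * ((n_cells + 1) - tie_term / (n_cells * (n_cells - 1.0)))
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, (rank_sum - mu) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        mean_in = x[:, in_type].mean(axis=1)
        mean_rest = x[:, ~in_type].mean(axis=1)
        lfc = np.log2((mean_in + pseudocount) / (mean_rest + pseudocount))
        qualifies = lfc >= min_lfc
        order = np.argsort(-z, kind="stable")
        chosen = [sc_matrix.index[i] for i in order if qualifies[i]][:top_n]
        markers[str(ctype)] = chosen
    return markers


def nmf_deconvolve(
    bulk: pd.DataFrame,
    k: int = 4,
    l1_ratio: float = 0.0,
    alpha: float = 1e-3,
    max_iter: int = 2000,
    tol: float = 1e-4,
    seed: int = 0,
    normalize: bool = True,
) -> ComponentSet:
    """Non-negative factorization of a marker-restricted bulk matrix.

    ``bulk`` is genes x samples. Negative values (possible after
    variance-stabilizing transforms) are clipped to 0 with a warning;
    with ``normalize`` each sample's marker vector is scaled to unit
    Euclidean norm so composition rather than depth drives the factors.
    The factorization minimizes the Frobenius reconstruction error with
    regularization of strength ``alpha`` on the sample-factor matrix
    (pure L2 at ``l1_ratio=0``), via coordinate descent from the
    deterministic NNDSVDa initialization.
    """
    if k > min(bulk.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(bulk.shape)}")
    x = bulk.to_numpy(dtype=float)
    if (x < 0).any():
        warnings.warn("negative values clipped to 0 before NMF", stacklevel=2)
        x = np.clip(x, 0.0, None)
    if normalize:
        norms = np.linalg.norm(x, axis=0)
        norms[norms == 0] = 1.0
        x = x / norms[None, :]
    model = NMF(
        n_components=k,
        init="nndsvda",
        solver="cd",
        l1_ratio=l1_ratio,
        alpha_W=alpha,
        alpha_H="same",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        w = model.fit_transform(x.T)  # samples x k
    if any(issubclass(c.category, ConvergenceWarning) for c in caught):
        warnings.warn(
            f"NMF did not converge; final reconstruction error "
            f"{model.reconstruction_err_:.4g}",
            stacklevel=2,
        )
    h = model.components_  # k x genes
    comp_names = [f"F{i + 1}" for i in range(k)]
    return ComponentSet(
        gene_weights=pd.DataFrame(h.T, index=bulk.index, columns=comp_names),
        sample_scores=pd.DataFrame(w, index=bulk.columns, columns=comp_names),
        method="nmf",
        reconstruction_error=float(model.reconstruction_err_),
    )


def assign_factors(
    gene_profiles: pd.DataFrame, celltype_signatures: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Match factors to cell types by cosine similarity of gene profiles.

    Both inputs are genes x columns; they are aligned on their shared
    gene universe. Returns the factors x cell-types similarity matrix and
    each factor's argmax assignment (``"none"`` for an all-zero factor).
    """
    shared = gene_profiles.index.intersection(celltype_signatures.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between factors and signatures")
    f = gene_profiles.loc[shared].to_numpy(dtype=float)
    s = celltype_signatures.loc[shared].to_numpy(dtype=float)
    fn = np.linalg.norm(f, axis=0)
    sn = np.linalg.norm(s, axis=0)
    sim = (f.T @ s) / np.outer(np.where(fn == 0, 1.0, fn), np.where(sn == 0, 1.0, sn))
    sim_df = pd.DataFrame(sim, index=gene_profiles.columns, columns=celltype_signatures.columns)
    assignment = pd.Series(
        np.where(fn == 0, "none", sim_df.columns[np.argmax(sim, axis=1)]),
        index=gene_profiles.columns,
        name="cell_type",
    )
    return sim_df, assignment
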