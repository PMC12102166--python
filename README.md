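# sinetkit

Analysis toolkit for whole-genome and transcriptome studies of small
intestinal neuroendocrine tumors (siNETs) — slow-growing gut cancers that
arise from enteroendocrine cells, frequently metastasize, and carry few
recurrent driver mutations. The package implements the bespoke
computations such a study needs downstream of variant calling, copy-number
calling, and expression quantification, together with a synthetic-data
generator so that every stage can be exercised and validated without
access-protected patient data.

## What it computes

**Clonality-resolved mutation timing.** For a mutation with variant allele
fraction VAF, local total copy number CN, and tumor cell content tcc, the
expected VAF under purity/copy-number mixing is

    E[VAF] = m · tcc / (CN · tcc + 2 · (1 − tcc))

with m mutated alleles per tumor cell. `clonality.mutated_alleles` inverts
this (mode `model_consistent`, m = VAF·(CN·tcc + 2(1−tcc))/tcc) and also
offers the literal published correction (mode `printed`,
m = VAF·CN·tcc/(CN·tcc + 2(1−tcc))·CN); the two agree at tcc = 1 for a
diploid locus and diverge otherwise. Mutations of a primary/metastasis
pair with coverage 20–250× in both samples are split at a 0.5
mutated-allele threshold into shared, primary-specific, and
metastasis-specific clusters (minimum size 100), which are then dated by
signature refitting.

**SBS-96 signature refitting.** Catalogs use the pyrimidine-centered
96-channel classification; exposures solve min ‖C − S·E‖₂, E ≥ 0 by
non-negative least squares against a fixed reference signature matrix,
with iterative per-signature cutoffs on normalized exposure. Exposure
differences between clone clusters are tested per signature with
Kruskal–Wallis plus Benjamini–Hochberg adjustment.

**Burden, kataegis, telomeres.** TMB = coding SNVs+indels per Mb of merged
non-overlapping coding sequence (Gencode v19 constant 35,345,952 bp as the
default denominator). Hypermutated regions are maximal runs of ≥ 6
consecutive SNVs with mean inter-mutational distance < 1000 bp. Bulk
telomere content is purity-corrected exactly:
telomere_corrected = (telomere_tumor − telomere_control·(1 − tcc))/tcc.

**Allele-specific expression / loss of imprinting.** Het-SNP read counts
are filtered (depth ≥ 10, ≤ 3 otherBases, otherBases not exceeding both
allelic counts, HLA genes removed) and aggregated per gene as the mean
major-allele ratio max(ref, alt)/total; thresholds call genes
monoallelic, biallelic (supporting loss of imprinting for IGF2), or
indeterminate.

**Expression deconvolution.** Variance-stabilized counts → 1000 most
variable genes → 7-component FastICA; component sample scores are
correlated with purity, and preranked GSEA (weighted Kolmogorov–Smirnov
running sum, gene-label permutation null, BH per collection) is run on
component gene weights. For cell-of-origin assignment, top-10 Wilcoxon
markers per cell type (min log2 fold change 2) from a labeled single-cell
reference define the gene space; the marker-restricted bulk matrix is
factorized by NMF (4 factors, L1-ratio 0, alpha 10⁻³) and factors are
matched to cell-type signatures by cosine similarity.

## Worked example

Simulate a primary/metastasis pair (purities 0.6 / 0.8, depth 80×) whose
shared clone lacks the HR-deficiency-like signature while both private
clones carry 30% of it, then classify and refit:

```python
import numpy as np
from sinetkit.synthetic import CloneSpec, example_signature_set, simulate_paired_tumor
from sinetkit.clonality import classify_pair, extract_clusters
from sinetkit.signatures import build_catalog, fit_exposures

sigset = example_signature_set()
clones = [
    CloneSpec("shared", 1000, 1.0, 1.0, np.array([0.5, 0.5, 0.0])),
    CloneSpec("primary_private", 500, 1.0, 0.0, np.array([0.35, 0.35, 0.30])),
    CloneSpec("metastasis_private", 500, 0.0, 1.0, np.array([0.35, 0.35, 0.30])),
]
pair, truth = simulate_paired_tumor(clones, tcc_primary=0.6, tcc_metastasis=0.8,
                                    mean_depth=80, signatures=sigset, seed=1)
result = classify_pair(pair, tcc_primary=0.6, tcc_metastasis=0.8)
print(result.counts().to_dict())
for label, cluster in extract_clusters(result, min_size=100).items():
    fit = fit_exposures(build_catalog(cluster, entity_id=label), sigset)
    print(label, fit.normalized.round(3).to_dict())
```

prints

```
{'shared': 999, 'primary_specific': 499, 'metastasis_specific': 501, 'subthreshold': 1, 'coverage_filtered': 0}
shared {'SBS1like': 0.464, 'SBS5like': 0.536, 'SBS3like': 0.0}
primary_specific {'SBS1like': 0.312, 'SBS5like': 0.365, 'SBS3like': 0.323}
metastasis_specific {'SBS1like': 0.359, 'SBS5like': 0.333, 'SBS3like': 0.307}
```

All 2000 mutations but one land in their generating cluster, and the
refit recovers the planted exposures: the shared clone shows 0% of the
SBS3-like signature while both lesion-specific clones show it within a
few percent of the simulated 30% — mutational processes active only after
the lineages diverged leave their imprint only in the private clusters.

A CLI mirrors the library (`sinetkit simulate|clonality|signatures|
burden|telomere|ase|deconv|gsea`); every subcommand logs its full
parameterization and seed.

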