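# Methods

This note records the models behind each sinetkit module, the parameters
that matter, the numerical choices, and what the synthetic-data
validation does and does not demonstrate about real data.

## Mutation copy number and pair classification

A bulk tumor sample with tumor cell content (purity) tcc ∈ (0, 1] mixes
tumor cells carrying CN total allele copies at a mutated locus (m of them
mutated, clonality f of tumor cells carrying the mutation) with normal
cells carrying two unmutated copies. Reads sample alleles uniformly, so

    E[VAF] = m · f · tcc / (CN · tcc + 2 · (1 − tcc)).

`mutated_alleles` offers two inversions of the observed VAF:

* `model_consistent` (default): m = VAF · (CN·tcc + 2(1−tcc)) / tcc, the
  exact algebraic inverse; a clonal heterozygous mutation maps to 1.0 at
  any purity. This matches the standard mutation copy number concept.
* `printed`: m = VAF · CN·tcc/(CN·tcc + 2(1−tcc)) · CN, the correction
  exactly as published for this pipeline. It agrees with the inverse at
  tcc = 1 when CN = 2 and is biased low otherwise (a clonal het mutation
  at tcc = 0.5, CN = 2 yields 0.25, below the 0.5 calling threshold).

Both are kept because the published form does not invert the mixing model
it cites; the default is the model-consistent inverse, the `printed` mode
gives literal reproduction. Classification of a primary/metastasis pair
applies, in order: a coverage filter (20 ≤ depth ≤ 250 inclusive, both
samples — per-sample semantics chosen since the published filter does not
specify; configurable), then the 0.5 mutated-allele threshold per sample
(ties count as above). Sites on CN = 0 segments get m = 0 (the dilution
is undefined; they cannot be called present). Clusters below 100
mutations are discarded before signature refitting to avoid noisy
deconvolution.

## Signature refitting

Catalogs are 96-channel counts in the canonical pyrimidine-centered
order (A[C>A]A … T[T>G]T); purine-strand SNVs are reverse-complemented.
Exposures solve min ‖C − S·E‖₂ s.t. E ≥ 0 via the Lawson–Hanson
active-set NNLS (deterministic; scipy). Per-signature cutoffs act on
normalized exposures: all below-cutoff signatures are removed
simultaneously each round and the survivors refitted, iterating until
every surviving normalized exposure meets its cutoff (a one-at-a-time
variant, smallest first, is available; the reference implementation's
exact schedule is not published, and cutoff values are a user input with
default 0). Cluster-exposure differences use the tie-corrected
Kruskal–Wallis statistic with the χ² approximation and BH adjustment
across signatures; raw p and q are both reported.

The bundled 3-signature toy set (`example_signature_set`) is constructed
deterministically — a CpG C>T spike, a flat clock-like signature, and a
C>G-concentrated stand-in for the HR-deficiency signature — because a
reference catalog is a fixed input, not part of experiment randomness.
The flat and C>G signatures are linearly well separated, so NNLS recovery
at 1000 mutations per cluster is accurate to a few percent; real COSMIC
signatures are more collinear (notably the genuinely flat SBS3 vs SBS5),
and refitting real catalogs should use the COSMIC matrix with its
published cutoffs.

## Burden, kataegis, telomere

TMB counts SNVs and indels whose 1-based position (indels: first changed
base) falls in the merged union of 0-based half-open coding intervals,
divided by the union length in Mb; without a BED the Gencode v19 merged
coding length 35,345,952 bp is the documented default denominator.

Hypermutated regions are found by a greedy maximal-run scan over sorted
per-chromosome SNV positions: a run extends while its running mean
successive gap stays strictly below 1000 bp, and runs of ≥ 6 SNVs are
reported with their span, count, mean inter-mutational distance, and
overlapping genes. A window closed by a long gap is not re-opened by a
later short one; this maximal-run reading (rather than a sliding window)
is an interpretation choice and is the only semantics implemented.

Telomere correction is exact algebra on the linear mixing model
T_obs = tcc·T_tumor + (1−tcc)·T_control; negative corrected values
(control exceeding tumor at low purity) are reported with a QC flag, not
clipped.

## Allele-specific expression

Sites survive iff depth ≥ 10, otherBases ≤ 3, otherBases not exceeding
*both* allelic counts (the published wording is ambiguous between AND and
OR; AND is the default, OR a toggle), gene not in the supplied HLA list,
and optionally depth within twofold of the sample mean. Per gene the
major-allele ratio max(ref, alt)/(ref+alt+other) is averaged over sites.
Call thresholds (biallelic ≤ 0.65, monoallelic ≥ 0.85, indeterminate
between) are explicit configuration echoed in the output: no published
decision rule exists, and the gap between the bounds is deliberate so
that borderline genes are not forced into either call.

## Expression deconvolution

*Normalization.* Median-of-ratios size factors followed by
log2(count/sf + 1). This is a deliberate stand-in for the rlog shrinkage
transform: it removes depth effects and compresses the variance–mean
relation, which is all the downstream rank- and correlation-based steps
consume; it does not reproduce rlog's per-gene shrinkage.

*ICA.* The 1000 most variable genes (ties broken lexicographically) enter
FastICA with 7 components, genes as observations. Rotation/sign/scale
ambiguity is fixed by unit-norm gene weights, positive skewness
orientation, and ordering by descending sample-score variance;
non-convergence raises rather than silently returning a partial fit.
Component scores are correlated with purity (Pearson default, Spearman
optional).

*Preranked GSEA.* ES is the extremum of the weighted KS running sum
(hits weighted by |metric|^1 normalized, misses by 1/(N−Nh)). The null
permutes gene labels — equivalent to drawing random same-size sets from
the universe — because the ranking metric is a component weight vector,
not per-sample data; nulls are cached per set size. p compares the signed
ES against same-sign null values with a +1 smoothing; BH runs across the
sets of a collection. Sets smaller than 5 in-universe members, or equal
to the whole universe (no misses defined), are skipped with warnings.

*Markers and NMF.* Marker selection ranks genes per cell type by the
tie-corrected Wilcoxon rank-sum z-score (type vs rest), filters to
log2 fold change of arithmetic means ≥ 2 (pseudocount 1e-9), and keeps
the top 10. The fold change is defined on arithmetic means of the input
values; tools that compute it on expm1-transformed log means will differ
subtly at the filter boundary. The marker-restricted bulk matrix is
clipped at 0, each sample scaled to unit Euclidean norm (sample-wise so
composition, not depth, drives factors — the normalization axis is
otherwise unspecified), and factorized by coordinate-descent NMF from
the deterministic NNDSVDa initialization (k = 4, L1-ratio 0, alpha 10⁻³
on the sample-factor matrix, mirrored on H). Factors are assigned to cell
types by cosine similarity of gene profiles over the shared gene
universe; an all-zero factor is assigned "none".

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed). Read counts use
Poisson depth + binomial alt sampling — the minimal model consistent with
the VAF correction; real data add mapping bias, strand artifacts, and
overdispersion. Contexts are simulated directly as channel labels, so no
reference genome is involved. Bulk mixtures are linear with Gaussian
noise and report purity as the enteroendocrine composition fraction —
exactly the assumption NMF deconvolution makes, so recovery there
validates the implementation, not the biological model. The single-cell
reference uses i.i.d. Poisson backgrounds with planted fold-change
markers; real atlases have correlated programs and continuous lineages.
Default study conditions: purities 0.6/0.8, mean depth 80×, 500–1000
mutations per clone, 30% private-clone exposure of the HR-deficiency-like
signature, 24 bulk samples × 4 cell types with enteroendocrine fraction
0.3–0.9, ASE depth 1000 at 20 sites with 0.99/0.5 major-allele
probability and 0.002 error. These sizes keep the full validation suite
and the acceptance script each under a minute of compute while leaving
comfortable statistical margins.

Passing on these simulations shows the algebra, the solvers, and the
decision rules are implemented correctly and are well calibrated under
the stated models. It does not show robustness to purity estimation
error, subclonal copy number, signature collinearity, or batch effects in
real cohorts.

## Known limitations

* De-novo signature extraction, indel/CN signature pipelines, subclonal
  deconvolution beyond the three-way split, and phasing are out of scope.
* The kataegis scan's greedy run extension can split one biological event
  in two when a single long gap interrupts it.
* The published exposure cutoffs are not redistributable here; without a
  cutoff file, refitting applies none.
* `mutated_alleles(mode="printed")` reproduces the published correction
  verbatim, including its divergence from the mixing model at low purity;
  results from the two modes should not be mixed within one analysis.
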