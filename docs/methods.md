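# Methods

`cgwas` implements cluster-based genome-wide association scanning (cGWAS):
phenotypically heterogeneous cases are partitioned into clusters by deep
embedded clustering (DEC) of their questionnaire-derived features, and each
cluster is scanned against a single shared control pool with an
additive-dosage logistic model. The premise is that a variant with a strong
effect confined to a small phenotypic subgroup is diluted to invisibility in
an all-cases-versus-all-controls scan, but attains genome-wide significance
when its subgroup is scanned alone. Because each cluster scan is small and
the number of scans is large, the genomic inflation factor λ of every scan
is used as a guard against spurious inflation: a clustering is treated as
valid only when the average λ across cluster scans stays below 1.05.

## Synthetic cohorts

The generator stands in for controlled-access autism case-control data and
defines the study conditions under which the pipeline is validated.

* **Genotypes.** Independent biallelic autosomal variants. Each ALT
  frequency is drawn uniformly from `maf_range` (default 0.05–0.5) and
  genotypes are Binomial(2, f) hard calls — Hardy–Weinberg proportions by
  construction. Variants are laid out round-robin across chromosomes 1–22
  at 10 kb spacing. There is no linkage disequilibrium between simulated
  variants; LD behaviour (clumping) is exercised by dedicated fixtures with
  planted correlated pairs.
* **Disease model.** A causal specification is a list of
  (variant, subgroup, per-allele OR) triples. Case genotypes for subgroup g
  are rejection-sampled with acceptance probability proportional to the
  logistic odds `prod_v OR_v^dosage_v`. This exponential tilt makes the case
  genotype distribution at a causal variant exactly Hardy–Weinberg at
  `f' = f·OR/(1−f+f·OR)`, so the planted *allelic* odds ratio of a
  case-versus-control comparison equals the configured OR with no further
  calibration. (An acceptance anchored to a disease prevalence through a
  sigmoid would attenuate the realized OR whenever the per-genotype
  probability saturates.) Controls are drawn from the base distribution.
* **Phenotypes.** Cases only. Numeric items mimic three questionnaire
  blocks of 15, 40 and 43 items (motor coordination, social communication,
  repetitive behaviour) plus age in months; each item is N(0, 1) noise, and
  the items assigned round-robin to subgroup g are shifted by
  `subgroup_item_shift` (default 2) standard deviations for members of g.
  Categorical background variables (ethnicity, dominant hand, three
  intervention histories) are uniform multinomials. Missingness is MCAR at
  `missing_rate` (default 5%) — consistent with downstream mean imputation,
  which assumes it.
* **Default scale.** 2,000 cases / 875 controls / 20,000 variants: the
  shape of the emulated study at desk scale.

What the generator does **not** emulate: family structure, sex chromosomes
(the emulated study is male-only autosomal), population stratification,
genotyping batch effects, LD, and any realistic joint distribution of
phenotype and genotype within real subgroups — the subgroup structure is an
assumption. Passing tests therefore demonstrate internal statistical
correctness and calibration of the pipeline, not that real cohorts contain
recoverable subgroups.

## Feature construction

Categorical variables are dummy-encoded first, with a missing category kept
as its own explicit level; numeric columns are then mean-imputed;
all-missing columns are dropped with a warning; constant columns are
dropped; finally every column is z-standardized (toggleable). One-hot is
full rather than k−1: the consumer is a distance-based clustering model, so
collinearity is harmless and level symmetry is preferable. Standardization
is on by default because the autoencoder is scale-sensitive.

## Deep embedded clustering

DEC jointly learns a latent representation and centroids:

1. **Pretraining.** A symmetric autoencoder (ReLU hidden layers, linear
   latent and output) is trained on mean squared reconstruction error with
   Adam (lr 1e-3). Default widths are d–64–32–10 — a desk-scale choice;
   the canonical d–500–500–2000–10 stack is available through
   `encoder_dims`/`latent_dim`.
2. **Initialization.** k-means (10 restarts, seeded) on the latent codes.
3. **Refinement.** Soft assignments use the Student-t kernel with one
   degree of freedom, `q_ij ∝ (1+‖z_i−μ_j‖²)^{-1}`, row-normalized. The
   target distribution sharpens Q: `p_ij ∝ q_ij²/f_j` with `f_j = Σ_i q_ij`
   (empty-cluster columns contribute zero). Mini-batch SGD with momentum
   0.9 (lr 0.01) descends KL(P‖Q) with respect to the encoder and the
   centroids; P is refreshed on the full data every `update_interval`
   iterations, and training stops when the fraction of hard labels changed
   between consecutive refreshes falls below `tolerance`, or at
   `max_iterations`.

Defaults follow the emulated study: k = 40, batch 256, 300 pretraining
epochs, 400 maximum refinement iterations, update interval 30, tolerance
0.001. Hard labels are the row argmax (ties resolved to the lowest cluster
index by argmax semantics); clusters may end up empty without error.
Networks are plain NumPy; everything is seeded and single-threaded, so runs
are bit-reproducible.

## Genotype QC

Variant filters (defaults): minor allele frequency ≥ 0.01, call rate
≥ 0.95, exact Hardy–Weinberg test p ≥ 1e-6, computed jointly on cases and
controls. The HWE test is the conditional exact test (two-sided: sum of
probabilities of heterozygote counts no more likely than observed, given
the allele counts), evaluated with a log-space recurrence; a chi-square
variant is available. Fractional dosages are rounded to hard calls for HWE
only; frequencies and association use raw dosage. The retained set is the
AND of the three predicates; the report attributes removals in the order
maf → call rate → HWE. Sample exclusion follows the 6-SD rule: PCA on the
standardized genotype matrix (missing → mean), samples whose PC1 or PC2
score exceeds 6 SD of that component are removed. Multi-allelic VCF records
are skipped with a warning.

## Association scans and λ

Per variant the model is `logit P(case) = β₀ + β·dosage`, no covariates;
p is the two-sided Wald test on β. Fits are Newton–Raphson vectorized
across variants; for hard-call data the six genotype-by-status counts are
sufficient statistics, making each iteration O(variants). Complete
separation and non-convergence (|β| ≥ 12, singular Hessian, or no
convergence in 25 damped Newton steps) are flagged `converged = False` and
excluded from λ and significance lists rather than raised — small cluster
scans make separation routine. Variants monomorphic within a scan's samples
are skipped per scan. p-values that underflow double precision are floored
at the smallest positive double so they remain in (0, 1].

λ = median of the observed 1-df chi-square quantiles (from two-sided p)
divided by 0.4549, computed over all converged records of a scan; no
post-clumping restriction. Per-cluster eligibility requires ≥ 10 cases
("more than nine"), applied as an eligibility rule rather than a reporting
rule. The mean λ across eligible cluster scans is the validity statistic;
1.05 is the safety threshold. Significance uses the fixed genome-wide
5×10⁻⁸ threshold with no additional correction across clusters — matching
the emulated analysis; this is a known multiplicity caveat of the method,
not of this implementation.

## Clumping, annotation, profiles

Clumping is greedy over converged records with p < 5×10⁻⁸: the smallest-p
unassigned record becomes an index (ties by chromosome, position) and
absorbs unassigned significant records on the same chromosome within 250 kb
whose dosage r² with the index is ≥ 0.1 (composite LD — squared Pearson
correlation of dosage vectors, no phasing). r² and window defaults are
conservative PLINK-style choices and configurable; only the p threshold is
anchored. Clumping runs per cluster scan. Annotation is containment /
nearest-flank lookup against a BED gene model (0-based half-open on disk,
1-based closed internally); the function class (e.g. intronic,
ncRNA_intronic) passes through from the model's fifth column, intergenic
positions get both flanking symbols and chromosome ends a sentinel. The
cluster profile table reports per-cluster n, numeric means and categorical
level percentages, with an optional heatmap.

## Numerical and design notes

* One global seed fans out to per-stage seeds via a fixed SeedSequence
  derivation; identical configuration gives byte-identical TSV outputs.
* k-means initialization with fewer samples than clusters pads the
  centroids with jittered data points after a warning.
* Newton steps larger than 5 in either coordinate are damped to length 5;
  this stabilizes early iterations near separation without changing the
  converged solution.
* The Wald test is conservative at small counts (Hauck–Donner); with tiny
  clusters and rare variants, cluster-scan λ tends to sit slightly below 1.
* Problem sizes used in validation: null calibration at the full default
  scale (2,000/875, 20,000 variants, k = 40); power replicates at 250
  variants per replicate, since the genome-wide threshold is fixed and
  additional null variants add nothing to a detection experiment.

## Known limitations

Single-threaded CPU training only; no covariate adjustment, mixed models or
meta-analysis; no genotype imputation, liftover or relatedness inference;
annotation is interval lookup, not functional consequence prediction; the
simulator's subgroup model is an assumption, not an inference from data.
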