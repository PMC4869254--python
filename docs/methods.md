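# Methods

`renovar` analyses somatic single-nucleotide variation across multiple
clonally independent tumours per patient, the situation that arises in
von Hippel–Lindau (VHL) disease, where a germline *VHL* mutation
predisposes each kidney to many independent clear cell renal carcinomas.
Because genetic background and environment are held constant within a
patient, differences between tumours of one patient isolate stochastic
mutagenesis, while recurring within-patient patterns point to
patient-specific influences. This note documents the models, parameter
choices and numerical conventions behind each component, what the
synthetic cohort does and does not emulate, and the known limitations.

## Filtering cascade

Raw tumour-versus-normal SNV calls from a sensitive caller at ~38x
whole-genome coverage contain many artefacts. The cascade applies three
tiers, in order:

1. **Sample-level.** A call is kept iff tumour depth ≥ 14, normal depth
   ≥ 10, tumour VAF ≥ 10%, normal VAF ≤ 2%, and the site is not in the
   supplied known-SNP list. The published thresholds are worded as
   strict discard rules ("fewer than 14 reads", "<10%", ">2%"), so a
   call sitting exactly on a boundary is kept. The first failing rule is
   recorded as the call's fate.
2. **Dataset-level.** Uses variant-supporting read counts at the site in
   every cohort sample: (a) sites flagged as unstably aligned in more
   than half of samples are dropped; (b) so are sites with >10% VAF in
   an *uncalled* sample of another patient (both tumours and normals of
   other patients are screened — the narrower reading, tumours only, is
   not distinguishable from the source description); (c) remaining calls
   must beat the cross-patient background read rate under an exact
   upper-tail binomial test, P(X ≥ alt | depth, p_bg) ≤ 1e-8, where p_bg
   pools alt/total reads over all samples of *other* patients. With zero
   background depth p_bg = 0 and any variant read gives p = 0 (no
   pseudocount: the exact distribution, with no invented floor).
3. **Pipeline-level.** Intersection of the call sets from two
   independent pipeline versions, keyed by (sample, chrom, pos, ref,
   alt), carrying counts from the primary set.

The filter report keeps a monotone ledger (input → after sample-level →
after dataset-level → after pipeline-level) and a per-variant fate map.

## Purity estimation

For a nearly diploid tumour, clonal heterozygous somatic variants sit at
VAF ≈ purity/2. VAFs of filtered variants are binned into 20 equal-width
bins over [0, 1] (left-closed, last bin closed); the estimate is twice
the mean VAF of the most populated bin, clamped to 1. Ties between
equally populated bins break toward the lower bin — deterministic, and
biased *against* subclonal contamination inflating the estimate. The
bin-edge convention and tie-break are declared choices; they are not
derivable from the method's published description. At depth 38 with
2,000 variants the estimator's mean absolute error over purities
0.3–0.9 is ≈ 0.046, dominated by the half-bin-width discretisation
(0.025 in VAF = 0.05 in purity); it is slightly biased low, a direct
consequence of the lower-bin tie-break.

## Mutation spectra

Substitutions are collapsed onto a pyrimidine reference: a purine-ref
change is reverse-complemented (ref, alt and both flanks, flank order
swapped), giving 6 classes C>A, C>G, C>T, T>A, T>C, T>G and, with the
flanking bases, 96 trinucleotide contexts ordered class-major then 5'
A<C<G<T then 3' (the COSMIC layout, so external signature TSVs load
without remapping). For the clustered heat-map view, per-sample count
rows are converted to proportions and each context column is centred at
zero across samples; whether the original analysis also scaled columns
to unit variance is ambiguous, and proportions + centring is the
declared choice here. Tumours are clustered by average linkage on
correlation distance (1 − Pearson r between row profiles); the linkage
and distance are likewise unstated in the source and declared here as
the common choice for spectrum heat maps. Signature comparison offers
Spearman correlation (mid-ranks — 96-bin count vectors routinely tie)
and cosine similarity on proportion vectors.

## Within-patient similarity permutation test

The statistic is the mean over patients of the mean pairwise Spearman
correlation between the 96-context spectra of that patient's tumours;
averaging per patient first prevents patients with many tumours from
dominating. Patient labels are then permuted uniformly at random
(sampled with replacement from the permutation space, seed-controlled),
and p = #(permuted statistic **strictly** greater than observed)/n_perm.
The strict-inequality count reproduces the published arithmetic of the
original analysis (14 of 100,000 higher permutations → p = 0.00014); a
(count+1)/(n_perm+1) variant is available via `add_one=True` but is not
the default. Because sample ranks are invariant under relabelling, the
full pairwise Spearman matrix is computed once and each permutation
costs only submatrix averaging.

## Exact tail tests

* Whole-chr3-loss bias: P(X ≥ k) for X ~ Binomial(n, p) with the
  background rate p defaulting to 0.10, the approximate population
  frequency of whole-chromosome-3 loss in sporadic ccRCC. With k = 10 of
  n = 13 this gives 2.1e-8.
* Tree-half clustering: the probability that all n_group samples land in
  one *specified* half of size half_size, C(n_total − n_group,
  half_size − n_group)/C(n_total, half_size); no doubling for "either
  half" — the convention matched by the printed value
  C(27,7)/C(40,20) = 6.4e-6.
* Substitution-type differences between patients: classical one-way
  ANOVA per class on raw per-sample proportions (no transformation, no
  multiple-testing adjustment — unadjusted p-values are the reported
  quantity).

## Independence and kidney-specific variants

For each called variant, the number of same-patient tumours with ≥ 1
variant-supporting read determines exclusive versus read-sharing status;
1 read is the declared threshold for "found in" another tumour (the
shared signal of interest is explicitly "one or a few reads"). Variants
*called* in ≥ 2 tumours are classified against the patient's normals
with a 2-read threshold (more robust to sequencing error): present in
adjacent normal kidney but absent from blood → kidney-specific (an early
developmental variant, not tumour lineage); present in blood →
blood-present; otherwise tumour-shared-only. Without a kidney normal the
kidney/tumour distinction is flagged undetermined.

## Chromosome-3 classification

Per tumour, the fraction of each arm covered by loss-state segments is
computed from BED-convention segments against declared arm boundaries.
Whole-chromosome loss requires both arms ≥ 90% lost; p-arm loss requires
only p. The 0.9 threshold operationalises "complete loss" with tolerance
for segmentation edge noise; the source gives no numeric definition.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions
under which everything downstream is validated.

* **Cohort structure.** Six patients (three male, three female), ages
  22–60, contributing 5, 6, 5, 6, 5 and 13 tumours (40 total), each with
  a blood normal; three patients also have an adjacent normal kidney
  sample. Per-sample mean depth ~ Uniform(30, 47) (study range, mean
  ≈ 38x); per-tumour purity ~ Uniform(0.4, 0.9).
* **Mutation load.** Per-tumour somatic counts ~ Poisson(75 ·
  age_years · lognormal(0, 0.25)). The 75/year rate reproduces the
  study-scale range (~900–6,700 per tumour over ages 22–60, ~10^5
  cohort-wide) and plants the positive age correlation.
* **Spectra.** Each patient has a fixed 96-context probability vector:
  renal-typical class totals (C>T 0.35, T>C 0.28, C>A 0.14, T>A 0.10,
  C>G 0.09, T>G 0.04 — T>G rarest) with patient-specific Dirichlet flank
  structure; the 13-tumour patient carries a T>G-enriched profile
  (0.15), the planted within-patient signature effect.
* **Reads.** Total depth per variant per sample ~ Poisson(mean depth);
  variant reads ~ Binomial(depth, purity/2) in the originating tumour
  and Binomial(depth, 0.001) elsewhere (the low-level read-sharing
  background; configurable). Germline SNPs sit at VAF 0.5 in every
  sample of the patient; kidney-specific variants at VAF 0.5 in all
  kidney-derived samples and absent from blood. With probability 0.02 a
  somatic variant leaks 1–3 reads into one sibling tumour
  (cross-contamination; the real rate is unquantified, so this is a free
  parameter chosen once). Systematic error sites carry a shared per-site
  rate ~ Uniform(0.03, 0.15) across all samples; a subset is flagged
  unstably aligned. Somatic variants are placed only on diploid regions
  (a miniature chr1), keeping the purity estimator's diploid assumption
  valid.
* **Copy number.** Per tumour, whole-chr3 loss with the patient's
  propensity (10/13 for the 13-tumour patient, 0.08 otherwise), else
  3p-arm-only loss with probability 0.85, else neutral.
* **Reference.** A deterministic synthetic genome (~1 Mb: chr1 850 kb
  for variants, chr3 150 kb with p/q boundary at 60 kb) generated from a
  fixed internal seed, so trinucleotide contexts are computable offline;
  any FASTA can be substituted. Variant positions are drawn without
  replacement from pyrimidine-centred sites matching the drawn context.
* **Truth labels.** Every variant is labelled somatic_private,
  kidney_specific, germline_snp, sequencing_error or leaked, enabling
  exact precision/recall scoring of the cascade.

A companion generator, `simulate_normal_comparison`, emulates the
normal-versus-normal comparison in which every call is an artefact:
random-noise calls at error-prone sites with low-level background reads
in many samples, systematic error sites, cross-patient high-VAF sites,
known-SNP leak-through, and patient-private artefacts removable only by
pipeline intersection. Under the default mix the cascade ledger runs
~4,000 → ~1,500 → ~200 → ~40 and removes ≈ 99% of artefact calls.

**What the generator does not emulate:** alignment and caller behaviour
(mapping-quality structure, strand bias, indel-adjacent noise), GC- and
replication-timing-dependent mutation rates, subclonality, non-diploid
somatic regions, linked errors between the two pipeline versions beyond
a fixed retention probability, and realistic germline variant density
(only the SNPs that contaminate call sets are drawn). Passing tests
therefore demonstrate the pipeline's correctness and statistical
behaviour under the modelled structure, not performance on real
sequencing data. In particular, the simulated cohort's exclusive-variant
fraction (~77%) is below the ~90% seen in real data, because every
variant is given an independent 0.001 per-read background in every
sibling tumour — an intentionally conservative read-sharing model.

## Numerical and design choices

* All randomness flows from one integer seed per simulation or test;
  identical (config, seed) pairs give byte-identical cohorts and
  outputs.
* Binomial and hypergeometric tails are exact (scipy survival function /
  integer combinatorics), verified against exhaustive enumeration for
  n ≤ 12.
* Bin, threshold and boundary conventions: purity bins left-closed with
  closed last bin, lower-bin tie-break; filter thresholds keep boundary
  values; unstable-site majority is strictly more than half of samples.
* Degenerate inputs raise typed errors rather than returning NaN: empty
  VAF lists, constant vectors under Spearman/Pearson, single-patient
  permutation designs, zero-variance ANOVA, out-of-bounds segments.
* Default problem sizes are chosen for interactive use: simulated
  cohorts default to a 0.1 load scale (~11,000 calls) for `renovar run`,
  permutation tests to 10,000 draws, and the calibration check to 200
  replicates at 400 permutations; all are parameters, and the full
  study-scale cohort (scale 1.0, ~10^5 calls) runs in a few minutes.

## Limitations

* The cascade consumes caller output; it cannot recover variants the
  caller missed, and the pipeline-intersection tier inherits both
  pipelines' blind spots.
* The purity estimator assumes near-diploidy and clonal variants; it has
  a ~0.05 discretisation floor at 20 bins and is undefined for tumours
  with no filtered variants.
* The permutation p-value has resolution 1/n_perm and is 0 when no
  permutation exceeds the observed statistic; use `add_one=True` for a
  strictly positive estimate.
* The hypergeometric tree test conditions on a specified half of fixed
  size; it is not a general test of clustering quality.
* Kidney-specific classification requires an adjacent normal kidney
  sample; for patients without one the label set collapses and is
  flagged.
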