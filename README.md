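# renovar

Somatic-variation analysis of multiple independent tumours per patient.

Patients with von Hippel–Lindau (VHL) disease develop many clonally
independent clear cell renal carcinomas in the same genetic background
and environment. Comparing tumours *within* a patient therefore isolates
stochastic mutagenesis, while recurring within-patient patterns reveal
patient-specific influences on which mutations occur. `renovar` is a
tested, reusable implementation of that analysis for whole-genome
tumour/normal call sets, together with a fully ground-truth-labelled
synthetic cohort generator for validating every stage. It is aimed at
cancer-genomics analysts working with multi-tumour (multi-region or
multi-lesion) variant call sets.

## What it computes

* **Three-tier sSNV filter cascade** — sample-level read-count/VAF/SNP
  thresholds (tumour depth ≥ 14, normal depth ≥ 10, tumour VAF ≥ 10%,
  normal VAF ≤ 2%); dataset-level cross-sample screens including an
  exact upper-tail binomial test of variant reads against the pooled
  cross-patient background rate, P(X ≥ alt | depth, p_bg) ≤ 10⁻⁸; and the
  intersection of two pipeline versions' call sets. Emits a monotone
  count ledger and per-variant fates.
* **Tumour purity** — VAFs binned into 20 equal bins on [0, 1]; purity =
  2 × mean VAF of the most populated bin, clamped to 1.
* **Mutation spectra** — 6 pyrimidine-reference substitution classes and
  96 trinucleotide contexts (COSMIC ordering); row-normalised,
  column-centred spectrum matrices; average-linkage clustering on
  correlation distance; Spearman/cosine comparison to signature
  catalogues.
* **Within-patient similarity permutation test** — statistic = unweighted
  mean over patients of the mean pairwise Spearman correlation of
  96-context spectra; patient labels permuted, p = #(permuted > observed)/n_perm.
* **Clonal independence** — per-patient fraction of variants with reads
  in only one tumour; classification of variants called in ≥ 2 tumours
  as kidney-specific / blood-present / tumour-shared-only using the
  patient's normals.
* **Copy-number bias** — per-tumour chromosome-3 status (whole loss vs
  3p-arm loss) from BED segments, and an exact binomial census of
  whole-chr3 losses across a patient's tumours, P(X ≥ k | n, p₀ = 0.10).
* **Cohort statistics** — one-way ANOVA on substitution-type
  proportions, mutation load vs age correlation, and an exact
  hypergeometric test for all of a patient's samples falling in one half
  of a clustering tree, C(N−g, h−g)/C(N, h).

## Worked example

Simulate a six-patient, 40-tumour cohort (a 0.1-scale mutation load)
and run every stage:

```
$ renovar run --seed 7 --out-dir demo
INFO renovar.pipeline: simulated cohort: 11662 calls, 49 samples
INFO renovar.pipeline: filter ledger: 11662 -> 11099 -> 10967 -> 10760
{"filter_ledger": {"n_after_dataset": 10967, "n_after_pipeline": 10760,
  "n_after_sample": 11099, "n_input": 11662},
 "fraction_exclusive": 0.7696314875554698, "permutation_p": 0.0}
```

`demo/stats.json` then contains, among other stages:

```json
"permutation_test": {"observed_stat": 0.5798, "n_perm": 10000,
                     "n_higher": 0, "p_value": 0.0},
"age_correlation":  {"pearson_r": 0.7784, "spearman_r": 0.7971},
"chr3_census": {"F28green": {"whole_loss": 10, "n_tumours": 13,
                             "p_value": 2.1493e-08}}
```

Reading: the cascade removed all 170 injected germline-SNP and
sequencing-error calls while keeping >10,000 true somatic calls; no
random patient relabelling out of 10,000 produced spectra as similar
within patients as the true labelling (the planted patient-specific
spectra are detected); mutation load rises with patient age (r ≈ 0.78);
and 10 of the 13 tumours of patient F28green lost all of chromosome 3,
an excess with exact binomial tail probability 2.1 × 10⁻⁸ at a 10%
background rate.

Individual stages are available as subcommands (`simulate`, `filter`,
`purity`, `spectra`, `independence`, `stats`, `cnv`) and as library
functions:

```python
from renovar import binomial_enrichment_test, hypergeometric_half_tree_test
binomial_enrichment_test(10, 13, 0.10)        # 2.1e-08
hypergeometric_half_tree_test(40, 13, 20)     # 6.4e-06
```

## Layout

```
src/renovar/
  simulate.py      synthetic cohort + normal-vs-normal generators
  filtering.py     three-tier cascade, binomial background test
  purity.py        20-bin mode purity estimator
  spectra.py       6/96-context classification, signatures, clustering
  independence.py  read sharing, kidney-specific classification
  cohort_stats.py  permutation / binomial / hypergeometric / ANOVA / age tests
  cnv.py           chr3 status and loss census
  genome.py        synthetic reference and FASTA access
  io.py            VCF (pysam), TSV/BED/YAML readers and writers
  pipeline.py      end-to-end driver
  cli.py           `renovar` command
docs/methods.md    models, parameter choices, generator scope, limitations
```
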