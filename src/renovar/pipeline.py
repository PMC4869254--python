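"""End-to-end analysis driver.

Runs the whole study on a cohort (simulated or loaded): filter cascade,
per-tumour purity, 6-class and 96-context spectra with clustering and
the patient-label permutation test, ANOVA on substitution-type
proportions, mutation-load versus age correlation, cross-tumour read
sharing and multi-tumour variant classification, and the chromosome-3
whole-loss census. Every stage's inputs/outputs are logged and written
under the configured output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import independence, io
from .cnv import chr3_loss_census, classify_chr3_status
from .cohort_stats import (
    anova_type_proportions,
    permutation_similarity_test,
    snv_age_correlation,
)
from .filtering import run_cascade
from .purity import estimate_purity
from .simulate import (
    SimulatedCohort,
    build_read_matrix,
    default_cohort_config,
    second_pipeline_calls,
    simulate_cohort,
)
from .spectra import (
    CLASSES6,
    build_spectrum,
    cluster_samples,
    normalize_center,
    spectra_to_frame,
)

logger = logging.getLogger(__name__)


def run_full_analysis(config: io.RunConfig, cohort: SimulatedCohort | None = None) -> dict:
    """Execute every analysis stage; returns the results bundle as a dict.

    With no cohort supplied, one is simulated from the default
    study-shaped configuration at ``config.simulate_scale`` using
    ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        cohort = simulate_cohort(
            default_cohort_config(scale=config.simulate_scale), seed=config.seed
        )
        logger.info("simulated cohort: %d calls, %d samples",
                    len(cohort.calls), len(cohort.read_matrix.samples))

    matrix = build_read_matrix(cohort)
    calls_b = second_pipeline_calls(cohort, seed=config.seed + 1)
    final, report = run_cascade(cohort.calls, calls_b, matrix, config.filter)
    logger.info(
        "filter ledger: %d -> %d -> %d -> %d",
        report.n_input, report.n_after_sample, report.n_after_dataset,
        report.n_after_pipeline,
    )
    io.write_filter_report(report, out / "filter_report.tsv")
    io.write_read_matrix(matrix, out / "read_matrix.tsv")
    io.write_sample_metadata(matrix, out / "samples.tsv")
    io.write_truth_labels(cohort.truth, out / "truth_labels.tsv")
    io.write_snp_list(cohort.snp_sites, out / "snp_sites.tsv")
    io.write_segments_bed(cohort.segments, out / "segments.bed")

    # ---- purity -------------------------------------------------------
    purity_rows = []
    by_sample: dict[str, list] = {}
    for c in final:
        by_sample.setdefault(c.sample_id, []).append(c)
    for tid in sorted(cohort.tumour_params):
        calls_t = by_sample.get(tid, [])
        vafs = [c.tumour_vaf for c in calls_t if c.tumour_vaf > 0]
        if not vafs:
            continue
        est = estimate_purity(vafs, n_bins=config.purity_n_bins)
        purity_rows.append(
            dict(sample=tid, purity=est.purity, mode_bin=est.mode_bin_index,
                 n_mode=est.n_variants_in_mode_bin, n_total=est.n_variants_total,
                 true_purity=cohort.tumour_params[tid].purity)
        )
    purity_df = pd.DataFrame(purity_rows)
    purity_df.to_csv(out / "purity.tsv", sep="\t", index=False)

    # ---- spectra ------------------------------------------------------
    spectra = build_spectrum(final, cohort.genome)
    counts = spectra_to_frame(spectra)
    counts.to_csv(out / "spectra96.tsv", sep="\t", index_label="sample")
    centered = normalize_center(counts)
    linkage, leaves = cluster_samples(centered)
    np.savetxt(out / "linkage.tsv", linkage, delimiter="\t")

    patient_of = matrix.patient_of
    labels = [patient_of[s] for s in counts.index]
    perm = permutation_similarity_test(
        counts, labels, n_perm=config.n_perm, seed=config.seed
    )

    props6 = pd.DataFrame(
        {s: spectra[s].counts6 / max(spectra[s].total, 1) for s in counts.index},
        index=list(CLASSES6),
    ).T
    anova = anova_type_proportions(props6, labels)
    anova.to_csv(out / "anova_type_proportions.tsv", sep="\t", index_label="class")

    # ---- mutation load vs age ----------------------------------------
    age_of = {p.patient_id: p.age_years for p in cohort.patients}
    load = [len(by_sample.get(t, [])) for t in counts.index]
    ages = [age_of[patient_of[t]] for t in counts.index]
    r_pearson, p_pearson = snv_age_correlation(load, ages, method="pearson")
    r_spearman, p_spearman = snv_age_correlation(load, ages, method="spearman")

    # ---- independence -------------------------------------------------
    final_matrix = io_matrix_with_final_calls(matrix, final)
    sharing = independence.read_sharing_summary(
        final_matrix, min_evidence_reads=config.sharing_min_reads
    )
    frac_excl = independence.cohort_fraction_exclusive(sharing)
    pd.DataFrame(
        [
            dict(patient=s.patient_id, n_variants=s.n_variants,
                 n_exclusive=s.n_exclusive, n_shared_reads=s.n_shared_reads,
                 n_called_multi=s.n_called_multi,
                 fraction_exclusive=s.fraction_exclusive)
            for s in sharing.values()
        ]
    ).to_csv(out / "sharing_summary.tsv", sep="\t", index=False)

    multi_labels = {}
    blood_of = cohort.blood_sample_of
    kidney_of = cohort.kidney_normal_of
    tumours_of: dict[str, list[str]] = {}
    for s in final_matrix.samples:
        if final_matrix.sample_type.get(s) == "tumour":
            tumours_of.setdefault(patient_of[s], []).append(s)
    called_by_site: dict[tuple, set] = {}
    for c in final:
        called_by_site.setdefault(c.site, set()).add(c.sample_id)
    for site, callers in called_by_site.items():
        for pid, tums in tumours_of.items():
            if len(callers & set(tums)) >= 2:
                lab = independence.classify_multi_tumour_variant(
                    site, final_matrix, blood_of[pid], kidney_of.get(pid),
                    min_evidence_reads=config.normal_presence_min_reads,
                )
                multi_labels["|".join(map(str, site))] = lab.label

    # ---- chromosome 3 -------------------------------------------------
    statuses = {
        tid: classify_chr3_status(
            segs, cohort.arm_boundaries,
            loss_fraction_threshold=config.chr3_loss_threshold, sample_id=tid,
        )
        for tid, segs in cohort.segments.items()
    }
    census = {}
    for pid, tums in tumours_of.items():
        k, n, p = chr3_loss_census(
            [statuses[t] for t in tums if t in statuses],
            background_whole_loss_rate=config.chr3_background_rate,
        )
        census[pid] = dict(whole_loss=k, n_tumours=n, p_value=p)

    results = {
        "seed": config.seed,
        "filter_ledger": {
            "n_input": report.n_input,
            "n_after_sample": report.n_after_sample,
            "n_after_dataset": report.n_after_dataset,
            "n_after_pipeline": report.n_after_pipeline,
        },
        "purity": {r["sample"]: r["purity"] for r in purity_rows},
        "permutation_test": {
            "observed_stat": perm.observed_stat,
            "n_perm": perm.n_perm,
            "n_higher": perm.n_at_least_as_extreme,
            "p_value": perm.p_value,
        },
        "anova": {cls: dict(F=row["F"], p_value=row["p_value"])
                  for cls, row in anova.iterrows()},
        "age_correlation": {
            "pearson_r": r_pearson, "pearson_p": p_pearson,
            "spearman_r": r_spearman, "spearman_p": p_spearman,
        },
        "sharing": {
            "fraction_exclusive": frac_excl,
            "n_called_multi": int(sum(s.n_called_multi for s in sharing.values())),
        },
        "multi_tumour_labels": multi_labels,
        "chr3_census": census,
        "n_clustered_samples": len(leaves),
    }
    (out / "stats.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    return results


def io_matrix_with_final_calls(matrix, final_calls):
    """Copy of the read matrix whose called flags reflect the filtered set."""
    from .filtering import CrossSampleReadMatrix

    m = CrossSampleReadMatrix(
        variants=list(matrix.variants),
        samples=list(matrix.samples),
        patient_of=dict(matrix.patient_of),
        alt_reads=matrix.alt_reads.copy(),
        total_reads=matrix.total_reads.copy(),
        called=np.zeros_like(matrix.called),
        unstable=None if matrix.unstable is None else matrix.unstable.copy(),
        sample_type=dict(matrix.sample_type),
    )
    io.mark_called(m, final_calls)
    return m
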