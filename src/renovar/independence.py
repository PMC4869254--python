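"""Clonal independence from cross-tumour read sharing.

If two tumours in a patient descended from one clone they would share a
large fraction of somatic variants. Independence is quantified by
asking, for every called variant, how many tumours of the same patient
carry any variant-supporting reads: variants with reads in exactly one
tumour are *exclusive*; the remainder share reads (usually only one or a
few, consistent with contamination or sequencing error rather than
lineage). Variants actually *called* in two or more tumours are further
classified against the patient's normals: present in kidney normal but
not blood means a kidney-developmental (kidney-specific) variant rather
than a tumour-lineage one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filtering import CrossSampleReadMatrix, StructuralError

LABEL_KIDNEY = "kidney_specific"
LABEL_BLOOD = "blood_present"
LABEL_TUMOUR_ONLY = "tumour_shared_only"


@dataclass(frozen=True)
class SharingSummary:
    patient_id: str
    n_variants: int
    n_exclusive: int
    n_shared_reads: int
    n_called_multi: int

    @property
    def fraction_exclusive(self) -> float:
        return self.n_exclusive / self.n_variants if self.n_variants else float("nan")


@dataclass(frozen=True)
class MultiTumourLabel:
    label: str
    kidney_undetermined: bool = False


def _tumour_columns(matrix: CrossSampleReadMatrix, patient: str) -> np.ndarray:
    cols = []
    for j, s in enumerate(matrix.samples):
        if matrix.patient_of[s] != patient:
            continue
        if matrix.sample_type and matrix.sample_type.get(s) != "tumour":
            continue
        cols.append(j)
    return np.array(cols, dtype=int)


def read_sharing_summary(
    matrix: CrossSampleReadMatrix,
    patient_of: dict[str, str] | None = None,
    min_evidence_reads: int = 1,
) -> dict[str, SharingSummary]:
    """Per-patient exclusivity tally over all called variants.

    A variant belongs to the patient(s) in which it was called; it is
    exclusive if variant reads (>= ``min_evidence_reads``) appear in only
    one tumour of that patient. ``n_called_multi`` counts variants called
    in >= 2 tumours of the patient.
    """
    patient_of = patient_of or matrix.patient_of
    missing = [s for s in matrix.samples if s not in patient_of]
    if missing:
        raise StructuralError(f"samples without patient mapping: {missing}")
    patients = sorted({patient_of[s] for s in matrix.samples})
    out = {}
    for p in patients:
        cols = _tumour_columns(matrix, p)
        if cols.size == 0:
            continue
        called_here = matrix.called[:, cols]
        rows = np.nonzero(called_here.any(axis=1))[0]
        if rows.size == 0:
            out[p] = SharingSummary(p, 0, 0, 0, 0)
            continue
        evident = matrix.alt_reads[np.ix_(rows, cols)] >= min_evidence_reads
        n_tumours_with_reads = evident.sum(axis=1)
        n_excl = int((n_tumours_with_reads <= 1).sum())
        n_multi = int((called_here[rows].sum(axis=1) >= 2).sum())
        out[p] = SharingSummary(
            patient_id=p,
            n_variants=int(rows.size),
            n_exclusive=n_excl,
            n_shared_reads=int(rows.size) - n_excl,
            n_called_multi=n_multi,
        )
    return out


def cohort_fraction_exclusive(summaries: dict[str, SharingSummary]) -> float:
    """Overall fraction of called variants with reads in only one tumour."""
    n = sum(s.n_variants for s in summaries.values())
    k = sum(s.n_exclusive for s in summaries.values())
    return k / n if n else float("nan")


def classify_multi_tumour_variant(
    variant_key: tuple,
    matrix: CrossSampleReadMatrix,
    blood_sample: str,
    kidney_normal_sample: str | None = None,
    min_evidence_reads: int = 2,
) -> MultiTumourLabel:
    """Label a variant called in >= 2 tumours by its presence in the normals.

    kidney_specific: evident in adjacent normal kidney but not blood;
    blood_present: evident in blood; tumour_shared_only: neither. Without
    a kidney normal the kidney/tumour distinction is undetermined and the
    label is restricted to blood_present / tumour_shared_only.
    """
    i = matrix.row_index(variant_key)
    blood_alt = matrix.alt_reads[i, matrix.col_index(blood_sample)]
    in_blood = blood_alt >= min_evidence_reads
    if kidney_normal_sample is None:
        label = LABEL_BLOOD if in_blood else LABEL_TUMOUR_ONLY
        return MultiTumourLabel(label, kidney_undetermined=not in_blood)
    kidney_alt = matrix.alt_reads[i, matrix.col_index(kidney_normal_sample)]
    if in_blood:
        return MultiTumourLabel(LABEL_BLOOD)
    if kidney_alt >= min_evidence_reads:
        return MultiTumourLabel(LABEL_KIDNEY)
    return MultiTumourLabel(LABEL_TUMOUR_ONLY)
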