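"""Three-tier somatic SNV filtering cascade.

Raw caller output from a ~38x tumour/normal whole-genome comparison is
noisy; the cascade reduces it to a high-confidence call set in three
stages:

1. **Sample-level** — per-call read-count thresholds (tumour depth >= 14,
   normal depth >= 10, tumour VAF >= 10%, normal VAF <= 2%) and exclusion
   of known-SNP sites.
2. **Dataset-level** — uses variant-supporting read counts at the same
   site across *every* sample in the cohort: sites that cannot be
   reliably quantified in most samples (unstable alignments) are dropped,
   as are sites seen at >10% VAF in an uncalled sample of another
   patient, and sites whose variant reads do not exceed the cross-patient
   background read rate under an exact upper-tail binomial test at
   p <= 1e-8.
3. **Pipeline-level** — intersection of the call sets produced by two
   independent pipeline versions.

Boundary conventions follow the thresholds' wording literally: "fewer
than 14 reads", "<10% variant reads", ">2% variant reads" are strict, so
a call sitting exactly on a threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

VALID_BASES = frozenset("ACGT")

# fate codes recorded in FilterReport.per_variant_fate
KEPT = "kept"
FATE_TUMOUR_DEPTH = "low_tumour_depth"
FATE_NORMAL_DEPTH = "low_normal_depth"
FATE_TUMOUR_VAF = "low_tumour_vaf"
FATE_NORMAL_VAF = "high_normal_vaf"
FATE_SNP = "snp_site"
FATE_UNSTABLE = "unstable_site"
FATE_OTHER_PATIENT_VAF = "other_patient_vaf"
FATE_BACKGROUND = "background_binomial"
FATE_NOT_IN_OTHER_PIPELINE = "not_in_other_pipeline"


class InvalidConfigError(ValueError):
    pass


class StructuralError(KeyError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic SNV in one tumour, with tumour/normal counts."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumour_total: int
    tumour_alt: int
    normal_total: int
    normal_alt: int
    is_snp_site: bool = False
    unstable_alignment: bool = False

    def __post_init__(self):
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-ACGT alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if not (0 <= self.tumour_alt <= self.tumour_total):
            raise ValueError("tumour_alt outside [0, tumour_total]")
        if not (0 <= self.normal_alt <= self.normal_total):
            raise ValueError("normal_alt outside [0, normal_total]")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumour_vaf(self) -> float:
        return self.tumour_alt / self.tumour_total if self.tumour_total else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_total if self.normal_total else 0.0


@dataclass
class CrossSampleReadMatrix:
    """Per-variant, per-sample variant-supporting and total read counts.

    Rows are variant sites (chrom, pos, ref, alt); columns are every
    sample in the cohort (tumours and normals). ``patient_of`` maps each
    sample to its patient, ``sample_type`` (optional) to one of
    ``tumour``/``blood``/``kidney_normal``.
    """

    variants: list[tuple]
    samples: list[str]
    patient_of: dict[str, str]
    alt_reads: np.ndarray
    total_reads: np.ndarray
    called: np.ndarray
    unstable: np.ndarray | None = None
    sample_type: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
        self.total_reads = np.asarray(self.total_reads, dtype=np.int64)
        self.called = np.asarray(self.called, dtype=bool)
        shape = (len(self.variants), len(self.samples))
        for name in ("alt_reads", "total_reads", "called"):
            if getattr(self, name).shape != shape:
                raise InvalidConfigError(f"{name} shape != {shape}")
        if (self.alt_reads < 0).any() or (self.alt_reads > self.total_reads).any():
            raise InvalidConfigError("alt_reads must satisfy 0 <= alt <= total")
        if (self.called & (self.total_reads == 0)).any():
            raise InvalidConfigError("called cell with zero total reads")
        missing = [s for s in self.samples if s not in self.patient_of]
        if missing:
            raise StructuralError(f"samples without patient mapping: {missing}")
        self._row = {v: i for i, v in enumerate(self.variants)}
        self._col = {s: j for j, s in enumerate(self.samples)}

    def row_index(self, site: tuple) -> int:
        try:
            return self._row[site]
        except KeyError:
            raise StructuralError(f"site {site} missing from read matrix") from None

    def col_index(self, sample: str) -> int:
        try:
            return self._col[sample]
        except KeyError:
            raise StructuralError(f"sample {sample} missing from read matrix") from None

    def columns_of_other_patients(self, patient: str) -> np.ndarray:
        return np.array(
            [j for j, s in enumerate(self.samples) if self.patient_of[s] != patient],
            dtype=int,
        )


@dataclass
class FilterConfig:
    """Numeric thresholds of the cascade (defaults as published)."""

    min_tumour_depth: int = 14
    min_normal_depth: int = 10
    min_tumour_vaf: float = 0.10
    max_normal_vaf: float = 0.02
    other_patient_vaf_cutoff: float = 0.10
    binomial_p_cutoff: float = 1e-8
    unstable_majority_fraction: float = 0.5

    def __post_init__(self):
        if self.min_tumour_depth <= 0 or self.min_normal_depth <= 0:
            raise InvalidConfigError("depth thresholds must be positive")
        for name in (
            "min_tumour_vaf",
            "max_normal_vaf",
            "other_patient_vaf_cutoff",
            "unstable_majority_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InvalidConfigError(f"{name} must lie in (0, 1)")
        if self.binomial_p_cutoff <= 0:
            raise InvalidConfigError("binomial_p_cutoff must be positive")


@dataclass
class FilterReport:
    """Monotone count ledger of the cascade plus per-variant fates."""

    n_input: int = 0
    n_after_sample: int = 0
    n_after_dataset: int = 0
    n_after_pipeline: int = 0
    per_variant_fate: dict = field(default_factory=dict)

    def validate(self) -> None:
        ledger = (
            self.n_input,
            self.n_after_sample,
            self.n_after_dataset,
            self.n_after_pipeline,
        )
        if any(a < b for a, b in zip(ledger, ledger[1:])) or ledger[-1] < 0:
            raise AssertionError(f"non-monotone filter ledger {ledger}")


def sample_level_filter(
    calls: list[VariantCall], cfg: FilterConfig | None = None
) -> tuple[list[VariantCall], dict]:
    """Apply per-sample read-count thresholds and SNP exclusion.

    Returns the kept calls and a fate map recording, for each discarded
    call, the first rule it failed.
    """
    cfg = cfg or FilterConfig()
    kept, fates = [], {}
    for c in calls:
        if c.tumour_total < cfg.min_tumour_depth:
            fates[c.key] = FATE_TUMOUR_DEPTH
        elif c.normal_total < cfg.min_normal_depth:
            fates[c.key] = FATE_NORMAL_DEPTH
        elif c.tumour_vaf < cfg.min_tumour_vaf:
            fates[c.key] = FATE_TUMOUR_VAF
        elif c.normal_vaf > cfg.max_normal_vaf:
            fates[c.key] = FATE_NORMAL_VAF
        elif c.is_snp_site:
            fates[c.key] = FATE_SNP
        else:
            fates[c.key] = KEPT
            kept.append(c)
    return kept, fates


def background_binomial_pvalue(
    alt_in_caller: int,
    depth_in_caller: int,
    alt_other_patients: int,
    depth_other_patients: int,
) -> float:
    """Exact upper-tail binomial test of variant reads against background.

    The background rate is the pooled variant-read fraction at the site in
    samples from other patients; returns P(X >= alt_in_caller) for
    X ~ Binomial(depth_in_caller, background rate). With zero background
    depth the rate is 0, so any variant read gives p = 0.
    """
    if depth_in_caller <= 0:
        raise ValueError("depth_in_caller must be positive")
    if not (0 <= alt_in_caller <= depth_in_caller):
        raise ValueError("alt_in_caller outside [0, depth_in_caller]")
    if depth_other_patients < 0 or not (0 <= alt_other_patients <= max(depth_other_patients, 0)):
        raise ValueError("invalid background counts")
    p_bg = alt_other_patients / depth_other_patients if depth_other_patients > 0 else 0.0
    return float(stats.binom.sf(alt_in_caller - 1, depth_in_caller, p_bg))


def dataset_level_filter(
    calls: list[VariantCall],
    matrix: CrossSampleReadMatrix,
    cfg: FilterConfig | None = None,
) -> tuple[list[VariantCall], dict]:
    """Apply cross-sample filters: unstable sites, cross-patient VAF, binomial.

    Checks run in that order per call and the first failure is recorded.
    """
    cfg = cfg or FilterConfig()
    kept, fates = [], {}
    n_samples = len(matrix.samples)
    for c in calls:
        i = matrix.row_index(c.site)
        other = matrix.columns_of_other_patients(matrix.patient_of.get(c.sample_id, c.sample_id))
        if matrix.unstable is not None and (
            matrix.unstable[i].sum() > cfg.unstable_majority_fraction * n_samples
        ):
            fates[c.key] = FATE_UNSTABLE
            continue
        alt_o = matrix.alt_reads[i, other]
        tot_o = matrix.total_reads[i, other]
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf_o = np.where(tot_o > 0, alt_o / np.maximum(tot_o, 1), 0.0)
        uncalled = ~matrix.called[i, other]
        if bool(((vaf_o > cfg.other_patient_vaf_cutoff) & uncalled).any()):
            fates[c.key] = FATE_OTHER_PATIENT_VAF
            continue
        p = background_binomial_pvalue(
            c.tumour_alt, c.tumour_total, int(alt_o.sum()), int(tot_o.sum())
        )
        if p > cfg.binomial_p_cutoff:
            fates[c.key] = FATE_BACKGROUND
        else:
            fates[c.key] = KEPT
            kept.append(c)
    return kept, fates


def pipeline_level_filter(
    calls_a: list[VariantCall], calls_b: list[VariantCall]
) -> list[VariantCall]:
    """Intersection of two pipelines' call sets, keeping counts from the first."""
    keys_b = {c.key for c in calls_b}
    return [c for c in calls_a if c.key in keys_b]


def run_cascade(
    calls_a: list[VariantCall],
    calls_b: list[VariantCall],
    matrix: CrossSampleReadMatrix,
    cfg: FilterConfig | None = None,
) -> tuple[list[VariantCall], FilterReport]:
    """Full cascade: sample-level, dataset-level, then pipeline intersection.

    Both pipelines' call lists go through the first two tiers
    independently; the ledger counts follow the primary (``calls_a``)
    path.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(calls_a))

    kept_a, fates_a = sample_level_filter(calls_a, cfg)
    kept_b, _ = sample_level_filter(calls_b, cfg)
    report.n_after_sample = len(kept_a)
    report.per_variant_fate.update(fates_a)

    kept_a, fates_a2 = dataset_level_filter(kept_a, matrix, cfg)
    kept_b, _ = dataset_level_filter(kept_b, matrix, cfg)
    report.n_after_dataset = len(kept_a)
    report.per_variant_fate.update(fates_a2)

    final = pipeline_level_filter(kept_a, kept_b)
    report.n_after_pipeline = len(final)
    final_keys = {c.key for c in final}
    for c in kept_a:
        report.per_variant_fate[c.key] = (
            KEPT if c.key in final_keys else FATE_NOT_IN_OTHER_PIPELINE
        )
    report.validate()
    return final, report
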