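"""Synthetic multi-tumour cohort generator with ground-truth labels.

Emulates the statistical structure of a multi-patient, multi-tumour
whole-genome study of independent renal tumours: several patients, each
contributing 5–13 clonally independent tumours plus a blood normal (and
for some patients an adjacent normal kidney sample), sequenced at
~30–47x. Per tumour, somatic-private variants arise at a rate
proportional to patient age, with trinucleotide contexts drawn from a
patient-specific 96-context spectrum; read counts follow
Binomial(depth, purity/2) in the originating tumour and a low per-read
error rate elsewhere. The generator also injects the artefact classes
the filtering cascade exists to remove — germline SNP contamination,
systematic sequencing-error sites with reads shared across samples,
low-level cross-tumour read leakage — plus kidney-specific
(blood-absent) developmental variants and arm-level versus
whole-chromosome copy-number losses with a patient-specific
whole-chr3-loss propensity. Every injected variant carries a truth
label, so filter precision/recall and downstream analyses can be scored
exactly.

All randomness flows from a single integer seed; the same (config, seed)
pair reproduces the cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnv import ArmBoundaries, CNSegment
from .filtering import CrossSampleReadMatrix, InvalidConfigError, StructuralError, VariantCall
from .genome import BASES, Genome, pyrimidine_site_index, synthetic_genome
from .spectra import CLASSES6

# truth labels
SOMATIC_PRIVATE = "somatic_private"
KIDNEY_SPECIFIC = "kidney_specific"
GERMLINE_SNP = "germline_snp"
SEQUENCING_ERROR = "sequencing_error"
LEAKED = "leaked"

#: internal seed offset for patient spectrum construction; spectra are part
#: of the cohort's fixed conditions, not of the per-run randomness.
_SPECTRUM_SEED_BASE = 777_000


@dataclass
class PatientProfile:
    """Per-patient simulation factors."""

    patient_id: str
    age_years: float
    n_tumours: int
    spectrum_weights: np.ndarray  # 96-vector summing to 1
    chr3_whole_loss_prob: float = 0.08
    has_normal_kidney: bool = False
    germline_snp_count: int = 200
    kidney_specific_variant_count: int = 12

    def __post_init__(self):
        self.spectrum_weights = np.asarray(self.spectrum_weights, dtype=float)
        if self.age_years <= 0 or self.n_tumours <= 0:
            raise InvalidConfigError("age and tumour count must be positive")
        if self.spectrum_weights.shape != (96,) or (self.spectrum_weights < 0).any():
            raise InvalidConfigError("spectrum_weights must be a non-negative 96-vector")
        if abs(self.spectrum_weights.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("spectrum_weights must sum to 1")
        if not (0 <= self.chr3_whole_loss_prob <= 1):
            raise InvalidConfigError("chr3_whole_loss_prob must lie in [0, 1]")
        if self.germline_snp_count < 0 or self.kidney_specific_variant_count < 0:
            raise InvalidConfigError("variant counts must be non-negative")


@dataclass
class TumourSimParams:
    tumour_id: str
    purity: float
    mean_depth: float
    expected_mutation_count: float
    contamination_rate: float

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise InvalidConfigError("purity must lie in (0, 1]")
        if self.mean_depth <= 0 or self.expected_mutation_count <= 0:
            raise InvalidConfigError("depth and mutation count must be positive")
        if not (0 <= self.contamination_rate <= 1):
            raise InvalidConfigError("contamination_rate must lie in [0, 1]")


@dataclass
class CohortConfig:
    """All simulation parameters; defaults are the study-scale conditions."""

    patients: list[PatientProfile]
    mean_depth_range: tuple[float, float] = (30.0, 47.0)
    purity_range: tuple[float, float] = (0.4, 0.9)
    mutations_per_year: float = 75.0
    load_jitter_sd: float = 0.25  # lognormal sd of per-tumour load around age trend
    contamination_rate: float = 0.02
    error_read_rate: float = 0.001
    n_error_sites: int = 500
    error_site_rate_range: tuple[float, float] = (0.03, 0.15)
    n_unstable_sites: int = 30
    arm_loss_prob: float = 0.85  # P(3p-only loss | no whole-chr3 loss)
    somatic_contig: str = "chr1"
    genome: Genome | None = None
    arm_boundaries: ArmBoundaries = field(
        default_factory=lambda: ArmBoundaries("chr3", 0, 60_000, 150_000)
    )

    def __post_init__(self):
        if len(self.patients) < 2 or any(p.n_tumours < 2 for p in self.patients):
            raise InvalidConfigError("need >= 2 patients with >= 2 tumours each")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise InvalidConfigError("duplicate patient ids")
        if self.mutations_per_year <= 0 or self.error_read_rate < 0:
            raise InvalidConfigError("rates must be positive")
        if self.n_error_sites < 0 or self.n_unstable_sites < 0:
            raise InvalidConfigError("site counts must be non-negative")


@dataclass
class SimulatedCohort:
    patients: list[PatientProfile]
    tumour_params: dict[str, TumourSimParams]
    calls: list[VariantCall]
    read_matrix: CrossSampleReadMatrix
    segments: dict[str, list[CNSegment]]
    truth: dict[tuple, str]
    snp_sites: set[tuple]
    sample_type: dict[str, str]
    genome: Genome
    arm_boundaries: ArmBoundaries
    seed: int

    @property
    def blood_sample_of(self) -> dict[str, str]:
        return {
            self.read_matrix.patient_of[s]: s
            for s in self.read_matrix.samples
            if self.sample_type.get(s) == "blood"
        }

    @property
    def kidney_normal_of(self) -> dict[str, str]:
        return {
            self.read_matrix.patient_of[s]: s
            for s in self.read_matrix.samples
            if self.sample_type.get(s) == "kidney_normal"
        }


def patient_spectrum_weights(index: int, t_g_enriched: bool = False) -> np.ndarray:
    """Deterministic patient-specific 96-context weights.

    Class totals follow typical renal-tumour proportions (C>T and T>C
    dominate, T>G rarest); ``t_g_enriched`` raises the T>G share, the
    planted patient-specific effect. Within each class the 16 flank
    combinations get a patient-specific Dirichlet draw from a fixed
    internal seed, so profiles are stable across runs and distinct across
    patients.
    """
    class_totals = (
        np.array([0.12, 0.08, 0.30, 0.09, 0.26, 0.15])
        if t_g_enriched
        else np.array([0.14, 0.09, 0.35, 0.10, 0.28, 0.04])
    )
    rng = np.random.default_rng(_SPECTRUM_SEED_BASE + index)
    parts = [total * rng.dirichlet(np.full(16, 8.0)) for total in class_totals]
    w = np.concatenate(parts)
    return w / w.sum()


def default_patient_profiles() -> list[PatientProfile]:
    """Six-patient cohort: three males, three females, ages 22–60, 5–13 tumours.

    One young female patient contributes 13 tumours and carries a strong
    whole-chr3-loss propensity (10/13) and a T>G-enriched spectrum; three
    patients have adjacent normal kidney tissue.
    """
    rows = [
        # id, age, n_tumours, kidney_normal, chr3_whole_loss_prob, tg
        ("M45orange", 45, 5, True, 0.08, False),
        ("M28purple", 28, 6, True, 0.08, False),
        ("M22red", 22, 5, False, 0.08, False),
        ("F60yellow", 60, 6, False, 0.08, False),
        ("F58blue", 58, 5, True, 0.08, False),
        ("F28green", 28, 13, False, 10 / 13, True),
    ]
    return [
        PatientProfile(
            patient_id=pid,
            age_years=age,
            n_tumours=n,
            spectrum_weights=patient_spectrum_weights(i, t_g_enriched=tg),
            chr3_whole_loss_prob=p3,
            has_normal_kidney=kn,
        )
        for i, (pid, age, n, kn, p3, tg) in enumerate(rows)
    ]


def default_cohort_config(scale: float = 1.0, **overrides) -> CohortConfig:
    """Study-scale config, optionally scaled down in mutation load.

    ``scale`` multiplies per-tumour mutation loads and artefact-site
    counts only; cohort structure (patients, depths, purities) is
    unchanged, so scaled cohorts keep the same statistical shape at lower
    cost.
    """
    if scale <= 0:
        raise InvalidConfigError("scale must be positive")
    patients = default_patient_profiles()
    for p in patients:
        p.germline_snp_count = max(2, round(p.germline_snp_count * scale))
    cfg = dict(
        patients=patients,
        mutations_per_year=75.0 * scale,
        n_error_sites=max(10, round(500 * scale)),
        n_unstable_sites=max(2, round(30 * scale)),
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)


class _PositionAllocator:
    """Draws unique variant positions whose trinucleotide matches a context."""

    def __init__(self, genome: Genome, contig: str, rng: np.random.Generator):
        self._pools = {}
        self._ptr = {}
        for trinuc, pos in pyrimidine_site_index(genome, contig).items():
            p = pos.copy()
            rng.shuffle(p)
            self._pools[trinuc] = p
            self._ptr[trinuc] = 0

    def take(self, trinuc: str) -> int:
        i = self._ptr[trinuc]
        pool = self._pools[trinuc]
        if i >= len(pool):
            raise InvalidConfigError(
                f"reference exhausted for context {trinuc}; use a larger genome"
            )
        self._ptr[trinuc] = i + 1
        return int(pool[i])


def _context_to_alleles(ctx: int) -> tuple[str, str, str]:
    """96-context index -> (trinucleotide, ref, alt)."""
    cls, rem = divmod(ctx, 16)
    f, t = divmod(rem, 4)
    ref, alt = CLASSES6[cls][0], CLASSES6[cls][2]
    return BASES[f] + ref + BASES[t], ref, alt


def simulate_cohort(config: CohortConfig, seed: int) -> SimulatedCohort:
    """Generate a full cohort: variants, read matrix, calls, segments, truth."""
    rng = np.random.default_rng(seed)
    genome = config.genome or synthetic_genome()
    contig = config.somatic_contig
    alloc = _PositionAllocator(genome, contig, rng)

    # ---- samples -----------------------------------------------------
    samples: list[str] = []
    patient_of: dict[str, str] = {}
    sample_type: dict[str, str] = {}
    tumour_params: dict[str, TumourSimParams] = {}
    tumour_cols: dict[str, list[int]] = {}
    blood_col: dict[str, int] = {}
    kidney_col: dict[str, int] = {}

    def _add(sid, pid, stype):
        if sid in patient_of:
            raise InvalidConfigError(f"duplicate sample id {sid}")
        samples.append(sid)
        patient_of[sid] = pid
        sample_type[sid] = stype
        return len(samples) - 1

    for prof in config.patients:
        pid = prof.patient_id
        tumour_cols[pid] = []
        for k in range(1, prof.n_tumours + 1):
            tid = f"{pid}-T{k}"
            col = _add(tid, pid, "tumour")
            tumour_cols[pid].append(col)
            tumour_params[tid] = TumourSimParams(
                tumour_id=tid,
                purity=float(rng.uniform(*config.purity_range)),
                mean_depth=float(rng.uniform(*config.mean_depth_range)),
                expected_mutation_count=float(
                    config.mutations_per_year
                    * prof.age_years
                    * rng.lognormal(0.0, config.load_jitter_sd)
                ),
                contamination_rate=config.contamination_rate,
            )
        blood_col[pid] = _add(f"{pid}-BL", pid, "blood")
        if prof.has_normal_kidney:
            kidney_col[pid] = _add(f"{pid}-KN", pid, "kidney_normal")

    n_samples = len(samples)
    depth_mean = np.empty(n_samples)
    for j, sid in enumerate(samples):
        depth_mean[j] = (
            tumour_params[sid].mean_depth
            if sid in tumour_params
            else float(rng.uniform(*config.mean_depth_range))
        )

    # ---- variant records ---------------------------------------------
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    labels: list[str] = []
    origin_col: list[int] = []  # originating tumour column, -1 if none
    patient_idx: list[str] = []
    row_rate: list[float] = []  # per-row off-target read rate

    def _new_variant(ctx: int, label: str, origin: int, pid: str, rate: float):
        trinuc, ref, alt = _context_to_alleles(int(ctx))
        positions.append(alloc.take(trinuc))
        refs.append(ref)
        alts.append(alt)
        labels.append(label)
        origin_col.append(origin)
        patient_idx.append(pid)
        row_rate.append(rate)

    for prof in config.patients:
        pid = prof.patient_id
        for col in tumour_cols[pid]:
            tid = samples[col]
            n_som = int(rng.poisson(tumour_params[tid].expected_mutation_count))
            ctxs = rng.choice(96, size=n_som, p=prof.spectrum_weights)
            for ctx in ctxs:
                _new_variant(ctx, SOMATIC_PRIVATE, col, pid, config.error_read_rate)
        for ctx in rng.integers(0, 96, size=prof.germline_snp_count):
            _new_variant(ctx, GERMLINE_SNP, -1, pid, config.error_read_rate)
        for ctx in rng.integers(0, 96, size=prof.kidney_specific_variant_count):
            _new_variant(ctx, KIDNEY_SPECIFIC, -1, pid, config.error_read_rate)

    error_rates = rng.uniform(*config.error_site_rate_range, size=config.n_error_sites)
    for ctx, q in zip(rng.integers(0, 96, size=config.n_error_sites), error_rates):
        _new_variant(int(ctx), SEQUENCING_ERROR, -1, "", float(q))

    n_var = len(positions)
    labels_arr = np.array(labels)
    origin_arr = np.array(origin_col)

    # ---- read counts -------------------------------------------------
    total = rng.poisson(np.broadcast_to(depth_mean, (n_var, n_samples)))
    p_alt = np.tile(np.asarray(row_rate, dtype=float)[:, None], (1, n_samples))
    for i in range(n_var):
        pid = patient_idx[i]
        if labels[i] == SOMATIC_PRIVATE:
            col = origin_arr[i]
            p_alt[i, col] = tumour_params[samples[col]].purity * 0.5
        elif labels[i] == GERMLINE_SNP:
            pcols = [j for j, s in enumerate(samples) if patient_of[s] == pid]
            p_alt[i, pcols] = 0.5
        elif labels[i] == KIDNEY_SPECIFIC:
            kcols = list(tumour_cols[pid])
            if pid in kidney_col:
                kcols.append(kidney_col[pid])
            p_alt[i, kcols] = 0.5
    alt = rng.binomial(total, p_alt)

    # cross-tumour leakage: a somatic variant drops 1-3 reads into one sibling
    som_rows = np.nonzero(labels_arr == SOMATIC_PRIVATE)[0]
    leak = rng.random(som_rows.size) < config.contamination_rate
    for i in som_rows[leak]:
        pid = patient_idx[i]
        sibs = [c for c in tumour_cols[pid] if c != origin_arr[i]]
        sib = sibs[int(rng.integers(len(sibs)))]
        reads = int(rng.integers(1, 4))
        total[i, sib] = max(total[i, sib], reads)
        alt[i, sib] = max(alt[i, sib], reads)
        labels_arr[i] = LEAKED

    # ---- called matrix ------------------------------------------------
    called = np.zeros((n_var, n_samples), dtype=bool)
    all_tumour_cols = np.array(
        [j for j, s in enumerate(samples) if sample_type[s] == "tumour"]
    )
    for i in range(n_var):
        lab = labels_arr[i]
        pid = patient_idx[i]
        if lab in (SOMATIC_PRIVATE, LEAKED):
            called[i, origin_arr[i]] = True
        elif lab == GERMLINE_SNP:
            cols = tumour_cols[pid]
            called[i, cols[int(rng.integers(len(cols)))]] = True
        elif lab == KIDNEY_SPECIFIC:
            called[i, tumour_cols[pid]] = True
        else:  # sequencing error: called where it looks most variant-like
            j = all_tumour_cols[int(np.argmax(alt[i, all_tumour_cols]))]
            called[i, j] = True
    total = np.where(called & (total == 0), 1, total)
    alt = np.minimum(alt, total)

    # unstable-alignment flags on a subset of error sites
    unstable = np.zeros((n_var, n_samples), dtype=bool)
    err_rows = np.nonzero(labels_arr == SEQUENCING_ERROR)[0]
    n_unst = min(config.n_unstable_sites, err_rows.size)
    for i in rng.choice(err_rows, size=n_unst, replace=False) if n_unst else []:
        frac = rng.uniform(0.6, 0.9)
        cols = rng.choice(n_samples, size=max(1, int(frac * n_samples)), replace=False)
        unstable[i, cols] = True

    variants = [(contig, int(p), r, a) for p, r, a in zip(positions, refs, alts)]
    matrix = CrossSampleReadMatrix(
        variants=variants,
        samples=samples,
        patient_of=patient_of,
        alt_reads=alt,
        total_reads=total,
        called=called,
        unstable=unstable,
        sample_type=sample_type,
    )

    # ---- per-tumour calls --------------------------------------------
    calls: list[VariantCall] = []
    truth: dict[tuple, str] = {}
    snp_sites: set[tuple] = set()
    for i, site in enumerate(variants):
        truth[site] = str(labels_arr[i])
        if labels_arr[i] == GERMLINE_SNP:
            snp_sites.add(site)
        pid = patient_idx[i]
        for j in np.nonzero(called[i])[0]:
            bcol = blood_col[patient_of[samples[j]]]
            calls.append(
                VariantCall(
                    sample_id=samples[j],
                    chrom=site[0],
                    pos=site[1],
                    ref=site[2],
                    alt=site[3],
                    tumour_total=int(total[i, j]),
                    tumour_alt=int(alt[i, j]),
                    normal_total=int(total[i, bcol]),
                    normal_alt=int(alt[i, bcol]),
                    is_snp_site=bool(labels_arr[i] == GERMLINE_SNP),
                    unstable_alignment=bool(unstable[i, j]),
                )
            )

    # ---- copy-number segments ----------------------------------------
    ab = config.arm_boundaries
    segments: dict[str, list[CNSegment]] = {}
    for prof in config.patients:
        for col in tumour_cols[prof.patient_id]:
            tid = samples[col]
            segs = [CNSegment(contig, 0, genome.length(contig), "neutral")]
            u = rng.random()
            if u < prof.chr3_whole_loss_prob:
                segs.append(CNSegment(ab.chrom, ab.p_start, ab.q_end, "loss"))
            elif rng.random() < config.arm_loss_prob:
                segs.append(CNSegment(ab.chrom, ab.p_start, ab.centromere, "loss"))
                segs.append(CNSegment(ab.chrom, ab.centromere, ab.q_end, "neutral"))
            else:
                segs.append(CNSegment(ab.chrom, ab.p_start, ab.q_end, "neutral"))
            segments[tid] = segs

    return SimulatedCohort(
        patients=list(config.patients),
        tumour_params=tumour_params,
        calls=calls,
        read_matrix=matrix,
        segments=segments,
        truth=truth,
        snp_sites=snp_sites,
        sample_type=sample_type,
        genome=genome,
        arm_boundaries=ab,
        seed=seed,
    )


def build_read_matrix(cohort: SimulatedCohort) -> CrossSampleReadMatrix:
    """Cohort's cross-sample read matrix, validated against its own calls."""
    if not cohort.calls:
        raise InvalidConfigError("cohort has no calls")
    m = cohort.read_matrix
    for c in cohort.calls:
        if c.sample_id not in m.patient_of:
            raise StructuralError(f"call sample {c.sample_id} missing from matrix")
        i, j = m.row_index(c.site), m.col_index(c.sample_id)
        if m.alt_reads[i, j] != c.tumour_alt or m.total_reads[i, j] != c.tumour_total:
            raise StructuralError(f"matrix inconsistent with call at {c.key}")
    return m


def second_pipeline_calls(
    cohort: SimulatedCohort, seed: int, keep_prob: float = 0.98
) -> list[VariantCall]:
    """Emulate an independent pipeline version's call set.

    Real calls are robust to pipeline changes, so each is retained with
    high probability; sequencing-error calls are fragile and retained
    with probability 0.3.
    """
    rng = np.random.default_rng(seed)
    out = []
    for c in cohort.calls:
        p = 0.3 if cohort.truth[c.site] == SEQUENCING_ERROR else keep_prob
        if rng.random() < p:
            out.append(c)
    return out


def simulate_normal_comparison(
    seed: int, n_sites: int = 4000, n_patients: int = 6
) -> tuple[list[VariantCall], list[VariantCall], CrossSampleReadMatrix]:
    """Error-only call sets from comparing two normals of the same patient.

    No true somatic variants exist, so every call is an artefact: random
    noise (low depth / low VAF), systematic error sites with reads shared
    across all samples, sites with high VAF in another patient, known-SNP
    leak-through, and patient-private artefacts that only the
    pipeline-intersection tier can remove. Returns call sets for two
    pipeline versions plus the cross-sample matrix.
    """
    if n_patients < 2 or n_sites < 1:
        raise InvalidConfigError("need >= 2 patients and >= 1 site")
    rng = np.random.default_rng(seed)
    samples, patient_of, sample_type = [], {}, {}
    for p in range(1, n_patients + 1):
        pid = f"P{p}"
        for sid, st in ((f"{pid}-NK", "kidney_normal"), (f"{pid}-BL", "blood")):
            samples.append(sid)
            patient_of[sid] = pid
            sample_type[sid] = st
    caller, matched_normal = "P1-NK", "P1-BL"
    ci, ni = samples.index(caller), samples.index(matched_normal)
    n_samp = len(samples)

    kinds = rng.choice(
        ["noise", "systematic", "cross_patient", "private", "snp"],
        size=n_sites,
        p=[0.60, 0.25, 0.04, 0.06, 0.05],
    )
    pos = rng.choice(800_000, size=n_sites, replace=False) + 1
    ref_alt = [("C", "T"), ("C", "A"), ("T", "C"), ("T", "G")]

    total = rng.poisson(38.0, size=(n_sites, n_samp))
    alt = rng.binomial(total, 0.0005)
    in_b = np.zeros(n_sites, dtype=bool)
    calls_a: list[VariantCall] = []
    variants = []
    for i in range(n_sites):
        r, a = ref_alt[int(rng.integers(4))]
        variants.append(("chr1", int(pos[i]), r, a))
        kind = kinds[i]
        is_snp = False
        if kind == "noise":
            # error-prone site: low-level reads in many samples, a few in
            # the caller -- the dataset-level binomial tier's target
            q_bg = rng.uniform(0.005, 0.03)
            alt[i] = rng.binomial(total[i], q_bg)
            total[i, ci] = rng.poisson(18.0)
            alt[i, ci] = min(1 + rng.poisson(1.0), total[i, ci])
            alt[i, ni] = 0
            in_b[i] = rng.random() < 0.3
        elif kind == "systematic":
            q = rng.uniform(0.03, 0.08)
            alt[i] = rng.binomial(total[i], q)
            alt[i, ci] = rng.binomial(total[i, ci], 0.15)
            in_b[i] = rng.random() < 0.5
        elif kind == "cross_patient":
            alt[i, ci] = rng.binomial(total[i, ci], 0.15)
            alt[i, ni] = 0
            other = [j for j in range(n_samp) if patient_of[samples[j]] != "P1"]
            alt[i, other[int(rng.integers(len(other)))]] = int(
                0.2 * total[i, other[0]] + 1
            )
            in_b[i] = rng.random() < 0.5
        elif kind == "private":
            alt[i, ci] = rng.binomial(total[i, ci], 0.15)
            alt[i, ni] = 0
            in_b[i] = rng.random() < 0.2
        else:  # snp
            alt[i, ci] = rng.binomial(total[i, ci], 0.5)
            alt[i, ni] = rng.binomial(total[i, ni], 0.5)
            is_snp = True
            in_b[i] = rng.random() < 0.9
        total[i, ci] = max(total[i, ci], alt[i, ci], 1)
        calls_a.append(
            VariantCall(
                sample_id=caller,
                chrom="chr1",
                pos=int(pos[i]),
                ref=r,
                alt=a,
                tumour_total=int(total[i, ci]),
                tumour_alt=int(alt[i, ci]),
                normal_total=int(max(total[i, ni], 1)),
                normal_alt=int(min(alt[i, ni], total[i, ni])),
                is_snp_site=is_snp,
            )
        )
    alt = np.minimum(alt, total)
    called = np.zeros((n_sites, n_samp), dtype=bool)
    called[:, ci] = True
    total[:, ci] = np.maximum(total[:, ci], 1)
    matrix = CrossSampleReadMatrix(
        variants=variants,
        samples=samples,
        patient_of=patient_of,
        alt_reads=alt,
        total_reads=total,
        called=called,
        sample_type=sample_type,
    )
    calls_b = [c for c, keep in zip(calls_a, in_b) if keep]
    return calls_a, calls_b, matrix
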