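"""Readers and writers for the standard formats the pipeline touches.

VCF (v4.2, AD/DP FORMAT fields, tumour + matched-normal columns) is read
and written through pysam. The cross-sample read matrix, SNP site list,
sample metadata, truth labels, spectra and filter reports travel as TSV;
copy-number segments as 4-column BED (0-based half-open, state in
loss/neutral/gain); run configuration as YAML.

Coordinate conventions: variants are stored 1-based (VCF), segments in
BED convention; conversions happen only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .cnv import ArmBoundaries, CNSegment
from .filtering import CrossSampleReadMatrix, FilterConfig, FilterReport, VariantCall

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    calls: list[VariantCall],
    path,
    tumour_sample: str,
    normal_sample: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write one tumour's calls as VCF v4.2 with AD/DP for tumour and normal."""
    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    seen = {c.chrom for c in calls}
    for chrom in sorted(seen | set(contigs)):
        header.contigs.add(chrom, length=contigs.get(chrom))
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample(tumour_sample)
    header.add_sample(normal_sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt)
            )
            rec.samples[tumour_sample]["AD"] = (c.tumour_total - c.tumour_alt, c.tumour_alt)
            rec.samples[tumour_sample]["DP"] = c.tumour_total
            rec.samples[normal_sample]["AD"] = (c.normal_total - c.normal_alt, c.normal_alt)
            rec.samples[normal_sample]["DP"] = c.normal_total
            vcf.write(rec)


def read_variant_calls(
    vcf_path,
    tumour_sample: str,
    normal_sample: str,
    snp_sites: set[tuple] | None = None,
) -> list[VariantCall]:
    """Read biallelic SNVs from a VCF into VariantCall records.

    Multi-allelic records are split per alt allele; indels are skipped
    with a counted warning. ``snp_sites`` marks known-SNP sites on load.
    """
    snp_sites = snp_sites or set()
    calls: list[VariantCall] = []
    n_indel = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for name in (tumour_sample, normal_sample):
            if name not in vcf.header.samples:
                raise FormatError(f"sample {name!r} absent from {vcf_path}")
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or ()):
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    n_indel += 1
                    continue
                row = {}
                for name in (tumour_sample, normal_sample):
                    fmt = rec.samples[name]
                    if fmt.get("AD") is None:
                        raise FormatError(
                            f"missing AD for {name} at {rec.chrom}:{rec.pos}"
                        )
                    ad = fmt["AD"]
                    dp = fmt.get("DP")
                    total = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
                    row[name] = (total, int(ad[1 + ai] or 0))
                site = (rec.chrom, rec.pos, rec.ref, alt)
                calls.append(
                    VariantCall(
                        sample_id=tumour_sample,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        tumour_total=row[tumour_sample][0],
                        tumour_alt=row[tumour_sample][1],
                        normal_total=row[normal_sample][0],
                        normal_alt=row[normal_sample][1],
                        is_snp_site=site in snp_sites,
                    )
                )
    if n_indel:
        logger.warning("skipped %d non-SNV allele(s) in %s", n_indel, vcf_path)
    return calls


# ---------------------------------------------------------------------------
# read matrix TSV


def write_read_matrix(matrix: CrossSampleReadMatrix, path) -> None:
    """TSV: chrom, pos, ref, alt, then one "alt,total" column per sample."""
    cols = {"chrom": [], "pos": [], "ref": [], "alt": []}
    for chrom, pos, ref, alt in matrix.variants:
        cols["chrom"].append(chrom)
        cols["pos"].append(pos)
        cols["ref"].append(ref)
        cols["alt"].append(alt)
    df = pd.DataFrame(cols)
    for j, s in enumerate(matrix.samples):
        df[s] = [
            f"{a},{t}" for a, t in zip(matrix.alt_reads[:, j], matrix.total_reads[:, j])
        ]
    df.to_csv(path, sep="\t", index=False)


def read_read_matrix(path, sample_meta: pd.DataFrame) -> CrossSampleReadMatrix:
    """Load a read-matrix TSV; sample metadata supplies patient and type.

    ``called`` is reconstituted as False everywhere (callers' VCFs carry
    that information); use ``mark_called`` to flag calls.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "pos", "ref", "alt"]
    if df.columns[:4].tolist() != fixed:
        raise FormatError(f"read matrix must start with columns {fixed}")
    samples = [c for c in df.columns if c not in fixed]
    meta = sample_meta.set_index("sample")
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise FormatError(f"samples missing from metadata: {missing}")
    n = len(df)
    alt = np.zeros((n, len(samples)), dtype=np.int64)
    total = np.zeros_like(alt)
    for j, s in enumerate(samples):
        parts = df[s].str.split(",", expand=True).astype(np.int64)
        alt[:, j], total[:, j] = parts[0], parts[1]
    return CrossSampleReadMatrix(
        variants=list(
            zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"])
        ),
        samples=samples,
        patient_of={s: str(meta.loc[s, "patient"]) for s in samples},
        alt_reads=alt,
        total_reads=total,
        called=np.zeros((n, len(samples)), dtype=bool),
        sample_type={s: str(meta.loc[s, "type"]) for s in samples},
    )


def mark_called(matrix: CrossSampleReadMatrix, calls: list[VariantCall]) -> None:
    for c in calls:
        matrix.called[matrix.row_index(c.site), matrix.col_index(c.sample_id)] = True


# ---------------------------------------------------------------------------
# small TSV tables


def write_sample_metadata(matrix: CrossSampleReadMatrix, path) -> None:
    pd.DataFrame(
        {
            "sample": matrix.samples,
            "patient": [matrix.patient_of[s] for s in matrix.samples],
            "type": [matrix.sample_type.get(s, "tumour") for s in matrix.samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "patient", "type"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample metadata needs columns {sorted(required)}")
    return df


def write_snp_list(sites: set[tuple], path) -> None:
    pd.DataFrame(sorted(sites), columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_snp_list(path) -> set[tuple]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
    }


def write_truth_labels(truth: dict[tuple, str], path) -> None:
    rows = [(c, p, r, a, lab) for (c, p, r, a), lab in sorted(truth.items())]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_filter_report(report: FilterReport, path) -> None:
    rows = [
        (sample, chrom, pos, ref, alt, fate)
        for (sample, chrom, pos, ref, alt), fate in sorted(
            report.per_variant_fate.items()
        )
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "fate"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED segments and arm boundaries


def write_segments_bed(segments: dict[str, list[CNSegment]], path) -> None:
    """BED per sample: chrom, start, end, state, sample (5th column)."""
    with open(path, "w") as fh:
        for sample in sorted(segments):
            for s in segments[sample]:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{sample}\n")


def read_segments_bed(path) -> dict[str, list[CNSegment]]:
    out: dict[str, list[CNSegment]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: expected 5 BED columns")
            chrom, start, end, state, sample = parts[:5]
            out.setdefault(sample, []).append(
                CNSegment(chrom, int(start), int(end), state)
            )
    return out


def write_arm_boundaries(ab: ArmBoundaries, path) -> None:
    pd.DataFrame(
        [(ab.chrom, ab.p_start, ab.centromere, ab.q_end)],
        columns=["chrom", "p_start", "centromere", "q_end"],
    ).to_csv(path, sep="\t", index=False)


def read_arm_boundaries(path) -> ArmBoundaries:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    r = df.iloc[0]
    return ArmBoundaries(r.chrom, int(r.p_start), int(r.centromere), int(r.q_end))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Paths and parameters for a full analysis run."""

    out_dir: str = "renovar_out"
    seed: int = 1
    simulate_scale: float = 0.1
    filter: FilterConfig = field(default_factory=FilterConfig)
    purity_n_bins: int = 20
    n_perm: int = 10_000
    sharing_min_reads: int = 1
    normal_presence_min_reads: int = 2
    chr3_loss_threshold: float = 0.9
    chr3_background_rate: float = 0.10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "filter"}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(filter=filt, **raw)

    def to_yaml(self, path) -> None:
        data = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "filter"
        }
        data["filter"] = vars(self.filter)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
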