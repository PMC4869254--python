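"""Chromosome-3 copy-number status and the whole-loss bias census.

In clear cell renal carcinoma the 3p arm is lost in >90% of tumours,
but loss of the *entire* chromosome 3 is rare (<10%). Per tumour, the
fraction of each arm covered by loss-state segments classifies the
chromosome as whole_loss (both arms essentially lost), p_arm_loss (p
lost, q retained) or other; the census over a patient's tumours then
asks, with an exact upper-tail binomial test, whether so many whole
losses could occur by chance at the population background rate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_stats import binomial_enrichment_test

STATES = ("loss", "neutral", "gain")


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment in BED convention (0-based half-open)."""

    chrom: str
    start: int
    end: int
    state: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.state not in STATES:
            raise ValueError(f"unknown copy state {self.state!r}")


@dataclass(frozen=True)
class ArmBoundaries:
    """p/q arm layout of one chromosome (BED coordinates)."""

    chrom: str
    p_start: int
    centromere: int
    q_end: int

    def __post_init__(self):
        if not (self.p_start < self.centromere < self.q_end):
            raise ValueError("require p_start < centromere < q_end")


@dataclass(frozen=True)
class Chr3Status:
    sample_id: str
    status: str  # whole_loss | p_arm_loss | other
    fraction_lost_p: float
    fraction_lost_q: float


def _loss_overlap(segments, lo: int, hi: int) -> int:
    covered = 0
    for seg in segments:
        if seg.state != "loss":
            continue
        covered += max(0, min(seg.end, hi) - max(seg.start, lo))
    return covered


def classify_chr3_status(
    segments: list[CNSegment],
    arm_boundaries: ArmBoundaries,
    loss_fraction_threshold: float = 0.9,
    sample_id: str = "",
) -> Chr3Status:
    """Classify one tumour's chromosome-3 state from its loss segments.

    whole_loss requires both arms >= ``loss_fraction_threshold`` covered
    by loss; p_arm_loss requires only the p arm to reach it. The default
    0.9 reads "complete loss" with tolerance for segmentation edge noise.
    """
    ab = arm_boundaries
    chrom_segs = [s for s in segments if s.chrom == ab.chrom]
    for s in chrom_segs:
        if s.start < ab.p_start or s.end > ab.q_end:
            raise ValueError(f"segment {s} outside chromosome bounds")
    p_len = ab.centromere - ab.p_start
    q_len = ab.q_end - ab.centromere
    f_p = _loss_overlap(chrom_segs, ab.p_start, ab.centromere) / p_len
    f_q = _loss_overlap(chrom_segs, ab.centromere, ab.q_end) / q_len
    if f_p >= loss_fraction_threshold and f_q >= loss_fraction_threshold:
        status = "whole_loss"
    elif f_p >= loss_fraction_threshold:
        status = "p_arm_loss"
    else:
        status = "other"
    return Chr3Status(sample_id, status, f_p, f_q)


def chr3_loss_census(
    statuses: list[Chr3Status], background_whole_loss_rate: float = 0.10
) -> tuple[int, int, float]:
    """(k, n, p-value): whole-chr3 losses among a patient's tumours vs background."""
    if not statuses:
        raise ValueError("need at least one tumour status")
    k = sum(1 for s in statuses if s.status == "whole_loss")
    n = len(statuses)
    return k, n, binomial_enrichment_test(k, n, background_whole_loss_rate)
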