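"""Mutation spectra: 6 substitution classes and 96 trinucleotide contexts.

Single-base substitutions are collapsed onto a pyrimidine reference
(purine-reference changes are reverse-complemented, flanks swapped),
giving 6 classes (C>A, C>G, C>T, T>A, T>C, T>G) and, with the 5' and 3'
neighbouring bases, 96 trinucleotide contexts. Context ordering follows
the COSMIC convention — class-major, then 5' base A<C<G<T, then 3' base
— so external signature tables load without remapping.

The module builds per-tumour spectra from filtered calls, normalises and
centres a cohort spectrum matrix for heat-map clustering, scores spectra
against signature catalogues by Spearman correlation or cosine
similarity, and clusters tumours by average linkage on correlation
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome import BASES, revcomp

logger = logging.getLogger(__name__)

CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES6)}

#: 96 context labels, "A[C>A]A" style, in canonical order.
CONTEXTS96 = tuple(
    f"{f}[{cls}]{t}" for cls in CLASSES6 for f in BASES for t in BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS96)}


class InvalidBaseError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


def classify_substitution(
    ref: str, alt: str, five_prime: str, three_prime: str
) -> tuple[int, int]:
    """Map a substitution with flanks to (class index in 0..5, context index in 0..95).

    Purine-reference substitutions are reverse-complemented (ref, alt and
    both flanks, flank order swapped) so the reported class always has a
    pyrimidine reference.
    """
    for b in (ref, alt, five_prime, three_prime):
        if b not in "ACGT" or len(b) != 1:
            raise InvalidBaseError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise InvalidBaseError("ref equals alt")
    if ref in "AG":  # purine: flip strand
        ref, alt = revcomp(ref), revcomp(alt)
        five_prime, three_prime = revcomp(three_prime), revcomp(five_prime)
    cls = _CLASS_INDEX[f"{ref}>{alt}"]
    ctx = cls * 16 + BASES.index(five_prime) * 4 + BASES.index(three_prime)
    return cls, ctx


def context_label(ctx_index: int) -> str:
    return CONTEXTS96[ctx_index]


@dataclass
class MutationSpectrum:
    """Per-sample counts over 96 trinucleotide contexts (6 classes derive)."""

    sample_id: str
    counts96: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))

    def __post_init__(self):
        self.counts96 = np.asarray(self.counts96, dtype=np.int64)
        if self.counts96.shape != (96,) or (self.counts96 < 0).any():
            raise ValueError("counts96 must be a non-negative 96-vector")

    @property
    def counts6(self) -> np.ndarray:
        return self.counts96.reshape(6, 16).sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts96.sum())

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise InsufficientDataError(f"empty spectrum for {self.sample_id}")
        return self.counts96 / self.total


def build_spectrum(calls, reference) -> dict[str, MutationSpectrum]:
    """Tally filtered calls into per-sample 96-context spectra.

    ``reference`` is any genome accessor exposing
    ``trinucleotide(chrom, pos)``. Calls at contig edges (missing flank)
    are excluded with a logged warning.
    """
    spectra: dict[str, MutationSpectrum] = {}
    n_skipped = 0
    for c in calls:
        try:
            trinuc = reference.trinucleotide(c.chrom, c.pos)
        except KeyError:
            n_skipped += 1
            continue
        if trinuc[1] != c.ref:
            raise ValueError(
                f"reference mismatch at {c.chrom}:{c.pos}: call ref {c.ref}, genome {trinuc[1]}"
            )
        _, ctx = classify_substitution(c.ref, c.alt, trinuc[0], trinuc[2])
        spectra.setdefault(c.sample_id, MutationSpectrum(c.sample_id)).counts96[ctx] += 1
    if n_skipped:
        logger.warning("excluded %d calls lacking a 5'/3' flank", n_skipped)
    return spectra


def spectra_to_frame(spectra: dict[str, MutationSpectrum]) -> pd.DataFrame:
    """Samples x 96 count matrix with context labels as columns."""
    return pd.DataFrame(
        {sid: sp.counts96 for sid, sp in spectra.items()},
        index=list(CONTEXTS96),
    ).T


def normalize_center(matrix) -> pd.DataFrame:
    """Rows to proportions, then centre each column at zero across samples.

    This is the transformation behind the clustered heat-map view: row
    normalisation removes mutation-load differences, column centring
    removes the cohort-average profile so patient-specific deviations
    stand out.
    """
    df = pd.DataFrame(matrix).astype(float)
    totals = df.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise InsufficientDataError(f"zero-total spectrum rows: {list(zero.index)}")
    props = df.div(totals, axis=0)
    return props - props.mean(axis=0)


@dataclass
class SignatureMatrix:
    """Named mutational-signature profiles over the 96 contexts."""

    names: list[str]
    profiles: np.ndarray  # signatures x 96, rows sum to 1

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.names), 96):
            raise ValueError("profiles must be (n_signatures, 96)")
        if (self.profiles < 0).any():
            raise ValueError("negative signature weight")
        if not np.allclose(self.profiles.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("signature rows must sum to 1")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        """Load a COSMIC-layout TSV: first column context labels, one column per signature."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(CONTEXTS96) - set(df.index)
        if missing:
            raise ValueError(f"signature table missing contexts, e.g. {sorted(missing)[:3]}")
        df = df.loc[list(CONTEXTS96)]
        return cls(names=list(df.columns), profiles=df.to_numpy().T)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.profiles.T, index=list(CONTEXTS96), columns=self.names
        ).to_csv(path, sep="\t", index_label="context")


def correlate_with_signatures(
    spectrum: MutationSpectrum, sigs: SignatureMatrix, method: str = "spearman"
) -> pd.Series:
    """Score a spectrum against each signature by Spearman (mid-ranks) or cosine."""
    if method not in ("spearman", "cosine"):
        raise ValueError(f"unknown method {method!r}")
    x = spectrum.proportions
    scores = {}
    for name, prof in zip(sigs.names, sigs.profiles):
        if method == "cosine":
            denom = np.linalg.norm(x) * np.linalg.norm(prof)
            if denom == 0:
                raise UndefinedCorrelationError("zero-norm vector")
            scores[name] = float(x @ prof / denom)
        else:
            if np.ptp(x) == 0 or np.ptp(prof) == 0:
                raise UndefinedCorrelationError("constant vector has no rank order")
            r = stats.spearmanr(x, prof).statistic
            scores[name] = float(r)
    return pd.Series(scores, name=f"{method}:{spectrum.sample_id}")


def cluster_samples(centered) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering on correlation distance.

    Returns a scipy linkage matrix and the leaf labels (input row order).
    Correlation distance is 1 - Pearson r between row profiles.
    """
    df = pd.DataFrame(centered).astype(float)
    if len(df) < 2:
        raise InsufficientDataError("need >= 2 samples to cluster")
    dist = pdist(df.to_numpy(), metric="correlation")
    linkage = hierarchy.linkage(dist, method="average")
    return linkage, [str(i) for i in df.index]
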