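"""Tumour purity from the VAF distribution of filtered variants.

In a nearly diploid tumour, clonal heterozygous somatic variants sit at
VAF = purity / 2, so twice the centre of the dominant VAF peak estimates
the fraction of malignant cells. The estimator bins VAFs into 20
equal-width bins over [0, 1], takes the most populated bin (ties broken
toward the lower bin, which is robust to subclonal variants), and
returns twice the mean VAF of that bin, clamped to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PurityEstimate:
    purity: float
    mode_bin_index: int
    n_variants_in_mode_bin: int
    n_variants_total: int


def estimate_purity(vafs, n_bins: int = 20) -> PurityEstimate:
    """Mode-bin purity estimate from variant allele frequencies in (0, 1].

    Bins are left-closed right-open over [0, 1] with the last bin closed.
    """
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size == 0:
        raise InsufficientDataError("no VAFs supplied")
    if (vafs <= 0).any() or (vafs > 1).any():
        raise ValueError("VAFs must lie in (0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    # assign bins; VAF == 1 falls in the last (closed) bin
    idx = np.minimum((vafs * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mode = int(np.argmax(counts))  # argmax takes the first = lower bin on ties
    in_mode = idx == mode
    purity = float(np.clip(2.0 * vafs[in_mode].mean(), 0.0, 1.0))
    return PurityEstimate(
        purity=purity,
        mode_bin_index=mode,
        n_variants_in_mode_bin=int(counts[mode]),
        n_variants_total=int(vafs.size),
    )
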