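"""Cohort-level inference.

The within-patient similarity question — are mutation spectra of tumours
from the same patient more alike than tumours from different patients? —
is answered with a patient-label permutation test on the mean pairwise
Spearman correlation of 96-context spectra, averaged per patient first
so patients with many tumours do not dominate. The module also provides
exact upper-tail binomial and hypergeometric tests for patient-specific
copy-number and clustering bias, one-way ANOVA on substitution-type
proportions, and the mutation-load versus age correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class InvalidDesignError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    n_perm: int
    n_at_least_as_extreme: int
    p_value: float
    seed: int


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, np.asarray(x, dtype=float))


def _spearman_matrix(spectra) -> np.ndarray:
    """All-pairs Spearman correlation between sample spectra (mid-ranks)."""
    x = np.asarray(pd.DataFrame(spectra), dtype=float)
    if x.shape[0] < 2:
        raise InvalidDesignError("need >= 2 samples")
    return np.corrcoef(_rank_rows(x))


def _groups(labels) -> dict:
    idx: dict = {}
    for i, lab in enumerate(labels):
        idx.setdefault(lab, []).append(i)
    return {k: np.array(v, dtype=int) for k, v in idx.items()}


def _stat_from_corr(corr: np.ndarray, groups: list[np.ndarray]) -> float:
    per_patient = []
    for g in groups:
        sub = corr[np.ix_(g, g)]
        iu = np.triu_indices(len(g), k=1)
        per_patient.append(sub[iu].mean())
    return float(np.mean(per_patient))


def within_patient_similarity_stat(spectra, patient_labels) -> float:
    """Unweighted mean over patients of mean within-patient pairwise Spearman r.

    Patients with fewer than two samples cannot contribute a pair and are
    excluded with a warning.
    """
    corr = _spearman_matrix(spectra)
    groups = _groups(list(patient_labels))
    usable = [g for g in groups.values() if len(g) >= 2]
    dropped = [k for k, g in groups.items() if len(g) < 2]
    if dropped:
        logger.warning("excluding single-sample patients from similarity: %s", dropped)
    if not usable:
        raise InvalidDesignError("no patient has >= 2 samples")
    return _stat_from_corr(corr, usable)


def permutation_similarity_test(
    spectra,
    patient_labels,
    n_perm: int = 100_000,
    seed: int = 0,
    add_one: bool = False,
) -> PermutationResult:
    """Patient-label permutation test of within-patient spectrum similarity.

    Labels are permuted uniformly at random (group sizes preserved); the
    p-value is the fraction of permutations with a *strictly higher*
    statistic than observed. ``add_one`` switches to the
    (count+1)/(n_perm+1) estimator.
    """
    labels = list(patient_labels)
    if len(set(labels)) < 2:
        raise InvalidDesignError("all samples belong to one patient")
    if n_perm < 1:
        raise InvalidDesignError("n_perm must be >= 1")
    corr = _spearman_matrix(spectra)
    groups = [g for g in _groups(labels).values() if len(g) >= 2]
    if not groups:
        raise InvalidDesignError("no patient has >= 2 samples")
    observed = _stat_from_corr(corr, groups)
    rng = np.random.default_rng(seed)
    n = len(labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _stat_from_corr(corr, [perm[g] for g in groups]) > observed:
            count += 1
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return PermutationResult(
        observed_stat=observed,
        n_perm=n_perm,
        n_at_least_as_extreme=count,
        p_value=float(p),
        seed=seed,
    )


def binomial_enrichment_test(k: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p)."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    return float(stats.binom.sf(k - 1, n, p))


def hypergeometric_half_tree_test(n_total: int, n_group: int, half_size: int) -> float:
    """Probability all ``n_group`` samples land in one specified half of a tree.

    With ``half_size`` leaves assigned at random out of ``n_total``, the
    chance the half contains every group member is
    C(n_total - n_group, half_size - n_group) / C(n_total, half_size).
    """
    if n_group < 0 or half_size < 0 or n_total < half_size:
        raise ValueError("require 0 <= half_size <= n_total and n_group >= 0")
    if n_group > half_size:
        return 0.0
    return math.comb(n_total - n_group, half_size - n_group) / math.comb(
        n_total, half_size
    )


def anova_type_proportions(proportions, patient_labels) -> pd.DataFrame:
    """One-way ANOVA per substitution class on per-sample proportions.

    Returns a class x (F, p_value) table of unadjusted p-values.
    """
    df = pd.DataFrame(proportions).astype(float)
    groups = _groups(list(patient_labels))
    if len(groups) < 2 or any(len(g) < 2 for g in groups.values()):
        raise InvalidDesignError("need >= 2 patients with >= 2 samples each")
    rows = {}
    for cls in df.columns:
        samples = [df[cls].to_numpy()[g] for g in groups.values()]
        if all(np.ptp(s) == 0 for s in samples):
            raise UndefinedStatisticError(
                f"zero within-group variance in every group for {cls}"
            )
        f, p = stats.f_oneway(*samples)
        rows[cls] = {"F": float(f), "p_value": float(p)}
    return pd.DataFrame(rows).T


def snv_age_correlation(counts, ages, method: str = "pearson") -> tuple[float, float]:
    """Correlation between per-tumour mutation load and patient age at surgery."""
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if counts.size != ages.size or counts.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(ages) == 0 or np.ptp(counts) == 0:
        raise UndefinedStatisticError("constant input has no defined correlation")
    if method == "pearson":
        res = stats.pearsonr(counts, ages)
    elif method == "spearman":
        res = stats.spearmanr(counts, ages)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
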