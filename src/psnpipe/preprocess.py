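"""Dimension reduction and cohort assembly for omics matrices.

Four reduction strategies are supported before network inference:

* ``wilcoxon_p`` — per-endpoint rank-sum test, keep features with p < 0.05;
* ``wilcoxon_top`` — same test, keep the 10% smallest p-values regardless of
  significance;
* ``variance_top`` — keep the 10% most varying features (endpoint-agnostic);
* ``pca_var`` — centered PCA pseudo-features explaining > 90% of variance;
* ``none`` — the complete matrix.

Selection statistics can be fitted on training patients only (default,
avoiding test leakage) or on all samples; see :class:`ReductionConfig`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import ClinicalTable, OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

STRATEGIES = ("wilcoxon_p", "wilcoxon_top", "variance_top", "pca_var", "none")


@dataclass
class ReductionConfig:
    strategy: str = "none"
    p_threshold: float = 0.05
    top_fraction: float = 0.10
    variance_target: float = 0.90
    fit_scope: str = "train_only"  # or "all_samples"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValidationError("p_threshold must be in (0, 1)")
        if not 0.0 < self.top_fraction < 1.0:
            raise ValidationError("top_fraction must be in (0, 1)")
        if not 0.0 <= self.variance_target < 1.0:
            raise ValidationError("variance_target must be in [0, 1)")
        if self.fit_scope not in ("train_only", "all_samples"):
            raise ValidationError(f"unknown fit_scope {self.fit_scope!r}")


def drop_missing_features(m: OmicsMatrix) -> OmicsMatrix:
    """Remove every feature with at least one missing value."""
    ok = ~np.isnan(m.values).any(axis=0)
    if not ok.any():
        raise ValidationError(f"source {m.source_tag!r}: no features remain "
                              "after dropping missing values")
    kept = [f for f, keep in zip(m.feature_ids, ok) if keep]
    if len(kept) < m.n_features:
        logger.info("source %s: dropped %d/%d features with missing values",
                    m.source_tag, m.n_features - len(kept), m.n_features)
    return m.subset_features(kept)


def _ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided two-sample rank-sum p-value.

    Exact null distribution when both groups have at most 10 members and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    correction.  A feature constant across all samples carries no group
    information and gets p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def wilcoxon_pvalues(m: OmicsMatrix, labels: Sequence[int]) -> np.ndarray:
    """Rank-sum p-value per feature between the two label groups."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (m.n_patients,):
        raise ValidationError("labels must align with the matrix patients")
    g0, g1 = m.values[labels == 0], m.values[labels == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValidationError("both label classes must be non-empty")
    return np.array([_ranksum_pvalue(g0[:, j], g1[:, j])
                     for j in range(m.n_features)])


def _fit_view(m: OmicsMatrix, labels: Sequence[int],
              fit_patients: Sequence[str] | None) -> tuple[OmicsMatrix, np.ndarray]:
    """Restrict matrix and labels to the patients the statistics are fit on."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (m.n_patients,):
        raise ValidationError("labels must align with the matrix patients")
    if fit_patients is None:
        return m, labels
    index = {p: i for i, p in enumerate(m.patient_ids)}
    rows = [index[p] for p in fit_patients if p in index]
    return m.subset_patients([m.patient_ids[r] for r in rows]), labels[rows]


def _top_k(fraction: float, n: int) -> int:
    return max(1, math.ceil(fraction * n))


def wilcoxon_select(m: OmicsMatrix, labels: Sequence[int], mode: str = "significant",
                    config: ReductionConfig | None = None,
                    fit_patients: Sequence[str] | None = None) -> OmicsMatrix:
    """Keep features that separate the two label groups.

    ``mode="significant"`` keeps p < ``p_threshold``; ``mode="top_fraction"``
    keeps the smallest ``top_fraction`` of p-values regardless of
    significance, ties broken by feature id.  ``fit_patients`` restricts the
    test to those patients (train-only scope); the selected columns are then
    returned for the full matrix.
    """
    if mode not in ("significant", "top_fraction"):
        raise ValidationError(f"unknown mode {mode!r}")
    config = config or ReductionConfig(strategy="wilcoxon_p")
    fit_m, fit_labels = _fit_view(m, labels, fit_patients)
    pvals = wilcoxon_pvalues(fit_m, fit_labels)
    if mode == "significant":
        kept = [f for f, p in zip(m.feature_ids, pvals) if p < config.p_threshold]
        if not kept:
            raise ValidationError("no features significant at "
                                  f"p < {config.p_threshold}")
    else:
        k = _top_k(config.top_fraction, m.n_features)
        order = sorted(range(m.n_features), key=lambda j: (pvals[j], m.feature_ids[j]))
        kept = sorted((m.feature_ids[j] for j in order[:k]),
                      key=m.feature_ids.index)
    logger.info("wilcoxon_select(%s): kept %d/%d features", mode, len(kept),
                m.n_features)
    return m.subset_features(kept)


def variance_select(m: OmicsMatrix, top_fraction: float = 0.10,
                    fit_patients: Sequence[str] | None = None) -> OmicsMatrix:
    """Keep the most varying fraction of features, ties broken by feature id."""
    if m.n_features < 10:
        raise ValidationError("variance_select needs at least 10 features")
    fit_m = m if fit_patients is None else m.subset_patients(list(fit_patients))
    var = fit_m.values.var(axis=0, ddof=1)
    k = _top_k(top_fraction, m.n_features)
    order = sorted(range(m.n_features), key=lambda j: (-var[j], m.feature_ids[j]))
    kept = sorted((m.feature_ids[j] for j in order[:k]), key=m.feature_ids.index)
    return m.subset_features(kept)


def pca_reduce(m: OmicsMatrix, variance_target: float = 0.90,
               fit_patients: Sequence[str] | None = None) -> OmicsMatrix:
    """Replace features by the leading principal components.

    Returns the smallest set of leading components whose cumulative explained
    variance ratio exceeds ``variance_target`` (at least one), as
    pseudo-features ``PC1..PCk``.
    """
    if m.n_patients < 2:
        raise ValidationError("pca_reduce needs at least 2 patients")
    if np.allclose(m.values.var(axis=0), 0.0):
        raise ValidationError("zero-variance matrix: PCA undefined")
    fit_m = m if fit_patients is None else m.subset_patients(list(fit_patients))
    n_max = min(fit_m.n_patients - 1, fit_m.n_features)
    pca = PCA(n_components=n_max, svd_solver="full")
    pca.fit(fit_m.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    above = np.nonzero(cum > variance_target)[0]
    k = int(above[0]) + 1 if len(above) else n_max
    scores = pca.transform(m.values)[:, :k]
    return OmicsMatrix(list(m.patient_ids), [f"PC{i + 1}" for i in range(k)],
                       scores, m.source_tag)


def reduce_matrix(m: OmicsMatrix, config: ReductionConfig,
                  labels: Sequence[int] | None = None,
                  fit_patients: Sequence[str] | None = None) -> OmicsMatrix:
    """Dispatch one reduction strategy; labels required for Wilcoxon modes."""
    if config.fit_scope == "all_samples":
        fit_patients = None
    if config.strategy == "none":
        return m
    if config.strategy in ("wilcoxon_p", "wilcoxon_top"):
        if labels is None:
            raise ValidationError("Wilcoxon strategies require endpoint labels")
        mode = "significant" if config.strategy == "wilcoxon_p" else "top_fraction"
        return wilcoxon_select(m, labels, mode, config, fit_patients)
    if config.strategy == "variance_top":
        return variance_select(m, config.top_fraction, fit_patients)
    return pca_reduce(m, config.variance_target, fit_patients)


def align_cohorts(omics: Sequence[OmicsMatrix],
                  clinical: ClinicalTable) -> dict[str, list[str]]:
    """Intersect patient coverage into 'large' and 'small' cohort views.

    The large cohort holds every patient covered by all sources except the
    last (the transcriptomic-class sources); the small cohort additionally
    requires the last source.  Both are sorted for determinism.
    """
    if not omics:
        raise ValidationError("no omics matrices given")
    clin = set(clinical.patient_ids)
    large = clin.copy()
    for m in omics[:-1]:
        large &= set(m.patient_ids)
    small = large & set(omics[-1].patient_ids)
    if len(omics) == 1:
        large = small = clin & set(omics[0].patient_ids)
    if not large:
        raise ValidationError("no patient shared by the large-cohort sources")
    if not small:
        warnings.warn("small cohort is empty: last source shares no patients",
                      stacklevel=2)
    return {"large": sorted(large), "small": sorted(small)}
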