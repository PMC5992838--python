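"""Patient Similarity Network inference.

A PSN is inferred per omics source by (1) computing Pearson correlations
between every pair of patient profiles, (2) min-max normalizing the
correlations and raising them to a soft-threshold power ``beta``
(WGCNA-style), which pushes the weighted-degree distribution toward
scale-free topology without pruning any edge:

    w_ab = ((c_ab - min(C)) / (max(C) - min(C))) ** beta

with ``C`` the multiset of all pairwise correlations.  ``beta`` is chosen as
the smallest candidate whose truncated scale-free fit index reaches the
target (0.90 by default); ``beta = 1`` is the un-thresholded control
("correl" networks).  Multiple PSNs over the same patients can be merged by
Similarity Network Fusion (SNF): iterative cross-diffusion of each network's
full kernel through the K-nearest-neighbour local kernels of the others.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import (CorrelationMatrix, OmicsMatrix,
                        PatientSimilarityNetwork, ValidationError)

logger = logging.getLogger(__name__)


class ScaleFreeWarning(UserWarning):
    """No candidate beta reached the scale-free fit target."""


@dataclass
class PSNConfig:
    beta_candidates: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    scale_free_target: float = 0.90
    tag: str = "WGCNA"
    fit_bins: int = 10

    def __post_init__(self) -> None:
        if not self.beta_candidates:
            raise ValidationError("beta_candidates must be non-empty")
        if list(self.beta_candidates) != sorted(self.beta_candidates):
            raise ValidationError("beta_candidates must be sorted ascending")
        if not 0.0 <= self.scale_free_target <= 1.0:
            raise ValidationError("scale_free_target must be in [0, 1]")
        if self.fit_bins < 3:
            raise ValidationError("fit_bins must be at least 3")


@dataclass
class FusionConfig:
    K: int = 10
    T: int = 50

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError("K must be at least 1")
        if self.T < 1:
            raise ValidationError("T must be at least 1")


def pearson_psn(m: OmicsMatrix) -> CorrelationMatrix:
    """Pearson correlation between all patient-pair profiles."""
    if m.n_features < 2:
        raise ValidationError("need at least 2 features to correlate profiles")
    if np.isnan(m.values).any():
        raise ValidationError("matrix contains missing values; run "
                              "drop_missing_features first")
    sd = m.values.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if len(flat):
        raise ValidationError(
            f"patient {m.patient_ids[flat[0]]!r} has a zero-variance profile"
        )
    c = np.corrcoef(m.values)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(list(m.patient_ids), c)


def rescale_correlations(cm: CorrelationMatrix, beta: float,
                         source_tag: str = "") -> PatientSimilarityNetwork:
    """Min-max rescale correlations to [0, 1] and raise to the power beta."""
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    off = cm.offdiag()
    lo, hi = off.min(), off.max()
    if hi <= lo:
        raise ValidationError("degenerate correlation range: max(C) == min(C)")
    w = ((cm.c - lo) / (hi - lo)) ** beta
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    tag = "WGCNA" if beta > 1 else "correl"
    meta = {"tag": tag, "beta": float(beta), "source_tag": source_tag}
    return PatientSimilarityNetwork(list(cm.patient_ids), w, meta)


def scale_free_fit(psn: PatientSimilarityNetwork, bins: int = 10) -> float:
    """Truncated scale-free topology fit index (R-squared) in [0, 1].

    Node connectivity is the weighted degree ``k_i = sum_j w_ij``.  The
    connectivities are histogrammed into equal-width bins; within each
    non-empty bin the mean connectivity and the node frequency are taken, and
    ``log10(frequency)`` is regressed on ``log10(mean k)`` and ``mean k``
    jointly — a power law with exponential truncation.  The index is the
    R-squared of that regression.
    """
    k = psn.w.sum(axis=1)
    n = len(k)
    if bins * 3 > n:
        bins = max(3, n // 3)
        logger.info("scale_free_fit: reduced bins to %d for %d nodes", bins, n)
    return truncated_fit_index(k, bins)


def truncated_fit_index(k: np.ndarray, bins: int = 10) -> float:
    """Truncated fit index of a connectivity vector (see scale_free_fit)."""
    k = np.asarray(k, dtype=float)
    n = len(k)
    if np.ptp(k) < 1e-12:
        warnings.warn("all connectivities equal: scale-free fit undefined",
                      stacklevel=2)
        return 0.0
    edges = np.linspace(k.min(), k.max(), bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, bins - 1)
    mean_k, freq = [], []
    for b in range(bins):
        members = k[which == b]
        if len(members) == 0 or members.mean() <= 0:
            continue
        mean_k.append(members.mean())
        freq.append(len(members) / n)
    if len(mean_k) < 3:
        warnings.warn("fewer than 3 occupied connectivity bins: fit index 0",
                      stacklevel=2)
        return 0.0
    mean_k = np.asarray(mean_k)
    y = np.log10(np.asarray(freq))
    X = np.column_stack([np.ones_like(mean_k), np.log10(mean_k), mean_k])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = ((y - y.mean()) ** 2).sum()
    if sst <= 0:
        return 0.0
    r2 = 1.0 - (resid ** 2).sum() / sst
    return float(min(max(r2, 0.0), 1.0))


def select_beta(cm: CorrelationMatrix, config: PSNConfig | None = None,
                source_tag: str = "") -> tuple[int, PatientSimilarityNetwork]:
    """Smallest candidate beta whose scale-free fit reaches the target.

    Candidates are evaluated in ascending order; if none reaches the target
    the best-fitting candidate is returned with a :class:`ScaleFreeWarning`.
    """
    config = config or PSNConfig()
    best_beta, best_psn, best_fit = None, None, -1.0
    for beta in config.beta_candidates:
        psn = rescale_correlations(cm, beta, source_tag)
        fit = scale_free_fit(psn, config.fit_bins)
        psn.meta["fit_index"] = fit
        logger.info("select_beta: beta=%d fit=%.4f", beta, fit)
        if fit >= config.scale_free_target:
            return int(beta), psn
        if fit > best_fit:
            best_beta, best_psn, best_fit = int(beta), psn, fit
    warnings.warn(
        f"no beta in {config.beta_candidates} reached scale-free fit "
        f">= {config.scale_free_target:.2f}; using beta={best_beta} "
        f"(fit={best_fit:.3f})", ScaleFreeWarning, stacklevel=2)
    return best_beta, best_psn


def _full_kernel(w: np.ndarray) -> np.ndarray:
    """SNF full kernel: off-diagonal mass halved row-wise, 1/2 on diagonal."""
    n = w.shape[0]
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    p = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _local_kernel(w: np.ndarray, K: int) -> np.ndarray:
    """SNF local kernel: row-normalized weights restricted to K nearest
    neighbours (self excluded), zero elsewhere."""
    n = w.shape[0]
    off = w.copy()
    np.fill_diagonal(off, -np.inf)
    s = np.zeros_like(w)
    for i in range(n):
        nbrs = np.argsort(-off[i])[:K]
        vals = np.clip(w[i, nbrs], 0.0, None)
        tot = vals.sum()
        if tot > 0:
            s[i, nbrs] = vals / tot
        else:
            s[i, nbrs] = 1.0 / len(nbrs)
    return s


def fuse_networks(psns: list[PatientSimilarityNetwork],
                  config: FusionConfig | None = None) -> PatientSimilarityNetwork:
    """Similarity Network Fusion of two or more PSNs on the same patients.

    Each network is turned into a full kernel ``P`` and a K-nearest-neighbour
    local kernel ``S``; for ``T`` iterations each ``P`` is replaced by
    ``S @ mean(other P's) @ S.T`` (then symmetrized and renormalized).  The
    fused output is the symmetrized average of the converged kernels, min-max
    rescaled to [0, 1] with a zero diagonal.
    """
    config = config or FusionConfig()
    if len(psns) < 2:
        raise ValidationError("fusion needs at least 2 networks")
    ids = psns[0].patient_ids
    for other in psns[1:]:
        if other.patient_ids != ids:
            diff = set(other.patient_ids) ^ set(ids)
            raise ValidationError(f"patient sets differ between networks: "
                                  f"{sorted(diff)[:10]}")
    n = len(ids)
    if config.K >= n:
        raise ValidationError(f"K={config.K} must be smaller than {n} patients")
    P = [_full_kernel(p.w) for p in psns]
    S = [_local_kernel(p.w, config.K) for p in psns]
    for _ in range(config.T):
        new = []
        for v in range(len(P)):
            others = [P[u] for u in range(len(P)) if u != v]
            mean_others = np.mean(others, axis=0)
            p = S[v] @ mean_others @ S[v].T
            p = (p + p.T) / 2.0
            new.append(_full_kernel(p))
        P = new
    fused = np.mean(P, axis=0)
    fused = (fused + fused.T) / 2.0
    np.fill_diagonal(fused, 0.0)
    lo, hi = fused.min(), fused.max()
    if hi > lo:
        fused = (fused - lo) / (hi - lo)
    np.fill_diagonal(fused, 0.0)
    meta = {"tag": "fused", "beta": None, "K": config.K, "T": config.T,
            "source_tag": "+".join(str(p.meta.get("source_tag", "?"))
                                   for p in psns)}
    return PatientSimilarityNetwork(list(ids), fused, meta)
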