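"""Module (community) features of a patient similarity network.

Two partitioning families are applied to each network and every near-optimal
partition is kept:

* spectral clustering on the weight matrix, with the number of modules
  chosen by the eigengap of the normalized graph Laplacian;
* a weighted degree-corrected stochastic block model (dc-SBM), fitted by
  spectral initialization plus greedy node moves, with the number of blocks
  chosen by a description-length criterion (profile log-likelihood penalized
  by the parameter and assignment coding costs).

Module memberships are then one-hot encoded and concatenated: a node ends up
with ``sum_s k_s`` binary features over the retained partitions ``s``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .datatypes import PatientSimilarityNetwork, TopoFeatureSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    method: str                  # "spectral" | "sbm"
    k_s: int
    assignment: dict[str, int]   # node -> module label in 1..k_s
    criterion_value: float

    def labels_for(self, ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[p] for p in ids], dtype=int)


def _canonical_labels(raw: np.ndarray, ids: list[str]) -> dict[str, int]:
    """Relabel modules by decreasing size (ties by first member id)."""
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(idx)
    order = sorted(groups, key=lambda g: (-len(groups[g]), ids[groups[g][0]]))
    remap = {g: rank + 1 for rank, g in enumerate(order)}
    return {ids[i]: remap[int(raw[i])] for i in range(len(ids))}


def _spectral_embedding(w: np.ndarray, k: int) -> np.ndarray:
    d = w.sum(axis=1)
    d[d == 0] = 1.0
    dinv = 1.0 / np.sqrt(d)
    lsym = np.eye(len(w)) - dinv[:, None] * w * dinv[None, :]
    vals, vecs = eigh(lsym, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vecs / norms


def _laplacian_eigenvalues(w: np.ndarray, upto: int) -> np.ndarray:
    d = w.sum(axis=1)
    d[d == 0] = 1.0
    dinv = 1.0 / np.sqrt(d)
    lsym = np.eye(len(w)) - dinv[:, None] * w * dinv[None, :]
    vals = eigh(lsym, eigvals_only=True, subset_by_index=(0, upto))
    return np.clip(vals, 0.0, None)


def _clip_range(k_range: tuple[int, int], n: int) -> tuple[int, int]:
    lo, hi = k_range
    if hi >= n:
        warnings.warn(f"k_range upper bound {hi} clipped to {n - 1}",
                      stacklevel=3)
        hi = n - 1
    if lo < 2:
        lo = 2
    if lo > hi:
        raise ValidationError(f"empty module count range after clipping: "
                              f"({lo}, {hi})")
    return lo, hi


def spectral_partitions(psn: PatientSimilarityNetwork,
                        k_range: tuple[int, int] = (2, 10),
                        tolerance: float = 0.05,
                        rng_seed: int = 0) -> list[ModulePartition]:
    """Spectral partitions for every near-optimal module count.

    The criterion for k is the eigengap ``lambda_{k+1} - lambda_k`` of the
    normalized Laplacian; every k whose gap is within ``tolerance``
    (relative) of the best gap is retained.
    """
    n = psn.n_patients
    if n < 4:
        raise ValidationError("need at least 4 patients to partition")
    lo, hi = _clip_range(k_range, n)
    vals = _laplacian_eigenvalues(psn.w, min(hi, n - 1))
    gaps = {k: float(vals[k] - vals[k - 1]) for k in range(lo, hi + 1)
            if k < len(vals)}
    if not gaps:
        raise ValidationError("could not evaluate any module count")
    best = max(gaps.values())
    keep = [k for k, g in sorted(gaps.items())
            if g >= best - tolerance * abs(best)]
    out = []
    for k in keep:
        emb = _spectral_embedding(psn.w, k)
        km = KMeans(n_clusters=k, n_init=10, random_state=rng_seed)
        raw = km.fit_predict(emb)
        out.append(ModulePartition(
            method="spectral", k_s=k,
            assignment=_canonical_labels(raw, psn.patient_ids),
            criterion_value=gaps[k]))
    return out


# ---------------------------------------------------------------------------
# weighted degree-corrected block model


def _dcsbm_loglik(m_rs: np.ndarray, kappa: np.ndarray) -> float:
    """Profile log-likelihood sum_rs m_rs * log(m_rs / (kappa_r kappa_s))."""
    kk = np.outer(kappa, kappa)
    ok = (m_rs > 0) & (kk > 0)
    return float(np.sum(m_rs[ok] * np.log(m_rs[ok] / kk[ok])))


def _fit_dcsbm(w: np.ndarray, k: int, rng_seed: int,
               max_passes: int = 10) -> tuple[np.ndarray, float]:
    n = len(w)
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        emb = _spectral_embedding(w, k)
        km = KMeans(n_clusters=k, n_init=10, random_state=rng_seed)
        labels = km.fit_predict(emb)
    deg = w.sum(axis=1)
    # node-to-group weight sums, updated incrementally during moves
    ind = np.zeros((n, k))
    ind[np.arange(n), labels] = 1.0
    node_group = w @ ind                       # n x k
    m_rs = ind.T @ w @ ind                     # group-group total weight
    kappa = deg @ ind                          # group weighted degrees
    loglik = _dcsbm_loglik(m_rs, kappa)
    if k == 1:
        return labels, loglik
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            r = labels[i]
            best_s, best_gain = r, 0.0
            for s in range(k):
                if s == r:
                    continue
                m_try = m_rs.copy()
                kap_try = kappa.copy()
                # move node i from r to s
                for t in range(k):
                    delta = node_group[i, t]
                    m_try[r, t] -= delta
                    m_try[t, r] -= delta
                    m_try[s, t] += delta
                    m_try[t, s] += delta
                # self-weight w[i,i]=0, so the rr/ss corrections vanish
                kap_try[r] -= deg[i]
                kap_try[s] += deg[i]
                gain = _dcsbm_loglik(m_try, kap_try) - loglik
                if gain > best_gain + 1e-10:
                    best_gain, best_s = gain, s
            if best_s != r:
                s = best_s
                for t in range(k):
                    delta = node_group[i, t]
                    m_rs[r, t] -= delta
                    m_rs[t, r] -= delta
                    m_rs[s, t] += delta
                    m_rs[t, s] += delta
                kappa[r] -= deg[i]
                kappa[s] += deg[i]
                labels[i] = s
                node_group -= np.outer(w[:, i], np.eye(k)[r])
                node_group += np.outer(w[:, i], np.eye(k)[s])
                loglik += best_gain
                improved = True
        if not improved:
            break
    return labels, loglik


def _description_length(loglik: float, k: int, n: int) -> float:
    m_obs = n * (n - 1) / 2.0
    param_cost = 0.5 * (k * (k + 1) / 2.0) * np.log(m_obs)
    assign_cost = n * np.log(k) if k > 1 else 0.0
    return -loglik + param_cost + assign_cost


def sbm_partitions(psn: PatientSimilarityNetwork,
                   k_range: tuple[int, int] = (2, 10),
                   tolerance: float = 0.05,
                   rng_seed: int = 0) -> list[ModulePartition]:
    """Weighted dc-SBM partitions for every near-optimal block count.

    Block counts from 1 (single community) to the top of ``k_range`` are
    fitted; the description length (negative profile log-likelihood plus
    parameter and assignment coding costs) selects the optimum, and every k
    within ``tolerance`` (relative) of the best description length is kept.
    On any fit failure an empty list is returned with a warning so the
    pipeline can proceed with spectral partitions alone.
    """
    n = psn.n_patients
    if n < 4:
        raise ValidationError("need at least 4 patients to partition")
    try:
        _, hi = _clip_range(k_range, n)
        fits: dict[int, tuple[np.ndarray, float]] = {}
        dls: dict[int, float] = {}
        for k in range(1, hi + 1):
            labels, loglik = _fit_dcsbm(psn.w, k, rng_seed)
            fits[k] = (labels, loglik)
            dls[k] = _description_length(loglik, k, n)
        best = min(dls.values())
        keep = [k for k in sorted(dls) if dls[k] <= best + tolerance * abs(best)]
        out = []
        for k in keep:
            labels, _ = fits[k]
            k_eff = len(np.unique(labels))
            out.append(ModulePartition(
                method="sbm", k_s=k_eff,
                assignment=_canonical_labels(labels, psn.patient_ids),
                criterion_value=dls[k]))
        return out
    except Exception as exc:  # noqa: BLE001 - contract: degrade, never abort
        warnings.warn(f"SBM fit failed ({exc}); proceeding without SBM "
                      "partitions", stacklevel=2)
        return []


def encode_membership(partitions: list[ModulePartition],
                      patient_ids: list[str] | None = None) -> TopoFeatureSet:
    """One-hot encode each partition and concatenate the blocks."""
    if not partitions:
        raise ValidationError("no partitions to encode")
    ids = patient_ids or sorted(partitions[0].assignment)
    blocks, names = [], []
    for s_idx, part in enumerate(partitions):
        if set(part.assignment) != set(ids):
            raise ValidationError("partitions cover different node sets")
        labels = part.labels_for(list(ids))
        onehot = np.zeros((len(ids), part.k_s))
        onehot[np.arange(len(ids)), labels - 1] = 1.0
        blocks.append(onehot)
        names.extend(f"{part.method}{s_idx}_m{j + 1}" for j in range(part.k_s))
    values = np.hstack(blocks)
    return TopoFeatureSet(list(ids), names, values, family="modularity")


def modularity_features(psn: PatientSimilarityNetwork,
                        k_range: tuple[int, int] = (2, 10),
                        tolerance: float = 0.05,
                        rng_seed: int = 0) -> TopoFeatureSet:
    """Spectral + SBM near-optimal partitions, one-hot encoded."""
    parts = spectral_partitions(psn, k_range, tolerance, rng_seed)
    parts += sbm_partitions(psn, k_range, tolerance, rng_seed)
    return encode_membership(parts, list(psn.patient_ids))
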