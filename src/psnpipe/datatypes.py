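"""Core containers shared across the pipeline.

The unit of data is a patients x features numeric matrix tagged with its
source (e.g. ``"microarray"``, ``"rnaseq"``); patient similarity networks are
complete weighted undirected graphs over the same patient ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} ids")
    return ids


@dataclass
class OmicsMatrix:
    """A patients x features numeric matrix from one omics source.

    Parameters
    ----------
    patient_ids : ordered patient identifiers (rows).
    feature_ids : ordered feature identifiers (columns).
    values : float array of shape ``(n_patients, n_features)``; may contain
        NaN until :func:`psnpipe.preprocess.drop_missing_features` is applied.
    source_tag : label of the originating data source.
    """

    patient_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    source_tag: str = "omics"

    def __post_init__(self) -> None:
        self.patient_ids = _check_unique(self.patient_ids, "patient")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_patients(self, ids: Sequence[str]) -> "OmicsMatrix":
        index = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in ids if p not in index]
        if missing:
            raise ValidationError(f"unknown patient ids: {missing[:5]}")
        rows = [index[p] for p in ids]
        return OmicsMatrix(list(ids), list(self.feature_ids),
                           self.values[rows, :], self.source_tag)

    def subset_features(self, ids: Sequence[str]) -> "OmicsMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing[:5]}")
        cols = [index[f] for f in ids]
        return OmicsMatrix(list(self.patient_ids), list(ids),
                           self.values[:, cols], self.source_tag)


@dataclass
class ClinicalTable:
    """Binary clinical endpoints per patient (values in {0, 1})."""

    patient_ids: list[str]
    endpoints: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.patient_ids = _check_unique(self.patient_ids, "patient")
        clean: dict[str, np.ndarray] = {}
        for name, vec in self.endpoints.items():
            arr = np.asarray(vec, dtype=int)
            if arr.shape != (len(self.patient_ids),):
                raise ValidationError(
                    f"endpoint {name!r} has {arr.shape} values for "
                    f"{len(self.patient_ids)} patients"
                )
            if not np.isin(arr, (0, 1)).all():
                raise ValidationError(f"endpoint {name!r} is not binary")
            clean[name] = arr
        self.endpoints = clean

    def labels(self, endpoint: str, patient_ids: Sequence[str] | None = None) -> np.ndarray:
        if endpoint not in self.endpoints:
            raise ValidationError(f"unknown endpoint {endpoint!r}")
        vec = self.endpoints[endpoint]
        if patient_ids is None:
            return vec.copy()
        index = {p: i for i, p in enumerate(self.patient_ids)}
        try:
            rows = [index[p] for p in patient_ids]
        except KeyError as exc:
            raise ValidationError(f"patient {exc.args[0]!r} not in clinical table")
        return vec[rows]


@dataclass
class PatientSimilarityNetwork:
    """Complete weighted undirected graph over patients.

    Weights lie in [0, 1] with a zero diagonal.  ``meta`` records how the
    network was produced: ``tag`` in {"WGCNA", "correl", "fused"}, the soft
    threshold ``beta``, the source tag and the scale-free ``fit_index``.
    """

    patient_ids: list[str]
    w: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patient_ids = _check_unique(self.patient_ids, "patient")
        w = np.asarray(self.w, dtype=float)
        n = len(self.patient_ids)
        if w.shape != (n, n):
            raise ValidationError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValidationError("weight matrix is not symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 1e-12:
            raise ValidationError("weight matrix diagonal must be zero")
        if w.min(initial=0.0) < -1e-12 or w.max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("weights must lie in [0, 1]")
        self.w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.w, 0.0)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of Pearson coefficients between patient profiles."""

    patient_ids: list[str]
    c: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = _check_unique(self.patient_ids, "patient")
        c = np.asarray(self.c, dtype=float)
        n = len(self.patient_ids)
        if c.shape != (n, n):
            raise ValidationError(f"correlation matrix shape {c.shape} != ({n}, {n})")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValidationError("correlation matrix is not symmetric")
        self.c = (c + c.T) / 2.0

    def offdiag(self) -> np.ndarray:
        """The multiset C of off-diagonal correlations (upper triangle)."""
        iu = np.triu_indices(len(self.patient_ids), k=1)
        return self.c[iu]


@dataclass
class TopoFeatureSet:
    """Patients x features matrix tagged by feature family."""

    patient_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    family: str  # centrality | modularity | embedding | diffusion
    standardized: bool = False

    def __post_init__(self) -> None:
        self.patient_ids = _check_unique(self.patient_ids, "patient")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ValidationError("feature matrix shape mismatch")
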