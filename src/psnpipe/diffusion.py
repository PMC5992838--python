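"""Diffusion features: post-propagation signal of random binary seed sets.

Each feature column comes from one diffusion round: 10% of the nodes are
drawn at random and given signal 1 (the rest 0), the signal is propagated
through a graph kernel, and the smoothed value at every node is recorded.
With the default 1,000 rounds each node gains 1,000 features.

The default kernel is the regularized Laplacian ``K = (I + L)^-1`` with
``L = D - W`` the weighted graph Laplacian (always invertible, symmetric
positive definite); a heat kernel ``K = expm(-tL)`` is available as an
alternative.  The kernel is computed once per network and reused across all
diffusion rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .datatypes import PatientSimilarityNetwork, TopoFeatureSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DiffusionConfig:
    n_diffusions: int = 1000
    seed_fraction: float = 0.10
    kernel: str = "regularized_laplacian"   # or "heat"
    heat_time: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diffusions < 1:
            raise ValidationError("n_diffusions must be >= 1")
        if not 0.0 < self.seed_fraction < 1.0:
            raise ValidationError("seed_fraction must be in (0, 1)")
        if self.kernel not in ("regularized_laplacian", "heat"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "heat" and self.heat_time <= 0:
            raise ValidationError("heat_time must be positive")


def diffusion_kernel(psn: PatientSimilarityNetwork,
                     config: DiffusionConfig | None = None) -> np.ndarray:
    """Symmetric PSD smoothing kernel of the network."""
    config = config or DiffusionConfig()
    if psn.w.min() < 0:
        raise ValidationError("negative weights: Laplacian undefined")
    lap = np.diag(psn.w.sum(axis=1)) - psn.w
    if config.kernel == "regularized_laplacian":
        k = np.linalg.inv(np.eye(len(lap)) + lap)
    else:
        k = expm(-config.heat_time * lap)
        if not np.isfinite(k).all():
            raise ValidationError("heat kernel overflowed; reduce heat_time")
    return (k + k.T) / 2.0


def propagate(kernel: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Smooth one signal vector (or matrix of column signals)."""
    return kernel @ signal


def diffusion_features(psn: PatientSimilarityNetwork,
                       config: DiffusionConfig | None = None) -> TopoFeatureSet:
    """One column per diffusion round of a random 10% seed set."""
    config = config or DiffusionConfig()
    n = psn.n_patients
    n_seeds = int(round(config.seed_fraction * n))
    if n_seeds == 0:
        raise ValidationError(
            f"cohort too small: {config.seed_fraction:.0%} of {n} nodes is 0 seeds")
    if n_seeds < 2:
        logger.warning("only %d seed node(s) per diffusion on %d nodes",
                       n_seeds, n)
    kernel = diffusion_kernel(psn, config)
    rng = np.random.default_rng(config.rng_seed)
    signals = np.zeros((n, config.n_diffusions))
    for col in range(config.n_diffusions):
        seeds = rng.choice(n, size=n_seeds, replace=False)
        signals[seeds, col] = 1.0
    values = propagate(kernel, signals)
    names = [f"diff_{i}" for i in range(config.n_diffusions)]
    return TopoFeatureSet(list(psn.patient_ids), names, values,
                          family="diffusion")
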