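"""Synthetic multi-omics cohorts with planted class structure.

Real cohorts of this kind pair transcriptome-wide profiles for every patient
with a genomic source available only for a subset, plus a handful of binary
clinical endpoints.  The generator emulates exactly that: several correlated
feature matrices over a shared patient set, a smaller last source covering a
patient subset, Bernoulli endpoint labels, and a known set of "signal"
features whose mean is shifted in the positive class.  Everything is
reproducible from a single seed, and the planted truth is returned so that
feature-selection and classification stages can be scored against it.

Correlated feature blocks use a latent-factor construction: within a block,
``x = sqrt(rho) * z_block + sqrt(1 - rho) * eps`` with ``z_block`` shared by
the block's features, which gives pairwise correlation ``rho`` in
expectation.  :func:`modular_profiles` uses the same construction across
*patients* to plant community structure in the similarity network itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .datatypes import ClinicalTable, OmicsMatrix, ValidationError


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``n_signal_features`` may be a single count applied to every
    (source, endpoint) pair or a mapping ``{(source_tag, endpoint): count}``.
    ``effect_size`` is the positive-class mean shift in units of the feature
    SD.  The last source in ``sources`` covers only ``small_cohort_fraction``
    of the patients; set ``small_bias_endpoint`` to bias that subset toward
    positive patients of one endpoint (``small_bias_strength`` is the
    selection-odds multiplier for positives).
    """

    n_patients: int
    sources: list[tuple[str, int]]
    endpoints: list[tuple[str, float]]
    n_signal_features: int | dict = 20
    effect_size: float = 1.0
    block_correlation: float = 0.3
    block_size: int = 10
    noise_sd: float = 1.0
    small_cohort_fraction: float = 1.0
    small_bias_endpoint: str | None = None
    small_bias_strength: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be at least 2")
        if not self.sources:
            raise ValidationError("sources must be non-empty")
        if not self.endpoints:
            raise ValidationError("endpoints must be non-empty")
        for tag, nf in self.sources:
            if nf < 1:
                raise ValidationError(f"source {tag!r}: n_features must be positive")
        for name, prev in self.endpoints:
            if not 0.0 < prev < 1.0:
                raise ValidationError(
                    f"endpoint {name!r}: prevalence must be strictly in (0, 1)"
                )
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValidationError("block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0.0 < self.small_cohort_fraction <= 1.0:
            raise ValidationError("small_cohort_fraction must be in (0, 1]")
        if self.block_size < 1:
            raise ValidationError("block_size must be positive")
        for tag, nf in self.sources:
            for name, _ in self.endpoints:
                if self.signal_count(tag, name) > nf:
                    raise ValidationError(
                        f"n_signal_features for ({tag!r}, {name!r}) exceeds "
                        f"the source's {nf} features"
                    )

    def signal_count(self, source_tag: str, endpoint: str) -> int:
        if isinstance(self.n_signal_features, dict):
            n = int(self.n_signal_features.get((source_tag, endpoint), 0))
        else:
            n = int(self.n_signal_features)
        if n < 0:
            raise ValidationError("n_signal_features must be non-negative")
        return n


@dataclass
class SyntheticCohort:
    """Generated cohort: omics matrices, clinical labels and planted truth."""

    omics: dict[str, OmicsMatrix]
    clinical: ClinicalTable
    truth: dict[tuple[str, str], list[str]]
    spec: CohortSpec | None = field(default=None, repr=False)


def _patient_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"P{i:0{width}d}" for i in range(n)]


def _block_noise(rng: np.random.Generator, n_patients: int, n_features: int,
                 rho: float, block_size: int) -> np.ndarray:
    """Feature matrix with within-block correlation rho, unit marginal SD."""
    eps = rng.standard_normal((n_patients, n_features))
    if rho <= 0:
        return eps
    n_blocks = int(np.ceil(n_features / block_size))
    z = rng.standard_normal((n_patients, n_blocks))
    block_of = np.repeat(np.arange(n_blocks), block_size)[:n_features]
    return np.sqrt(rho) * z[:, block_of] + np.sqrt(1.0 - rho) * eps


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``spec``.

    Labels are Bernoulli(prevalence) per endpoint, independent across
    endpoints.  Signal features gain ``effect_size * noise_sd`` in the
    positive class; all other features are pure (block-correlated) noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    patients = _patient_ids(spec.n_patients)

    endpoints: dict[str, np.ndarray] = {}
    for name, prev in spec.endpoints:
        endpoints[name] = (rng.random(spec.n_patients) < prev).astype(int)
    clinical = ClinicalTable(patients, endpoints)

    omics: dict[str, OmicsMatrix] = {}
    truth: dict[tuple[str, str], list[str]] = {}
    for s_idx, (tag, n_features) in enumerate(spec.sources):
        values = spec.noise_sd * _block_noise(
            rng, spec.n_patients, n_features, spec.block_correlation, spec.block_size
        )
        feature_ids = [f"{tag}_f{i}" for i in range(n_features)]
        for name, _ in spec.endpoints:
            k = spec.signal_count(tag, name)
            cols = rng.choice(n_features, size=k, replace=False) if k else np.array([], int)
            pos = endpoints[name] == 1
            values[np.ix_(pos, cols)] += spec.effect_size * spec.noise_sd
            truth[(tag, name)] = sorted(feature_ids[c] for c in cols)
        m = OmicsMatrix(patients, feature_ids, values, tag)
        is_last = s_idx == len(spec.sources) - 1
        if is_last and spec.small_cohort_fraction < 1.0:
            n_small = int(round(spec.small_cohort_fraction * spec.n_patients))
            n_small = max(n_small, 2)
            prob = np.ones(spec.n_patients)
            if spec.small_bias_endpoint is not None:
                lab = clinical.labels(spec.small_bias_endpoint)
                prob[lab == 1] = spec.small_bias_strength
            prob /= prob.sum()
            keep = np.sort(rng.choice(spec.n_patients, size=n_small,
                                      replace=False, p=prob))
            m = m.subset_patients([patients[i] for i in keep])
        omics[tag] = m
    return SyntheticCohort(omics=omics, clinical=clinical, truth=truth, spec=spec)


def modular_profiles(n_patients: int, n_blocks: int, rho: float,
                     n_features: int, noise_sd: float = 1.0,
                     rng_seed: int = 0, source_tag: str = "modular") -> OmicsMatrix:
    """Profiles whose patient-patient Pearson correlation is block-structured.

    Patients are split into ``n_blocks`` equal groups sharing a latent
    profile: two patients of the same block correlate at about ``rho``,
    patients of different blocks at about 0.  This is the canonical input for
    soft-threshold selection and community-detection tests, because the
    induced similarity network is modular by construction.
    """
    if n_blocks < 1 or n_blocks > n_patients:
        raise ValidationError("n_blocks must be in [1, n_patients]")
    if not 0.0 <= rho < 1.0:
        raise ValidationError("rho must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    patients = _patient_ids(n_patients)
    block_of = np.arange(n_patients) % n_blocks
    latent = rng.standard_normal((n_blocks, n_features))
    eps = rng.standard_normal((n_patients, n_features))
    values = noise_sd * (np.sqrt(rho) * latent[block_of, :] + np.sqrt(1.0 - rho) * eps)
    features = [f"{source_tag}_f{i}" for i in range(n_features)]
    return OmicsMatrix(patients, features, values, source_tag)


def write_cohort(cohort: SyntheticCohort, directory: Path | str) -> dict:
    """Write one TSV per source plus clinical and truth files.

    Returns the manifest (also written to ``manifest.yaml``): file names per
    source, the clinical and truth files, and basic shape information.
    Matrices round-trip losslessly through :mod:`psnpipe.io` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"sources": {}, "n_patients": cohort.clinical.patient_ids and
                      len(cohort.clinical.patient_ids)}
    for tag, m in cohort.omics.items():
        fname = f"{tag}.tsv"
        io.write_omics_tsv(m, directory / fname)
        manifest["sources"][tag] = {
            "file": fname, "n_patients": m.n_patients, "n_features": m.n_features,
        }
    io.write_clinical_tsv(cohort.clinical, directory / "clinical.tsv")
    manifest["clinical"] = "clinical.tsv"
    truth_plain = {f"{src}::{ep}": list(ids) for (src, ep), ids in cohort.truth.items()}
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_plain, fh)
    manifest["truth"] = "truth.yaml"
    manifest["endpoints"] = sorted(cohort.clinical.endpoints)
    io.write_manifest(manifest, directory / "manifest.yaml")
    return manifest


def read_cohort(directory: Path | str) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = io.read_manifest(directory / "manifest.yaml")
    omics = {
        tag: io.read_omics_tsv(directory / entry["file"], source_tag=tag)
        for tag, entry in manifest["sources"].items()
    }
    clinical = io.read_clinical_tsv(directory / manifest["clinical"])
    with open(directory / manifest["truth"]) as fh:
        truth_plain = yaml.safe_load(fh) or {}
    truth = {tuple(key.split("::", 1)): list(ids) for key, ids in truth_plain.items()}
    return SyntheticCohort(omics=omics, clinical=clinical, truth=truth)
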