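"""End-to-end orchestration: cohort -> PSNs -> features -> models -> vote.

Four integration modes mirror the experiment grid of the method:

* ``classical`` — classifiers consume the (reduced) omics matrices directly,
  one model per source, combined by weighted voting;
* ``topological`` — a PSN is inferred per source and one model is trained
  per (source, feature family), all combined by weighted voting;
* ``fused`` — the per-source PSNs are merged by SNF first and the feature
  families are extracted from the fused network;
* ``integrated`` — the classical and topological model sets vote together.

Every stage derives its RNG seed from the master seed, the stage name and
the source tag, so reruns with the same configuration and seed reproduce the
output tree exactly.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .centrality import compute_centralities, standardize_features
from .datatypes import TopoFeatureSet, ValidationError
from .diffusion import DiffusionConfig, diffusion_features
from .embedding import EmbeddingConfig, node2vec_features
from .modularity import modularity_features
from .modeling import (ModelConfig, compute_metrics, stratified_split,
                       train_predict, weighted_vote)
from .preprocess import (ReductionConfig, align_cohorts, drop_missing_features,
                         reduce_matrix)
from .psn import (FusionConfig, PSNConfig, fuse_networks, pearson_psn,
                  rescale_correlations, select_beta)
from .synthetic import read_cohort

logger = logging.getLogger(__name__)

MODES = ("classical", "topological", "integrated", "fused")
FAMILIES = ("centrality", "modularity", "embedding", "diffusion")


def derive_seed(master: int, stage: str, tag: str = "") -> int:
    """Stable per-stage child seed below 2**31."""
    return zlib.crc32(f"{master}:{stage}:{tag}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    cohort_dir: str
    output_dir: str
    rng_seed: int
    mode: str = "topological"
    endpoints: list[str] | None = None
    families: tuple[str, ...] = FAMILIES
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    psn: PSNConfig = field(default_factory=PSNConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    network_tag: str = "WGCNA"      # WGCNA | correl
    train_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValidationError(f"unknown feature family {fam!r}")
        if self.network_tag not in ("WGCNA", "correl"):
            raise ValidationError(f"unknown network tag {self.network_tag!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"cohort_dir", "output_dir", "rng_seed", "mode", "endpoints",
                 "families", "reduction", "psn", "fusion", "embedding",
                 "diffusion", "model", "network_tag", "train_fraction"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key, ctor in (("reduction", ReductionConfig), ("psn", PSNConfig),
                          ("fusion", FusionConfig), ("embedding", EmbeddingConfig),
                          ("diffusion", DiffusionConfig), ("model", ModelConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = ctor(**raw[key])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        if "psn" in raw and isinstance(raw["psn"], PSNConfig):
            pass
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output sink is excluded)."""
        plain = _plain_dict(self)
        plain.pop("output_dir", None)
        blob = yaml.safe_dump(plain, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain_dict(obj) -> dict:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _plain_dict(getattr(obj, k))
                for k in obj.__dataclass_fields__}
    if isinstance(obj, (list, tuple)):
        return [_plain_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _plain_dict(v) for k, v in obj.items()}
    return obj


def extract_family(psn, family: str, *, embedding: EmbeddingConfig | None = None,
                   diffusion: DiffusionConfig | None = None,
                   rng_seed: int = 0) -> TopoFeatureSet:
    """One standardized feature family for one network."""
    if family == "centrality":
        return compute_centralities(psn, standardize=True)
    if family == "modularity":
        fs = modularity_features(psn, rng_seed=rng_seed)
        return standardize_features(fs)
    if family == "embedding":
        cfg = embedding or EmbeddingConfig()
        cfg = EmbeddingConfig(**{**cfg.__dict__, "rng_seed": rng_seed})
        return standardize_features(node2vec_features(psn, cfg))
    if family == "diffusion":
        cfg = diffusion or DiffusionConfig()
        cfg = DiffusionConfig(**{**cfg.__dict__, "rng_seed": rng_seed})
        return standardize_features(diffusion_features(psn, cfg))
    raise ValidationError(f"unknown feature family {family!r}")


def infer_network(matrix, config: PSNConfig, network_tag: str,
                  source_tag: str):
    cm = pearson_psn(matrix)
    if network_tag == "correl":
        psn = rescale_correlations(cm, 1, source_tag)
        psn.meta["fit_index"] = None
        return psn
    _, psn = select_beta(cm, config, source_tag)
    return psn


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns the run manifest.

    All artifacts (networks, feature matrices, per-model and ensemble
    reports) are written under ``config.output_dir``; the manifest carries
    the config hash, derived seeds and per-endpoint results.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.cohort_dir)
    endpoints = config.endpoints or sorted(cohort.clinical.endpoints)
    sources = list(cohort.omics)
    views = align_cohorts([cohort.omics[s] for s in sources], cohort.clinical)
    # run on the patients covered by every configured source
    patients = sorted(set.intersection(
        *[set(cohort.omics[s].patient_ids) for s in sources]) &
        set(cohort.clinical.patient_ids))
    if len(patients) < 10:
        raise ValidationError("fewer than 10 patients shared by all sources")

    manifest: dict = {"config_hash": config.config_hash(),
                      "mode": config.mode, "rng_seed": config.rng_seed,
                      "cohort_views": {k: len(v) for k, v in views.items()},
                      "endpoints": {}}
    results: dict = {}
    for endpoint in endpoints:
        labels = cohort.clinical.labels(endpoint, patients)
        split = stratified_split(patients, labels, config.train_fraction,
                                 derive_seed(config.rng_seed, "split", endpoint))
        ep_dir = out / endpoint
        ep_dir.mkdir(exist_ok=True)
        reduced = {}
        for s in sources:
            m = drop_missing_features(cohort.omics[s].subset_patients(patients))
            reduced[s] = reduce_matrix(m, config.reduction, labels=labels,
                                       fit_patients=split.train)
        model_scores, model_perfs, model_names, reports = [], [], [], {}

        def _add_model(name: str, features: TopoFeatureSet, seed_tag: str):
            mc = ModelConfig(**{**config.model.__dict__,
                                "rng_seed": derive_seed(config.rng_seed,
                                                        "model", seed_tag)})
            scores, report = train_predict(features, labels, split, mc)
            model_scores.append(scores)
            model_perfs.append(report.cv_mean_bacc or 0.0)
            model_names.append(name)
            reports[name] = report
            io.write_features_tsv(features, ep_dir / f"features_{name}.tsv")

        if config.mode in ("classical", "integrated"):
            for s in sources:
                fs = TopoFeatureSet(patients, list(reduced[s].feature_ids),
                                    reduced[s].values, family="classical")
                _add_model(f"classical_{s}", fs, f"{endpoint}:{s}:classical")
        if config.mode in ("topological", "integrated", "fused"):
            psns = {}
            for s in sources:
                psn = infer_network(reduced[s], config.psn,
                                    config.network_tag, s)
                psns[s] = psn
                io.write_network_edgelist(psn, ep_dir / f"network_{s}.tsv")
            if config.mode == "fused":
                nets = {"fused": fuse_networks(list(psns.values()),
                                               config.fusion)} \
                    if len(psns) > 1 else {"fused": next(iter(psns.values()))}
                io.write_network_edgelist(nets["fused"],
                                          ep_dir / "network_fused.tsv")
            else:
                nets = psns
            for net_name, psn in nets.items():
                for family in config.families:
                    fs = extract_family(
                        psn, family, embedding=config.embedding,
                        diffusion=config.diffusion,
                        rng_seed=derive_seed(config.rng_seed, family,
                                             f"{endpoint}:{net_name}"))
                    _add_model(f"{family}_{net_name}", fs,
                               f"{endpoint}:{net_name}:{family}")

        consensus, predictions = weighted_vote(model_scores, model_perfs)
        y_test = cohort.clinical.labels(endpoint, split.test)
        vote_report = compute_metrics(
            y_test, np.array([predictions[p] for p in split.test]))
        ep_result = {
            "split": {"train": split.train, "test": split.test},
            "models": {name: _report_dict(rep)
                       for name, rep in reports.items()},
            "vote": _report_dict(vote_report),
            "weights": dict(zip(model_names,
                                (np.asarray(model_perfs)
                                 / np.sum(model_perfs)).tolist())),
        }
        io.write_manifest(ep_result, ep_dir / "report.yaml")
        _write_scores(consensus, predictions, ep_dir / "consensus.tsv")
        manifest["endpoints"][endpoint] = {
            "report": f"{endpoint}/report.yaml",
            "vote_bacc": vote_report.bacc,
        }
        results[endpoint] = ep_result
    io.write_manifest(manifest, out / "manifest.yaml")
    manifest["results"] = results
    return manifest


def _report_dict(rep) -> dict:
    return {k: (None if v is None else float(v) if isinstance(v, float) else v)
            for k, v in rep.__dict__.items()}


def _write_scores(consensus: dict, predictions: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tconsensus_score\tprediction\n")
        for p in sorted(consensus):
            fh.write(f"{p}\t{consensus[p]:.10g}\t{predictions[p]}\n")
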