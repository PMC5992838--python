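"""Readers and writers for the pipeline's on-disk formats.

Omics matrices are stored as TSV with features as rows and patients as
columns (header row = patient ids, first column = feature ids), the layout
usual for expression tables.  Clinical tables are patients x endpoints with
0/1 entries.  Networks round-trip through GraphML or a 3-column weighted
edge list; run metadata goes in YAML sidecars.
"""

from __future__ import annotations

import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import (ClinicalTable, OmicsMatrix, PatientSimilarityNetwork,
                        TopoFeatureSet, ValidationError)


def write_omics_tsv(m: OmicsMatrix, path: os.PathLike | str) -> None:
    df = pd.DataFrame(m.values.T, index=m.feature_ids, columns=m.patient_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_omics_tsv(path: os.PathLike | str, source_tag: str | None = None) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    tag = source_tag if source_tag is not None else Path(path).stem
    return OmicsMatrix(
        patient_ids=[str(c) for c in df.columns],
        feature_ids=[str(i) for i in df.index],
        values=df.to_numpy(dtype=float).T,
        source_tag=tag,
    )


def write_clinical_tsv(c: ClinicalTable, path: os.PathLike | str) -> None:
    df = pd.DataFrame(c.endpoints, index=c.patient_ids)
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t")


def read_clinical_tsv(path: os.PathLike | str) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(
        patient_ids=[str(i) for i in df.index],
        endpoints={str(c): df[c].to_numpy() for c in df.columns},
    )


def write_features_tsv(fs: TopoFeatureSet, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# family={fs.family} standardized={int(fs.standardized)}\n")
        df = pd.DataFrame(fs.values, index=fs.patient_ids, columns=fs.feature_ids)
        df.index.name = "patient_id"
        df.to_csv(fh, sep="\t")


def read_features_tsv(path: os.PathLike | str) -> TopoFeatureSet:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return TopoFeatureSet(
        patient_ids=[str(i) for i in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        family=meta.get("family", "unknown"),
        standardized=bool(int(meta.get("standardized", 0))),
    )


def write_network_edgelist(psn: PatientSimilarityNetwork, path: os.PathLike | str) -> None:
    ids = psn.patient_ids
    iu = np.triu_indices(len(ids), k=1)
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tweight\n")
        for i, j in zip(*iu):
            fh.write(f"{ids[i]}\t{ids[j]}\t{psn.w[i, j]:.17g}\n")
    _write_meta_sidecar(psn, path)


def read_network_edgelist(path: os.PathLike | str) -> PatientSimilarityNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    ids = sorted(set(df["id_a"]) | set(df["id_b"]))
    index = {p: i for i, p in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for a, b, weight in df.itertuples(index=False):
        w[index[a], index[b]] = w[index[b], index[a]] = float(weight)
    meta = _read_meta_sidecar(path)
    return PatientSimilarityNetwork(ids, w, meta)


def write_network_graphml(psn: PatientSimilarityNetwork, path: os.PathLike | str) -> None:
    g = nx.Graph()
    g.add_nodes_from(psn.patient_ids)
    ids = psn.patient_ids
    iu = np.triu_indices(len(ids), k=1)
    for i, j in zip(*iu):
        g.add_edge(ids[i], ids[j], weight=float(psn.w[i, j]))
    for key, val in psn.meta.items():
        g.graph[key] = val
    nx.write_graphml(g, path)


def read_network_graphml(path: os.PathLike | str) -> PatientSimilarityNetwork:
    g = nx.read_graphml(path)
    ids = sorted(g.nodes)
    index = {p: i for i, p in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for a, b, data in g.edges(data=True):
        w[index[a], index[b]] = w[index[b], index[a]] = float(data.get("weight", 0.0))
    return PatientSimilarityNetwork(ids, w, dict(g.graph))


def _sidecar_path(path: os.PathLike | str) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.yaml")


def _write_meta_sidecar(psn: PatientSimilarityNetwork, path: os.PathLike | str) -> None:
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump({k: _plain(v) for k, v in psn.meta.items()}, fh)


def _read_meta_sidecar(path: os.PathLike | str) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def _plain(v):
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    return v


def write_manifest(manifest: dict, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: os.PathLike | str) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValidationError(f"manifest {path} is not a mapping")
    return out
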