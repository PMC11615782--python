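"""Readers and writers for the package's tabular formats, plus run manifests.

All tables are TSV. Abundance tables are OTU rows x sample columns with the
OTU identifier in the first column; embedding and feature tables carry a
leading label column and named component columns. Readers validate rather
than coerce: negative counts, NaNs and duplicate labels are rejected with
the offending row/column named.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from deepphylo.embed import EmbeddingMatrix
from deepphylo.table import AbundanceTable
from deepphylo.unsupervised import SampleFeatures

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_embeddings",
    "write_embeddings",
    "read_features",
    "write_features",
    "read_labels",
    "write_manifest",
    "read_manifest",
]


def read_abundance_table(path: str) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    return AbundanceTable(values, [str(x) for x in df.index], [str(c) for c in df.columns])


def write_abundance_table(table: AbundanceTable, path: str) -> None:
    df = pd.DataFrame(table.values, index=table.otu_labels, columns=table.sample_labels)
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_embeddings(path: str) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return EmbeddingMatrix(df.to_numpy(dtype=float), [str(x) for x in df.index])


def write_embeddings(emb: EmbeddingMatrix, path: str) -> None:
    df = pd.DataFrame(
        emb.X, index=emb.labels, columns=[f"PC{i + 1}" for i in range(emb.d)]
    )
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_features(path: str, feature_kind: str = "fused") -> SampleFeatures:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SampleFeatures(df.to_numpy(dtype=float), [str(x) for x in df.index], feature_kind)


def write_features(feat: SampleFeatures, path: str) -> None:
    df = pd.DataFrame(
        feat.F, index=feat.sample_labels, columns=[f"F{i + 1}" for i in range(feat.q)]
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labels(path: str, column: str | None = None) -> pd.Series:
    """Per-sample metadata column keyed by the first (sample-id) column."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if column is None:
        if df.shape[1] != 1:
            raise ValueError(f"specify a column; available: {list(df.columns)}")
        column = df.columns[0]
    if column not in df.columns:
        raise ValueError(f"column {column!r} not in {list(df.columns)}")
    return df[column]


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_REQUIRED_MANIFEST_KEYS = ("subcommand", "seed", "parameters")


def write_manifest(out_dir: str, subcommand: str, seed: int, parameters: dict,
                   inputs: dict | None = None, results: dict | None = None) -> str:
    """Write a run manifest capturing parameters, seed and input checksums."""
    manifest = {
        "subcommand": subcommand,
        "seed": seed,
        "parameters": parameters,
        "input_checksums": {
            name: file_checksum(p) for name, p in (inputs or {}).items() if os.path.exists(p)
        },
        "results": results or {},
    }
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_manifest(path: str) -> dict:
    with open(path) as fh:
        manifest = json.load(fh)
    missing = [k for k in _REQUIRED_MANIFEST_KEYS if k not in manifest]
    if missing:
        raise ValueError(f"manifest missing required keys: {missing}")
    return manifest
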