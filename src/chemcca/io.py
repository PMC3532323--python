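"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular data travels as TSV (gene-set and descriptor names may contain
commas), gene sets as GMT, and fitted models as a single versioned JSON
archive.  Readers validate aggressively and raise :class:`InputError` with
the offending location, so a malformed file never propagates silently into
the statistics.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .genesets import GeneSetCollection
    from .retrieval import AnnotationSet

__all__ = [
    "InputError",
    "ParameterError",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gmt",
    "write_gmt",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "save_model",
    "load_model",
    "sha256_file",
]

MODEL_SCHEMA_VERSION = 1


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ParameterError(ValueError):
    """Invalid parameter value."""


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labeled numeric matrix from TSV.

    First column holds row ids, header row holds column ids.  Duplicate ids
    and non-numeric or missing cells are rejected with located errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate row id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise InputError(f"{path}: duplicate column id {dup!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise InputError(
                f"{path}: non-numeric or empty cell at row {row!r}, column {col!r}"
            )
        out[col] = converted.to_numpy(dtype=float)
    return out


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path: str | Path) -> "GeneSetCollection":
    """Read a GMT gene-set file (name, description, genes..., tab-separated)."""
    from .genesets import GeneSetCollection

    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: gene set with no genes")
            name = fields[0]
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise InputError(f"{path}:{lineno}: gene set with no genes")
            sets[name] = genes
    universe = sorted({g for genes in sets.values() for g in genes})
    return GeneSetCollection(sets={k: frozenset(v) for k, v in sets.items()}, universe=universe)


def write_gmt(collection: "GeneSetCollection", path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_annotations_tsv(path: str | Path) -> "AnnotationSet":
    """Read a compound annotation table: compound_id <TAB> label_id [<TAB> kind]."""
    from .retrieval import AnnotationSet

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"compound_id", "label_id"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: expected columns compound_id, label_id")
    if "kind" not in df.columns:
        df["kind"] = "target"
    if df[["compound_id", "label_id"]].isna().any().any():
        raise InputError(f"{path}: empty compound or label id")
    pairs = df[["compound_id", "label_id", "kind"]]
    if pairs.duplicated(["compound_id", "label_id"]).any():
        raise InputError(f"{path}: duplicate (compound, label) pair")
    return AnnotationSet(pairs=pairs.reset_index(drop=True))


def write_annotations_tsv(annotations: "AnnotationSet", path: str | Path) -> None:
    annotations.pairs.to_csv(path, sep="\t", index=False)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted CCA model to a versioned JSON archive."""
    payload = {"schema_version": MODEL_SCHEMA_VERSION, "model": _jsonify(model.to_dict())}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path: str | Path):
    from .rcca import CcaModel

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise InputError(f"{path}: unsupported model schema version {version!r}")
    return CcaModel.from_dict(payload["model"])


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
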