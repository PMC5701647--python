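"""On-disk formats: labeled TSV matrices, tables, YAML config, manifests.

All matrices are stored as tab-separated text with a header row and a
first column of region labels, preceded by ``#``-comment metadata lines
(tool version, seed, parameters) sufficient to regenerate the file.
Values are rendered with 17 significant digits so a write-read round
trip is lossless for float64.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

FLOAT_FMT = "%.17g"


def _meta_lines(meta: dict | None) -> list[str]:
    lines = [f"# hemilat {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def write_matrix(path, matrix: np.ndarray, labels: list[str], meta: dict | None = None) -> None:
    """Write a labeled square matrix as TSV with comment-header metadata."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square with one label per row")
    path = Path(path)
    with path.open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write("\t".join(["region"] + list(labels)) + "\n")
        for label, row in zip(labels, matrix):
            fh.write(label + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path, expect_labels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a labeled TSV matrix; validate squareness, symmetry and labels."""
    path = Path(path)
    rows, labels = [], []
    header: list[str] | None = None
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            labels.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if header is None:
        raise ValueError(f"{path}: no header row found")
    matrix = np.asarray(rows, dtype=float)
    n = len(header)
    if matrix.shape != (n, n):
        raise ValueError(f"{path}: matrix is not square (header {n}, shape {matrix.shape})")
    if labels != header:
        bad = next(i for i, (a, b) in enumerate(zip(labels, header)) if a != b)
        raise ValueError(f"{path}: row label {labels[bad]!r} != column label {header[bad]!r}")
    asym = np.abs(matrix - matrix.T)
    if asym.max() > 1e-8:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(f"{path}: asymmetric beyond 1e-8 at pair ({labels[i]}, {labels[j]})")
    if expect_labels is not None and labels != list(expect_labels):
        raise ValueError(f"{path}: labels do not match the node table ordering")
    return matrix, labels


def write_table(path, table: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_timeseries(path, ts: np.ndarray, labels: list[str], meta: dict | None = None) -> None:
    """Time series TSV: rows are time points, columns are regions."""
    df = pd.DataFrame(np.asarray(ts, dtype=float), columns=labels)
    write_table(path, df, meta)


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    df = read_table(path)
    return df.to_numpy(dtype=float), list(df.columns)


def load_config(path) -> dict:
    with Path(path).open() as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def verify_manifest(manifest_path) -> list[str]:
    """Recompute output checksums; return the names of tampered files."""
    manifest_path = Path(manifest_path)
    with manifest_path.open() as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    bad = []
    for name, digest in manifest.get("outputs", {}).items():
        target = base / name
        if not target.exists() or sha256_file(target) != digest:
            bad.append(name)
    return sorted(bad)


def write_manifest(path, config: dict, seed: int, outputs: list[Path]) -> dict:
    """Manifest JSON: version, seed, config hash, per-file checksums."""
    manifest = {
        "tool": "hemilat",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config,
        "outputs": {
            str(Path(p).name): sha256_file(p) for p in sorted(outputs, key=lambda p: str(p))
        },
    }
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
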