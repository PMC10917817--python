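"""Readers and writers for pipeline artifacts.

Canonical on-disk formats are plain text: square connectivity matrices
as TSV with a header row of ROI labels, metric tables as long-format
TSV, the design manifest as JSON, and the label table as two-column TSV
(index, ROI name). Matrix files follow the naming pattern
``sub-<id>_att-<melody|sentence>_deg-<spectral|temporal>_cut-<1..5>.tsv``.
Writes are atomic (temp file + rename) so interrupted runs never leave
truncated artifacts behind.
"""

from __future__ import annotations

import json
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ConnectivityMatrix

__all__ = [
    "matrix_filename",
    "write_matrix",
    "read_matrix",
    "write_dataset",
    "read_dataset",
    "write_label_table",
    "read_label_table",
    "write_metric_table",
    "read_metric_table",
]

_ASYMMETRY_TOL = 1e-8
_FILENAME_RE = re.compile(
    r"sub-(?P<participant>[^_]+)_att-(?P<attention>melody|sentence)"
    r"_deg-(?P<degradation>spectral|temporal)_cut-(?P<cutoff>[1-5])\.tsv$"
)


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def matrix_filename(matrix: ConnectivityMatrix) -> str:
    pid = matrix.participant.removeprefix("sub-")
    return (
        f"sub-{pid}_att-{matrix.attention}_deg-{matrix.degradation}"
        f"_cut-{matrix.cutoff}.tsv"
    )


def write_matrix(matrix: ConnectivityMatrix, path) -> Path:
    """Write one matrix as TSV with a header row of ROI labels."""
    path = Path(path)
    labels = matrix.labels or [f"ROI{i + 1:03d}" for i in range(matrix.n_roi)]
    header = "\t".join(labels)
    body = "\n".join(
        "\t".join(f"{v:.10g}" for v in row) for row in matrix.weights
    )
    _atomic_write(path, header + "\n" + body + "\n")
    return path


def read_matrix(path, dialect: str = "tab", nan_policy: str = "reject") -> ConnectivityMatrix:
    """Read a square connectivity matrix from delimited text.

    Condition labels are recovered from the filename when it follows the
    canonical pattern. Non-square content, NaNs (under the default
    policy) and asymmetry beyond 1e-8 are rejected; ``nan_policy="zero"``
    replaces NaNs with 0 instead.
    """
    path = Path(path)
    sep = {"tab": "\t", "comma": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, header=0)
    labels = [str(c) for c in df.columns]
    w = df.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"matrix in {path.name} is not square: {w.shape}")
    if np.isnan(w).any():
        if nan_policy == "zero":
            w = np.nan_to_num(w, nan=0.0)
        else:
            raise ValueError(f"NaN entries in {path.name}")
    if not np.allclose(w, w.T, atol=_ASYMMETRY_TOL, rtol=0.0):
        raise ValueError(f"matrix in {path.name} asymmetric beyond 1e-08")
    w = (w + w.T) / 2.0
    meta = _FILENAME_RE.search(path.name)
    kwargs = (
        {
            "participant": "sub-" + meta["participant"],
            "attention": meta["attention"],
            "degradation": meta["degradation"],
            "cutoff": int(meta["cutoff"]),
        }
        if meta
        else {"participant": path.stem, "attention": "", "degradation": "", "cutoff": 0}
    )
    return ConnectivityMatrix(weights=w, labels=labels, **kwargs)


def write_dataset(matrices: list[ConnectivityMatrix], out_dir) -> Path:
    """Write every matrix plus a JSON design manifest and the label table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in matrices:
        fname = matrix_filename(m)
        write_matrix(m, out_dir / fname)
        entries.append(
            {
                "file": fname,
                "participant": m.participant,
                "attention": m.attention,
                "degradation": m.degradation,
                "cutoff": m.cutoff,
                "n_roi": m.n_roi,
            }
        )
    manifest = {"n_matrices": len(entries), "matrices": entries}
    _atomic_write(out_dir / "manifest.json", json.dumps(manifest, indent=1))
    if matrices and matrices[0].labels:
        write_label_table(matrices[0].labels, out_dir / "labels.tsv")
    return out_dir


def read_dataset(in_dir) -> list[ConnectivityMatrix]:
    """Read every matrix listed in a dataset manifest."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {in_dir}")
    manifest = json.loads(manifest_path.read_text())
    return [read_matrix(in_dir / e["file"]) for e in manifest["matrices"]]


def write_label_table(labels, path) -> Path:
    path = Path(path)
    text = "".join(f"{i}\t{lab}\n" for i, lab in enumerate(labels))
    _atomic_write(path, text)
    return path


def read_label_table(path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["index", "label"])
    return df.sort_values("index")["label"].astype(str).tolist()


def write_metric_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    _atomic_write(path, table.to_csv(sep="\t", index=False))
    return path


def read_metric_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
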