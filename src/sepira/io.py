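"""Readers and writers for the TSV/YAML formats used across the toolkit.

All tabular formats are plain tab-separated text so that inputs and outputs
stay diff-able and language-neutral:

* expression / methylation matrix: first column = gene (probe) id, header
  row = sample ids;
* tissue map: two columns ``sample_id`` / ``tissue``;
* network: three-column edge list ``tf`` / ``target`` / ``sign`` with an
  optional leading ``#`` comment line recording build parameters;
* probe annotation: ``probe_id`` / ``gene_id`` / ``region_class``.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ActivityMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
    ProbeMethylationMatrix,
    RegulatoryNetwork,
)


def log_transform(rpkm_values, scale_divisor: float = 1.0):
    """Elementwise ``log2(x / scale_divisor + 1)``.

    A divisor of 10 compresses the unrealistically wide dynamic range of
    lowly expressed genes (RPKM < 10) in some normalized RNA-seq releases;
    a divisor of 1 is the plain log2(RPKM + 1) transform. Monotone, 0 -> 0.
    """
    if scale_divisor <= 0:
        raise ValueError("scale_divisor must be positive")
    arr = np.asarray(rpkm_values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log_transform requires non-negative input")
    out = np.log2(arr / scale_divisor + 1.0)
    if isinstance(rpkm_values, pd.DataFrame):
        return pd.DataFrame(out, index=rpkm_values.index, columns=rpkm_values.columns)
    return out


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (malformed header?)")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix entries ({exc})") from exc
    all_nan = df.index[df.isna().all(axis=1)]
    if len(all_nan):
        raise ValueError(f"{path}: rows with no values at all: {all_nan.tolist()[:5]}")
    return df


def _collapse_duplicate_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing an id (probe-collapse convention)."""
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    return df


def read_tissue_map(path) -> pd.Series:
    tmap = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#")
    if tmap.shape[1] < 2:
        raise ValueError(f"{path}: tissue map needs two columns (sample_id, tissue)")
    tmap = tmap.iloc[:, :2]
    tmap.columns = ["sample_id", "tissue"]
    return tmap.set_index("sample_id")["tissue"]


def read_expression(path, tissue_map) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus a sample->tissue map.

    Duplicate gene ids are collapsed by averaging before any analysis.
    Every sample column must appear in the tissue map.
    """
    values = _collapse_duplicate_rows(_read_matrix(path))
    tissues = read_tissue_map(tissue_map)
    return ExpressionMatrix(values, tissues)


def write_expression(expr: ExpressionMatrix, path, tissue_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    if tissue_path is not None:
        expr.tissues.rename("tissue").to_csv(path_or_buf=tissue_path, sep="\t",
                                             index_label="sample_id")


def read_dnam(path) -> ProbeMethylationMatrix:
    """Read a probes-x-samples beta-value TSV (missing cells allowed)."""
    return ProbeMethylationMatrix(_collapse_duplicate_rows(_read_matrix(path)))


def read_annotation(path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return ProbeAnnotation(table)


def write_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def write_network(net: RegulatoryNetwork, path, params: dict | None = None) -> None:
    """Write an edge-list TSV, rows sorted by (tf, target) for reproducibility."""
    with open(path, "w") as fh:
        if params:
            meta = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
            fh.write(f"# sepira network; {meta}\n")
        fh.write("tf\ttarget\tsign\n")
        for tf in net.tf_ids:
            for target in sorted(net.edges[tf]):
                fh.write(f"{tf}\t{target}\t{net.edges[tf][target]:+d}\n")


def read_network(path) -> RegulatoryNetwork:
    edges: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                if fields[0] == "tf":
                    continue  # header row
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            tf, target, sign_str = fields
            try:
                sign = int(sign_str)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer sign {sign_str!r}")
            if sign not in (-1, 1):
                raise ValueError(f"{path}:{lineno}: sign must be +1 or -1, got {sign}")
            edges.setdefault(tf, {})[target] = sign
    return RegulatoryNetwork(edges)


def write_activity(act: ActivityMatrix, path) -> None:
    act.values.to_csv(path, sep="\t", index_label="tf_id")


def read_activity(path, mode: str = "expression") -> ActivityMatrix:
    return ActivityMatrix(_read_matrix(path), mode=mode)


def load_config(path) -> dict:
    """Load a YAML config of build thresholds (keys match BuildParams fields)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
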