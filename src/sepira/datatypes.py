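"""Shared data model: expression / methylation matrices, signed regulons, activities.

All matrices are pandas DataFrames in genes-(or probes-)by-samples
orientation, mirroring how expression compendia are distributed. The
sklearn-facing estimators in :mod:`sepira.estimators` transpose to the
samples-by-features convention at their boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REGION_CLASSES = ("TSS200", "FirstExon", "TSS1500", "Other")

#: priority order used to summarize promoter methylation per gene
REGION_PRIORITY = ("TSS200", "FirstExon", "TSS1500")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, with one tissue label per sample.

    Parameters
    ----------
    values : DataFrame
        Genes as rows (unique stable gene IDs), samples as columns.
        Expression matrices must be complete (no NaN).
    tissues : Series
        Tissue label for every sample in ``values``; indexed by sample id.
    """

    values: pd.DataFrame
    tissues: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if np.isnan(self.values.to_numpy(dtype=float)).any():
            raise ValueError("expression matrix contains NaN; matrices must be complete")
        missing = self.values.columns.difference(self.tissues.index)
        if len(missing):
            raise ValueError(
                f"samples missing from tissue map: {missing.tolist()[:5]}"
            )
        # keep tissues aligned to the sample columns, drop extraneous entries
        self.tissues = self.tissues.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_tissues(self) -> int:
        """Number of distinct tissue labels (the effective sample size nT)."""
        return int(self.tissues.nunique())

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.tissues)

    def samples_in_tissue(self, tissue_or_tissues) -> list[str]:
        if isinstance(tissue_or_tissues, str):
            wanted = {tissue_or_tissues}
        else:
            wanted = set(tissue_or_tissues)
        mask = self.tissues.isin(wanted)
        return self.tissues.index[mask].tolist()


@dataclass
class RegulatoryNetwork:
    """Signed bipartite TF -> target map (+1 activation, -1 repression)."""

    edges: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for tf, targets in self.edges.items():
            if tf in targets:
                raise ValueError(f"TF {tf!r} appears among its own targets")
            bad = {g: s for g, s in targets.items() if s not in (-1, 1)}
            if bad:
                raise ValueError(f"edge signs must be +1/-1, got {bad}")

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.edges)

    def targets(self, tf: str) -> dict[str, int]:
        return dict(self.edges[tf])

    def all_targets(self) -> list[str]:
        out: set[str] = set()
        for targets in self.edges.values():
            out.update(targets)
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.edges.values())

    def sign_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) edge counts."""
        pos = sum(1 for t in self.edges.values() for s in t.values() if s == 1)
        return pos, self.n_edges - pos

    def binding_matrix(self, genes: Iterable[str]) -> pd.DataFrame:
        """TFs x genes matrix of {-1, 0, +1} binding profiles."""
        genes = list(genes)
        mat = pd.DataFrame(0, index=self.tf_ids, columns=genes, dtype=float)
        gene_set = set(genes)
        for tf in self.tf_ids:
            for g, s in self.edges[tf].items():
                if g in gene_set:
                    mat.at[tf, g] = s
        return mat

    def negated(self) -> "RegulatoryNetwork":
        """Network with every edge sign flipped (used in DNAm mode)."""
        return RegulatoryNetwork(
            {tf: {g: -s for g, s in t.items()} for tf, t in self.edges.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tf, g, self.edges[tf][g])
            for tf in self.tf_ids
            for g in sorted(self.edges[tf])
        ]
        return pd.DataFrame(rows, columns=["tf", "target", "sign"])


@dataclass
class ProbeMethylationMatrix:
    """Beta-values (methylation fractions), probes x samples, in [0, 1].

    Sporadic missing beta-values (NaN) are allowed and handled pairwise
    downstream; values outside [-0.01, 1.01] are rejected.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < -0.01 or finite.max() > 1.01):
            raise ValueError(
                "beta-values outside [-0.01, 1.01]; input does not look like "
                "methylation fractions"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class ProbeAnnotation:
    """Probe -> (gene, region class) map; one row per probe-gene mapping."""

    table: pd.DataFrame  # columns: probe_id, gene_id, region_class

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "region_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        bad = set(self.table["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(
                f"unknown region classes {sorted(bad)}; expected one of {REGION_CLASSES}"
            )


@dataclass
class ActivityMatrix:
    """TF x sample matrix of per-sample activity scores (slope t-statistics)."""

    values: pd.DataFrame
    mode: str = "expression"

    def __post_init__(self) -> None:
        if self.mode not in ("expression", "dnam"):
            raise ValueError(f"mode must be 'expression' or 'dnam', got {self.mode!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("activity matrix must be finite")

    @property
    def tf_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()
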