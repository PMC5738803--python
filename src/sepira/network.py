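"""Stages for reverse-engineering a tissue-specific signed TF-target network.

The pipeline (orchestrated by :class:`sepira.estimators.RegulonInference`):

1. variance filter — drop genes with sample SD below a floor;
2. TF x gene Pearson correlation with a Fisher-z null whose standard
   deviation is 1/sqrt(nT - 3), nT = number of distinct *tissues* (the
   effective sample size, counteracting within-tissue correlation), at a
   Bonferroni family-wise threshold;
3. minimum-target filter;
4. partial-correlation pruning of genes claimed by several TFs (precision
   matrix of the gene-plus-candidate-TFs correlation matrix);
5. minimum-target filter again;
6. tissue-specificity selection of TFs by two moderated-t contrasts —
   target tissue vs everything else, and target tissue vs designated
   "guard" tissues (e.g. blood/spleen) to reject immune-cell markers
   carried along by immune-cell infiltration of the target tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, RegulatoryNetwork
from .moderated import moderated_ttest

__all__ = [
    "BuildParams",
    "bonferroni_threshold",
    "CorrelationTestResult",
    "EmptyNetworkError",
    "build_network",
    "correlation_significance",
    "filter_by_variance",
    "filter_min_targets",
    "moderated_ttest",
    "network_from_adjacency",
    "prune_by_partial_correlation",
    "select_tissue_specific_tfs",
]


@dataclass
class BuildParams:
    """Thresholds of the network build.

    Defaults follow the construction recipe: SD floor 0.25 on log2
    expression, family-wise alpha 0.05 with Bonferroni correction over all
    TF-gene pairs, |partial correlation| >= 0.2 to keep an edge, at least
    10 targets per TF, and the two tissue-specificity contrasts at raw
    p < 0.05 with log2 fold-change > 1 (vs all tissues) and > 1.5 (vs the
    guard tissues).
    """

    target_tissue: str = ""
    guard_tissues: tuple = ("blood", "spleen")
    sd_min: float = 0.25
    alpha_fwer: float = 0.05
    pcor_min: float = 0.2
    min_targets: int = 10
    de_p: float = 0.05
    lfc_all: float = 1.0
    lfc_guard: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha_fwer < 1):
            raise ValueError("alpha_fwer must lie in (0, 1)")
        if not (0 < self.pcor_min < 1):
            raise ValueError("pcor_min must lie in (0, 1)")
        if self.min_targets < 2:
            raise ValueError("min_targets must be >= 2")
        for name in ("sd_min", "de_p", "lfc_all", "lfc_guard"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        self.guard_tissues = tuple(self.guard_tissues or ())


@dataclass
class CorrelationTestResult:
    """TF x gene correlation screen with its Fisher-z significance call."""

    pcc: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    signed_adjacency: pd.DataFrame
    per_test_alpha: float
    n_tissues: int


class EmptyNetworkError(ValueError):
    """Raised when no TF survives the build; carries the stage-count report."""

    def __init__(self, message: str, report: dict):
        super().__init__(f"{message}; stage counts: {report}")
        self.report = report


def filter_by_variance(expr: ExpressionMatrix, sd_min: float = 0.25) -> ExpressionMatrix:
    """Keep genes whose sample standard deviation (ddof=1) is >= sd_min."""
    if expr.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate variances")
    sd = expr.values.std(axis=1, ddof=1)
    keep = sd >= sd_min
    if not keep.any():
        warnings.warn("variance filter removed every gene", stacklevel=2)
    return ExpressionMatrix(expr.values.loc[keep], expr.tissues)


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    """Row z-scores (ddof=1); zero-variance rows become all-zero."""
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(mat, dtype=float)
    ok = sd[:, 0] > 0
    out[ok] = (mat[ok] - mu[ok]) / sd[ok]
    return out


def bonferroni_threshold(n_tf: int, n_gene: int, alpha_fwer: float = 0.05) -> float:
    """Per-test significance level controlling the family-wise error over
    all TF x gene correlation tests."""
    if n_tf < 1 or n_gene < 1:
        raise ValueError("need at least one TF and one gene")
    return alpha_fwer / (n_tf * n_gene)


def correlation_significance(
    expr: ExpressionMatrix, tf_ids, alpha_fwer: float = 0.05
) -> CorrelationTestResult:
    """Pearson correlation of every TF against every non-TF gene, with
    significance from the Fisher z-transform under an effective-sample-size
    null.

    z = atanh(pcc) is compared against Normal(0, 1/sqrt(nT - 3)) where nT is
    the number of distinct tissues — not the sample count — and called
    significant below the Bonferroni per-test level
    alpha_fwer / (n_tf * n_gene). Zero-variance profiles get pcc = 0 (no
    edge).
    """
    tf_ids = list(tf_ids)
    missing = set(tf_ids) - set(expr.values.index)
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {sorted(missing)[:5]}")
    nT = expr.n_tissues
    if nT < 5:
        raise ValueError(f"need at least 5 distinct tissues, got {nT}")
    genes = [g for g in expr.values.index if g not in set(tf_ids)]
    if not genes:
        raise ValueError("no non-TF genes left to test")
    X = expr.values.loc[tf_ids].to_numpy(dtype=float)
    Y = expr.values.loc[genes].to_numpy(dtype=float)
    n_samples = X.shape[1]
    Zx = _standardize_rows(X)
    Zy = _standardize_rows(Y)
    pcc = (Zx @ Zy.T) / (n_samples - 1)
    np.clip(pcc, -1.0, 1.0, out=pcc)
    with np.errstate(divide="ignore"):
        z = np.arctanh(pcc)
    null_sd = 1.0 / np.sqrt(nT - 3)
    p = 2.0 * sps.norm.sf(np.abs(z) / null_sd)
    per_test_alpha = bonferroni_threshold(len(tf_ids), len(genes), alpha_fwer)
    adjacency = np.where(p < per_test_alpha, np.sign(pcc), 0.0).astype(int)
    wrap = lambda m: pd.DataFrame(m, index=tf_ids, columns=genes)
    return CorrelationTestResult(
        pcc=wrap(pcc),
        z=wrap(z),
        p=wrap(p),
        signed_adjacency=wrap(adjacency),
        per_test_alpha=per_test_alpha,
        n_tissues=nT,
    )


def _partial_correlations(corr: np.ndarray, n_samples: int) -> np.ndarray:
    """Partial correlations of variable 0 with variables 1..k given the rest,
    from the precision matrix; pseudo-inverse fallback when singular or
    under-determined."""
    k1 = corr.shape[0]
    use_pinv = k1 > n_samples
    if not use_pinv:
        try:
            omega = np.linalg.inv(corr)
        except np.linalg.LinAlgError:
            use_pinv = True
    if use_pinv:
        warnings.warn(
            "singular or under-determined correlation sub-matrix; "
            "using Moore-Penrose pseudo-inverse",
            stacklevel=3,
        )
        omega = np.linalg.pinv(corr)
    d = np.diag(omega)
    return -omega[0, 1:] / np.sqrt(d[0] * d[1:])


def prune_by_partial_correlation(
    adj: pd.DataFrame, expr: ExpressionMatrix, pcor_min: float = 0.2
) -> pd.DataFrame:
    """Zero out edges whose partial correlation falls below the floor.

    For every gene with at least two candidate TFs, the partial correlation
    between the gene and each candidate, conditioning on the remaining
    candidates, is computed from the inverse of the empirical correlation
    matrix of [gene, TF_1..TF_k]; edges with |pcor| < pcor_min are removed.
    Genes with a single candidate TF are untouched.
    """
    adj = adj.copy()
    n_samples = expr.values.shape[1]
    n_candidates = (adj != 0).sum(axis=0)
    for gene in adj.columns[n_candidates >= 2]:
        tf_mask = adj[gene] != 0
        tfs = adj.index[tf_mask].tolist()
        block = expr.values.loc[[gene] + tfs].to_numpy(dtype=float)
        corr = np.corrcoef(block)
        pcor = _partial_correlations(corr, n_samples)
        drop = np.abs(pcor) < pcor_min
        if drop.any():
            adj.loc[np.asarray(tfs)[drop], gene] = 0
    return adj


def network_from_adjacency(adj: pd.DataFrame) -> RegulatoryNetwork:
    edges: dict[str, dict[str, int]] = {}
    for tf in adj.index:
        row = adj.loc[tf]
        nz = row[row != 0]
        if len(nz):
            edges[str(tf)] = {str(g): int(s) for g, s in nz.items()}
    return RegulatoryNetwork(edges)


def filter_min_targets(net, min_targets: int = 10):
    """Drop TFs with fewer than ``min_targets`` targets (inclusive boundary).

    Accepts either a :class:`RegulatoryNetwork` or a signed adjacency
    DataFrame (TFs x genes) and returns the same type.
    """
    if isinstance(net, RegulatoryNetwork):
        kept = {tf: dict(t) for tf, t in net.edges.items() if len(t) >= min_targets}
        return RegulatoryNetwork(kept)
    keep = (net != 0).sum(axis=1) >= min_targets
    return net.loc[keep]


def select_tissue_specific_tfs(
    expr: ExpressionMatrix, tf_ids, params: BuildParams
) -> list[str]:
    """TFs over-expressed in the target tissue by both moderated-t contrasts.

    Contrast (1): target tissue vs all other samples, requiring raw
    p < de_p and log2FC > lfc_all. Contrast (2): target tissue vs the union
    of guard-tissue samples only, requiring p < de_p and log2FC > lfc_guard;
    this rejects immune-cell markers that ride along on immune infiltration
    of the target tissue. P-values are used unadjusted, by design.
    """
    tf_ids = [t for t in tf_ids if t in expr.values.index]
    if not tf_ids:
        return []
    tissues = expr.tissues
    if params.target_tissue not in set(tissues):
        raise ValueError(f"target tissue {params.target_tissue!r} not in tissue labels")
    guards = set(params.guard_tissues)
    target_samples = expr.samples_in_tissue(params.target_tissue)
    other_samples = [s for s in expr.sample_ids if s not in set(target_samples)]
    sub = expr.values.loc[tf_ids]
    res_all = moderated_ttest(sub, target_samples, other_samples)
    selected = (res_all["p_value"] < params.de_p) & (res_all["log2_fc"] > params.lfc_all)
    if guards:
        missing = guards - set(tissues)
        if missing:
            raise ValueError(
                f"guard tissue(s) {sorted(missing)} absent from the data; pass "
                "guard_tissues=() to disable the guard contrast explicitly"
            )
        guard_samples = expr.samples_in_tissue(guards)
        res_guard = moderated_ttest(sub, target_samples, guard_samples)
        selected &= (res_guard["p_value"] < params.de_p) & (
            res_guard["log2_fc"] > params.lfc_guard
        )
    return sorted(res_all.index[selected])


def build_network(
    expr: ExpressionMatrix, tf_ids, params: BuildParams
) -> tuple[RegulatoryNetwork, dict]:
    """Run the full build pipeline; returns (network, stage-count report).

    Thin wrapper over :class:`sepira.estimators.RegulonInference`.
    """
    from .estimators import RegulonInference

    est = RegulonInference(tf_ids=list(tf_ids), **asdict(params))
    est.fit(expr.values.T, expr.tissues)
    return est.network_, est.report_
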