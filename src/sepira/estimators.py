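"""Scikit-learn style estimators wrapping the network build and activity scoring.

`RegulonInference` is fit on a multi-tissue expression compendium
(samples x genes, with tissue labels as ``y``) and exposes the inferred
signed network as ``network_``. `TFActivityScorer` is a transformer mapping
samples x genes (expression or gene-level promoter methylation) to
samples x TFs activity t-statistics; it learns per-gene normalization
statistics at fit time, so activities are relative to the fitted cohort.
Both compose with sklearn pipelines and ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ExpressionMatrix, RegulatoryNetwork
from .network import (
    BuildParams,
    EmptyNetworkError,
    correlation_significance,
    filter_by_variance,
    filter_min_targets,
    network_from_adjacency,
    prune_by_partial_correlation,
    select_tissue_specific_tfs,
)

__all__ = ["RegulonInference", "TFActivityScorer"]


def _as_dataframe(X, what: str) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            f"{what} must be a pandas DataFrame (samples x genes) so gene "
            "identifiers are available"
        )
    return X


class RegulonInference(BaseEstimator):
    """Reverse-engineer a tissue-specific signed TF-target network.

    Parameters mirror the build thresholds (see
    :class:`sepira.network.BuildParams`). ``fit`` expects ``X`` as a
    samples x genes DataFrame of log2 expression and ``y`` as one tissue
    label per sample.

    Attributes
    ----------
    network_ : RegulatoryNetwork
        The inferred signed TF -> target map.
    report_ : dict
        TF/gene counts after every pipeline stage.
    tf_ids_ : list of str
        TFs retained in the final network.
    """

    def __init__(
        self,
        tf_ids=None,
        target_tissue: str = "",
        guard_tissues=("blood", "spleen"),
        sd_min: float = 0.25,
        alpha_fwer: float = 0.05,
        pcor_min: float = 0.2,
        min_targets: int = 10,
        de_p: float = 0.05,
        lfc_all: float = 1.0,
        lfc_guard: float = 1.5,
    ):
        self.tf_ids = tf_ids
        self.target_tissue = target_tissue
        self.guard_tissues = guard_tissues
        self.sd_min = sd_min
        self.alpha_fwer = alpha_fwer
        self.pcor_min = pcor_min
        self.min_targets = min_targets
        self.de_p = de_p
        self.lfc_all = lfc_all
        self.lfc_guard = lfc_guard

    def fit(self, X, y):
        X = _as_dataframe(X, "X")
        if self.tf_ids is None:
            raise ValueError("tf_ids must be provided")
        if not self.target_tissue:
            raise ValueError("target_tissue must be provided")
        params = BuildParams(
            target_tissue=self.target_tissue,
            guard_tissues=tuple(self.guard_tissues or ()),
            sd_min=self.sd_min,
            alpha_fwer=self.alpha_fwer,
            pcor_min=self.pcor_min,
            min_targets=self.min_targets,
            de_p=self.de_p,
            lfc_all=self.lfc_all,
            lfc_guard=self.lfc_guard,
        )
        tissues = pd.Series(np.asarray(y, dtype=object), index=X.index)
        expr = ExpressionMatrix(X.T, tissues)

        report: dict[str, int] = {"n_genes_input": expr.values.shape[0]}
        expr_f = filter_by_variance(expr, params.sd_min)
        report["n_genes_after_variance_filter"] = expr_f.values.shape[0]

        tfs_present = sorted(set(self.tf_ids) & set(expr_f.values.index))
        report["n_tfs_tested"] = len(tfs_present)
        report["n_candidate_genes"] = report["n_genes_after_variance_filter"] - len(
            tfs_present
        )
        if not tfs_present:
            raise EmptyNetworkError("no TF passes the variance filter", report)

        cres = correlation_significance(expr_f, tfs_present, params.alpha_fwer)
        report["per_test_alpha"] = cres.per_test_alpha
        report["n_tissues"] = cres.n_tissues

        adj = filter_min_targets(cres.signed_adjacency, params.min_targets)
        report["n_tfs_after_first_min_target_filter"] = adj.shape[0]
        if adj.shape[0] == 0:
            raise EmptyNetworkError("no TF reaches min_targets", report)

        adj = prune_by_partial_correlation(adj, expr_f, params.pcor_min)
        adj = filter_min_targets(adj, params.min_targets)
        report["n_tfs_after_pruning"] = adj.shape[0]
        if adj.shape[0] == 0:
            raise EmptyNetworkError("no TF reaches min_targets after pruning", report)

        selected = select_tissue_specific_tfs(expr_f, adj.index.tolist(), params)
        report["n_tfs_tissue_specific"] = len(selected)
        if not selected:
            raise EmptyNetworkError("no TF passes the tissue-specificity contrasts", report)

        net = network_from_adjacency(adj.loc[selected])
        net = filter_min_targets(net, params.min_targets)
        if not net.tf_ids:
            raise EmptyNetworkError("final network is empty", report)
        pos, neg = net.sign_counts()
        report["n_tfs_final"] = len(net.tf_ids)
        report["n_targets_final"] = len(net.all_targets())
        report["n_edges_final"] = net.n_edges
        report["n_edges_positive"] = pos
        report["n_edges_negative"] = neg

        self.network_ = net
        self.report_ = report
        self.tf_ids_ = net.tf_ids
        return self


class TFActivityScorer(TransformerMixin, BaseEstimator):
    """Transform samples x genes profiles into samples x TFs activity scores.

    Parameters
    ----------
    network : RegulatoryNetwork
        Signed regulons. In ``mode="dnam"`` the edge signs are reversed
        internally (hypomethylation of activating targets marks activity).
    mode : {"expression", "dnam"}
    min_overlap : int
        Minimum number of a TF's targets that must be measured; TFs below
        this are dropped with a warning.
    center_only : bool
        Center gene profiles without scaling (DNAm option).
    assume_standardized : bool
        Skip normalization entirely; input profiles are already z-scored.

    Attributes
    ----------
    genes_ : list of network genes used in the regressions.
    mean_, scale_ : per-gene normalization learned at fit.
    tfs_ : TFs with enough measured targets.
    """

    def __init__(
        self,
        network: RegulatoryNetwork | None = None,
        mode: str = "expression",
        min_overlap: int = 10,
        center_only: bool = False,
        assume_standardized: bool = False,
    ):
        self.network = network
        self.mode = mode
        self.min_overlap = min_overlap
        self.center_only = center_only
        self.assume_standardized = assume_standardized

    def _effective_network(self) -> RegulatoryNetwork:
        if self.network is None:
            raise ValueError("network must be provided")
        if self.mode == "dnam":
            return self.network.negated()
        if self.mode != "expression":
            raise ValueError(f"mode must be 'expression' or 'dnam', got {self.mode!r}")
        return self.network

    def fit(self, X, y=None):
        import warnings

        X = _as_dataframe(X, "X")
        net = self._effective_network()
        network_genes = net.all_targets()
        present = [g for g in network_genes if g in set(X.columns)]
        if len(present) < len(network_genes):
            warnings.warn(
                f"{len(network_genes) - len(present)} network genes not measured",
                stacklevel=2,
            )
        if len(present) < 3:
            raise ValueError("fewer than 3 network genes measured; cannot regress")
        sub = X[present].to_numpy(dtype=float)
        mean = np.nanmean(sub, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scale = np.nanstd(sub, axis=0, ddof=1)
        scale = np.where(np.isfinite(scale) & (scale > 0), scale, 1.0)
        self.genes_ = present
        self.mean_ = mean
        self.scale_ = np.ones_like(scale) if self.center_only else scale
        binding = net.binding_matrix(present)
        measured = (~np.all(np.isnan(sub), axis=0))
        kept = []
        for tf in binding.index:
            n_own = int(((binding.loc[tf].to_numpy() != 0) & measured).sum())
            if n_own >= self.min_overlap:
                kept.append(tf)
            else:
                warnings.warn(
                    f"TF {tf} dropped: only {n_own} of its targets measured "
                    f"(min_overlap={self.min_overlap})",
                    stacklevel=2,
                )
        if not kept:
            raise ValueError("no TF has enough measured targets")
        self.tfs_ = kept
        self._binding = binding.loc[kept].to_numpy()
        return self

    def transform(self, X) -> pd.DataFrame:
        from .activity import slope_tstats

        if not hasattr(self, "genes_"):
            raise ValueError("TFActivityScorer is not fitted yet")
        X = _as_dataframe(X, "X")
        missing = set(self.genes_) - set(X.columns)
        if missing:
            raise ValueError(f"fitted genes missing from X: {sorted(missing)[:5]}")
        sub = X[self.genes_].to_numpy(dtype=float)
        if self.assume_standardized:
            z = sub
        else:
            z = (sub - self.mean_) / self.scale_
        t = slope_tstats(self._binding, z.T)
        return pd.DataFrame(t.T, index=X.index, columns=self.tfs_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.tfs_, dtype=object)
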