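"""Per-sample TF activity from z-normalized profiles vs signed binding profiles.

For one TF and one sample, activity is the t-statistic of the slope in an
ordinary least-squares regression (with intercept) of the sample's
z-normalized profile over all network genes (response) on the TF's binding
profile of +1 / -1 / 0 entries (single covariate). With an intercept, the
slope t equals r * sqrt((G - 2) / (1 - r^2)) where r is the Pearson
correlation between profile and binding vector over the G network genes —
the form used here, vectorized over TFs and samples. Estimation is
deliberately univariate per TF: multiple regulation is already accounted
for during network construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ActivityMatrix, ExpressionMatrix, RegulatoryNetwork
from .moderated import moderated_ttest

__all__ = [
    "differential_tf_expression_baseline",
    "infer_activity",
    "slope_tstats",
    "zscore_genes",
]


def zscore_genes(expr: ExpressionMatrix, gene_subset) -> ExpressionMatrix:
    """Z-score each gene's profile across samples (ddof=1), after subsetting.

    Genes in ``gene_subset`` missing from the matrix are dropped with a
    warning; zero-variance genes become all-zero rows (neutral in the
    downstream regressions) with a warning.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    wanted = list(gene_subset)
    present = [g for g in wanted if g in set(expr.values.index)]
    if len(present) < len(wanted):
        warnings.warn(
            f"{len(wanted) - len(present)} requested genes absent from the matrix",
            stacklevel=2,
        )
    sub = expr.values.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance genes set to all-zero", stacklevel=2)
    z = np.zeros_like(sub)
    ok = ~flat
    z[ok] = (sub[ok] - mu[ok]) / sd[ok]
    return ExpressionMatrix(
        pd.DataFrame(z, index=present, columns=expr.values.columns), expr.tissues
    )


def slope_tstats(binding: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Slope t-statistics of OLS-with-intercept regressions, vectorized.

    binding: (T, G) covariate rows; response: (G, S) response columns (may
    contain NaN — handled pairwise per sample). Returns a (T, S) array.
    Degenerate regressions (constant covariate or response over the
    available genes) yield 0.
    """
    binding = np.asarray(binding, dtype=float)
    response = np.asarray(response, dtype=float)
    if np.isnan(response).any():
        cols = []
        for j in range(response.shape[1]):
            mask = ~np.isnan(response[:, j])
            if mask.sum() >= 3:
                col = _slope_tstats_complete(binding[:, mask], response[mask, j][:, None])[:, 0]
            else:
                col = np.zeros(binding.shape[0])
            cols.append(col)
        return np.column_stack(cols)
    return _slope_tstats_complete(binding, response)


def _slope_tstats_complete(binding: np.ndarray, response: np.ndarray) -> np.ndarray:
    G = binding.shape[1]
    if G < 3:
        return np.zeros((binding.shape[0], response.shape[1]))
    bc = binding - binding.mean(axis=1, keepdims=True)
    yc = response - response.mean(axis=0, keepdims=True)
    sb = np.sqrt((bc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=0))
    denom = np.outer(sb, sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (bc @ yc) / np.where(denom > 0, denom, 1.0), 0.0)
    r2 = np.minimum(r * r, 1.0 - 1e-12)
    return r * np.sqrt((G - 2) / (1.0 - r2))


def infer_activity(
    expr_z: ExpressionMatrix, net: RegulatoryNetwork, min_overlap: int = 10
) -> ActivityMatrix:
    """TF x sample activity t-statistics from an already z-scored matrix.

    Thin wrapper over :class:`sepira.estimators.TFActivityScorer` with
    standardization disabled (profiles are assumed z-scored, as produced by
    :func:`zscore_genes`).
    """
    from .estimators import TFActivityScorer

    scorer = TFActivityScorer(
        network=net, mode="expression", min_overlap=min_overlap, assume_standardized=True
    )
    act = scorer.fit_transform(expr_z.values.T)
    return ActivityMatrix(act.T, mode="expression")


def differential_tf_expression_baseline(
    expr: ExpressionMatrix, tf_ids, group1, group2
) -> pd.DataFrame:
    """Moderated t-test on each TF's *own* expression (the naive surrogate).

    Provided to reproduce the comparison between regulon-based activity and
    plain differential expression of the TF transcript: a TF whose targets
    respond while its own mRNA stays flat is invisible to this baseline.
    """
    present = [t for t in tf_ids if t in set(expr.values.index)]
    if len(present) < len(list(tf_ids)):
        warnings.warn(
            f"{len(list(tf_ids)) - len(present)} TFs absent from the matrix",
            stacklevel=2,
        )
    if not present:
        raise ValueError("none of the requested TFs are in the matrix")
    return moderated_ttest(expr.values.loc[present], group1, group2)
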