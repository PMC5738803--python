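"""Differential-activity testing, randomization nulls, and target-set enrichment."""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import ActivityMatrix, RegulatoryNetwork

__all__ = [
    "bh_adjust",
    "differential_activity",
    "empirical_null_pvalue",
    "enrichment_montecarlo",
    "enrichment_test",
    "randomize_targets",
    "stage_trend",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_frame(act) -> pd.DataFrame:
    if isinstance(act, ActivityMatrix):
        return act.values
    return act


def differential_activity(
    act,
    group1,
    group2,
    method: str = "t",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-TF group contrast of activity scores.

    method "t": two-sample pooled-variance t-statistic with two-sided p.
    method "wilcoxon": rank-sum (Mann-Whitney) statistic with a one-tailed
    p in the requested direction (``alternative`` = "greater" tests
    group1 > group2). No multiplicity adjustment is applied to ``p_value``;
    BH values are provided alongside in ``adjusted_p``.
    """
    values = _as_frame(act)
    g1, g2 = list(group1), list(group2)
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    x1 = values[g1].to_numpy(dtype=float)
    x2 = values[g2].to_numpy(dtype=float)
    if method == "t":
        res = sps.ttest_ind(x1, x2, axis=1, equal_var=True)
        stat, p = res.statistic, res.pvalue
        stat = np.where(np.isfinite(stat), stat, 0.0)
        p = np.where(np.isfinite(p), p, 1.0)
    elif method == "wilcoxon":
        stat = np.empty(values.shape[0])
        p = np.empty(values.shape[0])
        for i in range(values.shape[0]):
            r = sps.mannwhitneyu(x1[i], x2[i], alternative=alternative)
            stat[i], p[i] = r.statistic, r.pvalue
    else:
        raise ValueError(f"unknown method {method!r} (use 't' or 'wilcoxon')")
    out = pd.DataFrame(
        {"statistic": stat, "p_value": p, "adjusted_p": bh_adjust(p)},
        index=values.index,
    )
    out.index.name = "feature_id"
    return out


def randomize_targets(
    net: RegulatoryNetwork,
    gene_universe: Iterable[str],
    n_iter: int,
    seed: int,
    preserve_signs: bool = True,
) -> Iterator[RegulatoryNetwork]:
    """Yield networks with each TF's targets re-drawn uniformly from a universe.

    Per-TF target counts are always preserved. With ``preserve_signs`` the
    per-TF multiset of edge signs is kept as well (the stricter null); with
    ``preserve_signs=False`` signs are resampled with replacement from the
    TF's original signs. Deterministic under ``seed``.
    """
    universe = sorted(set(gene_universe))
    tf_overlap = set(universe) & set(net.tf_ids)
    if tf_overlap:
        raise ValueError(
            f"gene universe must exclude the network TFs: {sorted(tf_overlap)[:5]}"
        )
    max_targets = max((len(t) for t in net.edges.values()), default=0)
    if len(universe) < max_targets:
        raise ValueError(
            f"universe of {len(universe)} genes is smaller than the largest "
            f"regulon ({max_targets} targets)"
        )
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe, dtype=object)
    for _ in range(n_iter):
        edges: dict[str, dict[str, int]] = {}
        for tf in net.tf_ids:
            original = net.edges[tf]
            k = len(original)
            new_targets = rng.choice(universe_arr, size=k, replace=False)
            signs = np.asarray([original[g] for g in sorted(original)])
            if not preserve_signs:
                signs = rng.choice(signs, size=k, replace=True)
            edges[tf] = {g: int(s) for g, s in zip(new_targets, signs)}
        yield RegulatoryNetwork(edges)


def empirical_null_pvalue(observed_stat: float, null_stats, tail: str = "lower") -> float:
    """Add-one empirical p-value against a permutation/randomization null.

    tail "lower": P(null <= observed); tail "upper": P(null >= observed).
    The add-one convention keeps p strictly positive (an observation below
    all of 1000 nulls gives p = 1/1001 < 0.001).
    """
    null = np.asarray(list(null_stats), dtype=float)
    if null.size == 0:
        raise ValueError("need at least one null statistic")
    if tail == "lower":
        extreme = int((null <= observed_stat).sum())
    elif tail == "upper":
        extreme = int((null >= observed_stat).sum())
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + extreme) / (1 + null.size)


def enrichment_test(net_targets, reference_targets, universe) -> tuple[float, float]:
    """One-tailed Fisher exact test for overlap of two gene sets in a universe.

    Returns (odds_ratio, p) for the 'greater' (enrichment) alternative; the
    p-value equals the hypergeometric upper-tail sum of the 2x2 table.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    net_set = set(net_targets)
    ref_set = set(reference_targets)
    if not net_set <= uni or not ref_set <= uni:
        raise ValueError("target sets must be subsets of the universe")
    a = len(net_set & ref_set)
    b = len(net_set - ref_set)
    c = len(ref_set - net_set)
    d = len(uni) - a - b - c
    odds_ratio, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds_ratio), float(p)


def enrichment_montecarlo(
    net: RegulatoryNetwork,
    reference_targets,
    universe,
    n_iter: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo verification of per-TF enrichment p-values.

    For each TF, draws ``n_iter`` random target sets of the same size from
    the universe and reports the add-one empirical p of observing at least
    the actual overlap with the reference set.
    """
    uni = sorted(set(universe))
    if not uni:
        raise ValueError("empty gene universe")
    ref_set = set(reference_targets)
    if not ref_set <= set(uni):
        raise ValueError("reference targets must be a subset of the universe")
    rng = np.random.default_rng(seed)
    uni_arr = np.asarray(uni, dtype=object)
    ref_mask = np.asarray([g in ref_set for g in uni])
    rows = []
    for tf in net.tf_ids:
        targets = set(net.edges[tf]) & set(uni)
        k = len(targets)
        if k == 0:
            rows.append((tf, 0, 0, 1.0))
            continue
        observed = len(targets & ref_set)
        null_overlaps = np.empty(n_iter, dtype=int)
        for i in range(n_iter):
            idx = rng.choice(len(uni_arr), size=k, replace=False)
            null_overlaps[i] = int(ref_mask[idx].sum())
        p = (1 + int((null_overlaps >= observed).sum())) / (1 + n_iter)
        rows.append((tf, k, observed, p))
    out = pd.DataFrame(rows, columns=["tf", "n_targets", "overlap", "empirical_p"])
    return out.set_index("tf")


def stage_trend(
    act,
    stages: pd.Series,
    replicate_groups: pd.Series | None = None,
    collapse: str = "off",
) -> pd.DataFrame:
    """Per-TF OLS of activity on an ordinal stage covariate.

    ``stages`` maps sample id -> numeric stage. With ``collapse='mean'`` and
    ``replicate_groups`` given (sample id -> subject id), replicate samples
    of the same subject and stage are averaged before the regression.
    """
    values = _as_frame(act)
    stages = stages.loc[values.columns].astype(float)
    if collapse not in ("off", "mean"):
        raise ValueError("collapse must be 'off' or 'mean'")
    if collapse == "mean":
        if replicate_groups is None:
            raise ValueError("collapse='mean' requires replicate_groups")
        groups = replicate_groups.loc[values.columns]
        key = pd.MultiIndex.from_arrays([groups.values, stages.values])
        values = values.T.groupby(key).mean().T
        stages = pd.Series([k[1] for k in values.columns], index=values.columns)
    x = stages.to_numpy()
    rows = []
    if len(x) < 3:
        # a 2-point regression has no residual df; report the slope only
        for tf, y in values.iterrows():
            res = sps.linregress(x, y.to_numpy(dtype=float))
            rows.append((tf, res.slope, 0.0, 1.0))
    else:
        for tf, y in values.iterrows():
            res = sps.linregress(x, y.to_numpy(dtype=float))
            t = res.slope / res.stderr if res.stderr > 0 else 0.0
            p = res.pvalue if np.isfinite(res.pvalue) else 1.0
            rows.append((tf, res.slope, t, p))
    out = pd.DataFrame(rows, columns=["feature_id", "slope", "statistic", "p_value"])
    out = out.set_index("feature_id")
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out
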