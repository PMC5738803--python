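import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sepira import (
    BuildParams,
    EmptyNetworkError,
    ExpressionMatrix,
    bonferroni_threshold,
    build_network,
    correlation_significance,
    filter_by_variance,
    filter_min_targets,
    prune_by_partial_correlation,
    select_tissue_specific_tfs,
    simulate_expression,
    SimConfig,
)
from sepira.datatypes import RegulatoryNetwork
from sepira.network import _partial_correlations


def _expr_from_rows(rows: dict, n_tissues: int) -> ExpressionMatrix:
    values = pd.DataFrame(
        np.asarray(list(rows.values()), dtype=float),
        index=list(rows),
        columns=[f"s{i}" for i in range(len(next(iter(rows.values()))))],
    )
    n = values.shape[1]
    tissues = pd.Series(
        [f"t{i % n_tissues}" for i in range(n)], index=values.columns
    )
    return ExpressionMatrix(values, tissues)


class TestVarianceFilter:
    def test_exact_sd_fixture(self):
        """Genes with sample sds {0.1, 0.2, 0.25, 0.5, 1.0}: exactly the
        three at or above 0.25 survive (inclusive boundary)."""
        base = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        base = (base - base.mean()) / base.std(ddof=1)  # unit sample sd
        rows = {
            f"g{sd}": 5 + sd * base for sd in (0.1, 0.2, 0.25, 0.5, 1.0)
        }
        expr = _expr_from_rows(rows, 3)
        kept = filter_by_variance(expr, 0.25)
        assert kept.gene_ids == ["g0.25", "g0.5", "g1.0"]

    def test_constant_gene_removed_and_empty_result_warns(self):
        expr = _expr_from_rows({"flat": np.full(6, 2.0)}, 3)
        with pytest.warns(UserWarning, match="every gene"):
            kept = filter_by_variance(expr, 0.25)
        assert kept.gene_ids == []


class TestCorrelationSignificance:
    def test_paper_scale_bonferroni_level(self):
        """The family-wise per-test level for 1313 TFs x 18165 genes at
        alpha 0.05 is ~2e-9."""
        thr = bonferroni_threshold(1313, 18165, 0.05)
        assert thr == pytest.approx(0.05 / (1313 * 18165))
        assert f"{thr:.0e}" == "2e-09"

    def test_known_pcc_against_normal_cdf_oracle(self):
        """pcc = 0.5 with 30 tissues: z = atanh(0.5), p = 2(1 - Phi(z sqrt(27)))."""
        n = 30
        rng = np.random.default_rng(5)
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        # construct y with empirical pcc exactly 0.5
        xs = (x - x.mean()) / x.std(ddof=1)
        resid = e - np.polyval(np.polyfit(xs, e, 1), xs)
        ys = 0.5 * xs + np.sqrt(0.75) * resid / resid.std(ddof=1)
        expr = _expr_from_rows({"TF": xs, "g": ys}, n_tissues=30)
        res = correlation_significance(expr, ["TF"], alpha_fwer=0.05)
        z_expected = np.arctanh(0.5)
        p_expected = 2 * (1 - sps.norm.cdf(z_expected * np.sqrt(27)))
        assert res.pcc.loc["TF", "g"] == pytest.approx(0.5, abs=1e-12)
        assert res.z.loc["TF", "g"] == pytest.approx(z_expected, abs=1e-12)
        assert res.p.loc["TF", "g"] == pytest.approx(p_expected, rel=1e-10)
        # p ~ 0.0043 < 0.05/(1x1): significant, positive edge
        assert res.signed_adjacency.loc["TF", "g"] == 1

    def test_perfect_anticorrelation_limit(self):
        x = np.linspace(0, 1, 10)
        expr = _expr_from_rows({"TF": x, "g": -2 * x + 3}, n_tissues=5)
        res = correlation_significance(expr, ["TF"])
        assert res.p.loc["TF", "g"] == 0.0
        assert res.signed_adjacency.loc["TF", "g"] == -1

    def test_zero_variance_gene_excluded(self):
        x = np.linspace(0, 1, 10)
        expr = _expr_from_rows({"TF": x, "flat": np.full(10, 1.0)}, n_tissues=5)
        res = correlation_significance(expr, ["TF"])
        assert res.pcc.loc["TF", "flat"] == 0.0
        assert res.signed_adjacency.loc["TF", "flat"] == 0

    def test_too_few_tissues_rejected(self):
        x = np.arange(8.0)
        expr = _expr_from_rows({"TF": x, "g": x**2}, n_tissues=4)
        with pytest.raises(ValueError, match="tissues"):
            correlation_significance(expr, ["TF"])


def _pcor_residualization(data: np.ndarray, j: int) -> float:
    """Independent oracle: partial correlation of columns 0 and j of ``data``
    given the remaining columns, via residuals of two OLS fits."""
    n, k = data.shape
    others = [c for c in range(k) if c not in (0, j)]
    X = np.column_stack([np.ones(n), data[:, others]])
    beta0, *_ = np.linalg.lstsq(X, data[:, 0], rcond=None)
    betaj, *_ = np.linalg.lstsq(X, data[:, j], rcond=None)
    r0 = data[:, 0] - X @ beta0
    rj = data[:, j] - X @ betaj
    return float(np.corrcoef(r0, rj)[0, 1])


class TestPartialCorrelation:
    def test_precision_matrix_equals_residualization_oracle(self):
        """Two independent formulas for the partial correlation agree to
        1e-10 on 100 random 5-variable systems."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            data = rng.normal(size=(40, 5)) @ rng.normal(size=(5, 5))
            corr = np.corrcoef(data.T)
            pcors = _partial_correlations(corr, n_samples=40)
            for j in range(1, 5):
                assert pcors[j - 1] == pytest.approx(
                    _pcor_residualization(data, j), abs=1e-10
                )

    def test_correlated_proxy_tf_is_pruned(self):
        """g is driven by TF1; TF2 is a noisy proxy of TF1. After
        conditioning, the TF2 edge drops below 0.2 while TF1 survives."""
        rng = np.random.default_rng(7)
        n = 1000
        tf1 = rng.normal(size=n)
        tf2 = tf1 + rng.normal(scale=0.5, size=n)
        g = tf1 + rng.normal(scale=0.3, size=n)
        expr = _expr_from_rows({"TF1": tf1, "TF2": tf2, "g": g}, n_tissues=5)
        adj = pd.DataFrame([[1], [1]], index=["TF1", "TF2"], columns=["g"])
        pruned = prune_by_partial_correlation(adj, expr, pcor_min=0.2)
        assert pruned.loc["TF1", "g"] == 1
        assert pruned.loc["TF2", "g"] == 0
        # oracle agreement on the conditioned values
        data = expr.values.loc[["g", "TF1", "TF2"]].to_numpy().T
        corr = np.corrcoef(data.T)
        pcors = _partial_correlations(corr, n)
        assert pcors[0] == pytest.approx(_pcor_residualization(data, 1), abs=1e-10)
        assert abs(pcors[1]) < 0.2

    def test_single_candidate_gene_untouched(self):
        rng = np.random.default_rng(0)
        expr = _expr_from_rows(
            {"TF1": rng.normal(size=20), "g": rng.normal(size=20)}, n_tissues=5
        )
        adj = pd.DataFrame([[1]], index=["TF1"], columns=["g"])
        pruned = prune_by_partial_correlation(adj, expr, pcor_min=0.99)
        assert pruned.loc["TF1", "g"] == 1

    def test_singular_submatrix_falls_back_to_pseudoinverse(self):
        rng = np.random.default_rng(1)
        tf1 = rng.normal(size=30)
        expr = _expr_from_rows({"TF1": tf1, "TF2": tf1.copy(), "g": tf1 + rng.normal(size=30)}, 5)
        adj = pd.DataFrame([[1], [1]], index=["TF1", "TF2"], columns=["g"])
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            prune_by_partial_correlation(adj, expr, pcor_min=0.2)


class TestMinTargets:
    def test_inclusive_boundary(self):
        net = RegulatoryNetwork(
            {
                "A": {f"g{i}": 1 for i in range(10)},
                "B": {f"g{i}": 1 for i in range(9)},
            }
        )
        kept = filter_min_targets(net, 10)
        assert kept.tf_ids == ["A"]

    def test_toy_example(self):
        net = RegulatoryNetwork(
            {
                "A": {f"g{i}": 1 for i in range(12)},
                "B": {f"g{i}": -1 for i in range(3)},
            }
        )
        assert filter_min_targets(net, 10).tf_ids == ["A"]

    def test_adjacency_frame_variant(self):
        adj = pd.DataFrame(
            [[1] * 10 + [0], [1] * 3 + [0] * 8],
            index=["A", "B"],
            columns=[f"g{i}" for i in range(11)],
        )
        assert filter_min_targets(adj, 10).index.tolist() == ["A"]


class TestTissueSpecificSelection:
    def test_flat_tf_excluded_and_planted_tf_included(self, sim_default):
        _, expr, truth = sim_default
        tfs = [g for g in expr.gene_ids if g.startswith("TF_")]
        selected = select_tissue_specific_tfs(expr, tfs, BuildParams(target_tissue="lung"))
        assert set(selected) == {"TF_SP01", "TF_SP02", "TF_SP03"}

    def test_immune_confounder_removed_by_guard_only(self, sim_default):
        _, expr, truth = sim_default
        tfs = [g for g in expr.gene_ids if g.startswith("TF_")]
        no_guard = select_tissue_specific_tfs(
            expr, tfs, BuildParams(target_tissue="lung", guard_tissues=())
        )
        assert {"TF_IM01", "TF_IM02"} <= set(no_guard)

    def test_missing_guard_tissue_error_mentions_disabling(self, toy_expr):
        with pytest.raises(ValueError, match="disable"):
            select_tissue_specific_tfs(
                toy_expr, ["gA"], BuildParams(target_tissue="liver")
            )


class TestBuildPipeline:
    def test_planted_network_recovered(self, sim_default, built_network):
        _, expr, truth = sim_default
        net, report = built_network
        assert net.tf_ids == ["TF_SP01", "TF_SP02", "TF_SP03"]
        true_edges = {
            (tf, g)
            for tf in net.tf_ids
            for g in truth.true_network.edges[tf]
        }
        found = {(tf, g) for tf in net.tf_ids for g in net.edges[tf]}
        tp = len(true_edges & found)
        f1 = 2 * tp / (len(found) + len(true_edges))
        assert f1 >= 0.9

    def test_report_counts_are_monotone_through_stages(self, built_network):
        net, report = built_network
        assert report["n_tfs_tested"] >= report["n_tfs_after_first_min_target_filter"]
        assert (
            report["n_tfs_after_first_min_target_filter"]
            >= report["n_tfs_after_pruning"]
            >= report["n_tfs_final"]
        )
        assert report["n_edges_final"] == report["n_edges_positive"] + report["n_edges_negative"]

    def test_edge_signs_match_marginal_correlation(self, sim_default, built_network):
        _, expr, _ = sim_default
        net, _ = built_network
        for tf in net.tf_ids:
            for g, sign in net.edges[tf].items():
                pcc = np.corrcoef(expr.values.loc[tf], expr.values.loc[g])[0, 1]
                assert np.sign(pcc) == sign

    def test_extreme_significance_threshold_empties_network(self, sim_default):
        """An unreachable per-test level leaves every TF below min_targets;
        the error carries the stage-by-stage counts."""
        _, expr, _ = sim_default
        tfs = [g for g in expr.gene_ids if g.startswith("TF_")]
        with pytest.raises(EmptyNetworkError) as err:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                build_network(
                    expr, tfs, BuildParams(target_tissue="lung", alpha_fwer=1e-12)
                )
        assert err.value.report["n_tfs_after_first_min_target_filter"] == 0

    def test_extreme_pcor_threshold_prunes_shared_targets(self, sim_default):
        """pcor_min = 0.99 removes (nearly) every edge of genes claimed by
        two or more TFs; single-candidate genes are untouched by design."""
        _, expr, _ = sim_default
        tfs = [g for g in expr.gene_ids if g.startswith("TF_")]
        expr_f = filter_by_variance(expr, 0.25)
        present = sorted(set(tfs) & set(expr_f.values.index))
        adj = correlation_significance(expr_f, present).signed_adjacency
        pruned = prune_by_partial_correlation(adj, expr_f, pcor_min=0.99)
        multi = adj.columns[(adj != 0).sum(axis=0) >= 2]
        if len(multi):
            assert (pruned[multi] != 0).to_numpy().sum() < (adj[multi] != 0).to_numpy().sum()
        single = adj.columns[(adj != 0).sum(axis=0) == 1]
        assert pruned[single].equals(adj[single])

    def test_guard_identical_to_target_blocks_all_tfs(self, sim_default):
        _, expr, _ = sim_default
        values = expr.values.copy()
        lung = [s for s in expr.sample_ids if s.startswith("lung")]
        for guard in ("blood", "spleen"):
            cols = [s for s in expr.sample_ids if s.startswith(guard)]
            values[cols] = expr.values[lung].to_numpy()
        clone = ExpressionMatrix(values, expr.tissues)
        tfs = [g for g in clone.gene_ids if g.startswith("TF_")]
        with pytest.raises(EmptyNetworkError, match="tissue-specificity"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                build_network(clone, tfs, BuildParams(target_tissue="lung"))

    @pytest.mark.parametrize(
        "loose,strict",
        [
            (dict(sd_min=0.25), dict(sd_min=0.6)),
            (dict(pcor_min=0.2), dict(pcor_min=0.5)),
            (dict(min_targets=10), dict(min_targets=25)),
        ],
    )
    def test_raising_thresholds_never_adds_edges(self, sim_default, loose, strict):
        _, expr, _ = sim_default
        tfs = [g for g in expr.gene_ids if g.startswith("TF_")]

        def edges_of(params):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net, _ = build_network(
                        expr, tfs, BuildParams(target_tissue="lung", **params)
                    )
            except EmptyNetworkError:
                return set()
            return {(tf, g) for tf in net.tf_ids for g in net.edges[tf]}

        assert edges_of(strict) <= edges_of(loose)

    def test_no_edges_on_permuted_expression(self, sim_default):
        """Destroying the gene-gene correlation structure (independent
        within-row permutations) yields essentially no significant edges
        under the effective-sample-size Bonferroni null (20 permutations)."""
        _, expr, _ = sim_default
        rng = np.random.default_rng(11)
        tfs = [g for g in expr.gene_ids if g.startswith("TF_")]
        total_edges = 0
        for _ in range(20):
            shuffled = expr.values.to_numpy().copy()
            for row in shuffled:
                rng.shuffle(row)
            perm = ExpressionMatrix(
                pd.DataFrame(shuffled, index=expr.values.index, columns=expr.values.columns),
                expr.tissues,
            )
            res = correlation_significance(perm, tfs, alpha_fwer=0.05)
            total_edges += int((res.signed_adjacency != 0).to_numpy().sum())
        assert total_edges <= 2
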