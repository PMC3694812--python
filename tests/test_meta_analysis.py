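import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from phosflow.errors import ValidationError
from phosflow.meta_analysis import (
    aw_null_minima, aw_statistic, bh_qvalues, build_regulation_pairs,
    combine_fisher_extended, hypergeometric_enrichment, meta_analyze,
    select_differential_per_mutant, select_globally_significant, significance_b,
)


# ---------------------------------------------------------------------------
# independent oracles

def bh_oracle(p):
    """O(n^2) literal step-up: q_i = min over {j: p_j >= p_i} of n p_j / rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, int)
    ranks[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        candidates = [
            n * p[j] / ranks[j] for j in range(n) if p[j] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


def chi2_upper_tail_by_integration(x, dof):
    val, _ = quad(lambda t: stats.chi2.pdf(t, dof), x, np.inf)
    return val


class TestSignificanceB:
    def test_target_at_median_gives_p_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        assert significance_b(x, float(np.median(x))) == pytest.approx(1.0)

    def test_one_sigma_deviation_matches_normal_tail(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        target = float(np.percentile(x, 84.13))
        # standardized deviation ~= 1, so two-sided p ~= 0.3173
        assert significance_b(x, target) == pytest.approx(0.3173, abs=0.02)

    def test_symmetric_sample_symmetric_p(self):
        base = np.linspace(0.1, 3.0, 50)
        x = np.concatenate([-base, base])
        assert significance_b(x, 1.7) == pytest.approx(
            significance_b(x, -1.7), abs=1e-12
        )

    def test_degenerate_scale_error_names_side(self):
        x = np.concatenate([np.zeros(30), [-1.0]])
        with pytest.raises(ValidationError, match="right"):
            significance_b(x, 2.0)

    def test_requires_twenty_values(self):
        with pytest.raises(ValidationError):
            significance_b(np.arange(10.0), 1.0)


class TestFisherExtension:
    def test_all_ones_gives_unit_combined_p(self):
        res = combine_fisher_extended([1.0] * 8)
        assert res.statistic == pytest.approx(0.0)
        assert res.dof == 16
        assert res.p_value == pytest.approx(1.0)

    def test_single_available_p_is_identity(self):
        res = combine_fisher_extended([0.05] + [None] * 7)
        assert res.dof == 2
        assert res.p_value == pytest.approx(0.05, abs=1e-12)

    def test_two_available_matches_integration_oracle(self):
        res = combine_fisher_extended([0.01, 0.04] + [None] * 6)
        assert res.statistic == pytest.approx(15.648, abs=1e-3)
        assert res.dof == 4
        assert res.p_value == pytest.approx(
            chi2_upper_tail_by_integration(res.statistic, 4), rel=1e-8
        )

    def test_complete_vector_matches_classical_fisher(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=8)
            ours = combine_fisher_extended(p)
            stat, pval = stats.combine_pvalues(p, method="fisher")
            assert ours.statistic == pytest.approx(stat, abs=1e-12)
            assert ours.p_value == pytest.approx(pval, abs=1e-12)

    def test_all_missing_yields_sentinel_not_exception(self):
        res = combine_fisher_extended([None] * 8)
        assert res.m_available == 0
        assert np.isnan(res.p_value)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = combine_fisher_extended([0.0] + [None] * 7)
        assert np.isfinite(res.statistic)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            combine_fisher_extended([1.5] + [None] * 7)

    def test_null_combined_p_is_uniform_per_missingness_level(self):
        rng = np.random.default_rng(11)
        for m in (2, 5, 8):
            pvals = [
                combine_fisher_extended(
                    list(rng.uniform(size=m)) + [None] * (8 - m)
                ).p_value
                for _ in range(400)
            ]
            assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestBHQvalues:
    def test_singleton_identity(self):
        assert bh_qvalues([0.04]) == pytest.approx([0.04])

    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_constant_vector_fixed_point(self):
        np.testing.assert_allclose(bh_qvalues([0.3] * 5), [0.3] * 5)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_qvalues(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_qvalues([0.1, 1.2])


class TestAwStatistic:
    def test_all_ones(self):
        res = aw_statistic(np.ones(8), n_null=1000, seed=0)
        assert res.aw_statistic == pytest.approx(1.0)
        assert res.calibrated_p > 0.9

    def test_single_signal_selects_single_condition(self):
        p = np.array([0.001] + [1.0] * 7)
        res = aw_statistic(p, n_null=1000, seed=0)
        # exhaustive oracle over the 255 weight vectors
        best_p, best_w = 2.0, None
        for w in range(1, 256):
            mask = [(w >> i) & 1 for i in range(8)]
            x = sum(m * -2 * np.log(v) for m, v in zip(mask, p))
            pv = stats.chi2.sf(x, 2 * sum(mask))
            if pv < best_p:
                best_p, best_w = pv, tuple(mask)
        assert res.best_weight_vector == best_w == (1, 0, 0, 0, 0, 0, 0, 0)
        assert res.aw_statistic == pytest.approx(best_p, rel=1e-10)

    def test_missing_values_rejected(self):
        p = np.array([0.5] * 7 + [np.nan])
        with pytest.raises(ValidationError):
            aw_statistic(p, n_null=1000, seed=0)

    def test_calibrated_p_uniform_under_null(self):
        rng = np.random.default_rng(7)
        null = aw_null_minima(2000, seed=1)
        obs = aw_null_minima(2000, seed=2)
        calibrated = np.array(
            [(np.sum(null <= o) + 1) / (len(null) + 1) for o in obs]
        )
        assert stats.kstest(calibrated, "uniform").pvalue > 1e-3

    def test_deterministic_under_seed(self):
        p = np.array([0.01, 0.2, 0.5, 0.9, 0.3, 0.7, 0.05, 0.6])
        a = aw_statistic(p, n_null=1000, seed=42)
        b = aw_statistic(p, n_null=1000, seed=42)
        assert a == b


class TestSelectionRules:
    def _meta_row(self, combined_p, q, n_sig, m_avail):
        return pd.DataFrame(
            {
                "combined_p": [combined_p],
                "q_value": [q],
                "n_significant_conditions": [n_sig],
                "m_available": [m_avail],
            },
            index=["pep"],
        )

    def test_all_criteria_met_complete(self):
        out = select_globally_significant(self._meta_row(0.01, 0.01, 4, 8))
        assert bool(out["globally_significant"].iloc[0])
        assert bool(out["high_confidence"].iloc[0])

    def test_count_rule_fails(self):
        out = select_globally_significant(self._meta_row(0.01, 0.01, 3, 8))
        assert not bool(out["globally_significant"].iloc[0])

    def test_incomplete_not_high_confidence(self):
        out = select_globally_significant(self._meta_row(0.01, 0.01, 5, 6))
        assert bool(out["globally_significant"].iloc[0])
        assert not bool(out["high_confidence"].iloc[0])

    def test_selection_monotone_in_per_condition_p(self, reference_matrix):
        matrix, _ = reference_matrix
        meta = meta_analyze(matrix)
        selected = set(meta.index[meta["globally_significant"]])
        # lowering every significance B can only grow the selected set
        import copy

        better = copy.deepcopy(matrix)
        better.significance_b = better.significance_b / 2.0
        meta2 = meta_analyze(better)
        selected2 = set(meta2.index[meta2["globally_significant"]])
        assert selected <= selected2


class TestDifferentialAndPairs:
    def test_significant_cell_becomes_edge(self, toy_matrix):
        diff = select_differential_per_mutant(toy_matrix, threshold=0.05)
        rows = {(r.kinase, r.modified_sequence, r.direction) for r in diff.itertuples()}
        assert ("SNF1", "_AAS(ph)GR_", "down") in rows
        # sigB 0.2 and 0.8 cells excluded; missing cells excluded
        assert all(k == "SNF1" for k, _, _ in rows)

    def test_per_mutant_semantics_and_isoform_explosion(self, toy_matrix):
        diff = select_differential_per_mutant(toy_matrix, threshold=0.9)
        pairs = build_regulation_pairs(diff)
        # the PFK2a;PFK2b peptide explodes into one edge per isoform
        targets = set(pairs["target_protein"])
        assert {"PFK2a", "PFK2b"} <= targets
        per_pep = pairs.groupby("modified_sequence")["kinase"].nunique()
        assert per_pep["_AAS(ph)GR_"] == 2  # significant in 2 mutants -> 2 kinases

    def test_empty_differential_empty_pairs(self):
        empty = pd.DataFrame(
            columns=["kinase", "modified_sequence", "proteins", "direction",
                     "significance_b", "ratio"]
        )
        assert build_regulation_pairs(empty).empty


class TestEnrichment:
    def test_term_equal_to_cluster_is_most_enriched(self):
        background = {f"g{i}" for i in range(20)}
        cluster = {f"g{i}" for i in range(10)}
        annotation = {
            "exact": frozenset(cluster),
            "half": frozenset(list(cluster)[:5]),
            "other": frozenset(f"g{i}" for i in range(10, 20)),
        }
        out = hypergeometric_enrichment(cluster, annotation, background)
        assert out.iloc[0]["term"] == "exact"

    def test_disjoint_term_p_one(self):
        background = {"a", "b", "c", "d"}
        out = hypergeometric_enrichment(
            {"a", "b"}, {"t": frozenset({"c", "d"})}, background
        )
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_pmf_summation_oracle(self):
        background = {f"g{i}" for i in range(12)}
        cluster = {"g0", "g1", "g2", "g3"}
        term = frozenset({"g0", "g1", "g4", "g5", "g6"})
        out = hypergeometric_enrichment(cluster, {"t": term}, background)
        # sum the hypergeometric pmf over overlaps >= observed
        N, K, n, k = 12, 5, 4, 2
        oracle = sum(
            stats.hypergeom.pmf(x, N, K, n) for x in range(k, min(K, n) + 1)
        )
        assert out["p_value"].iloc[0] == pytest.approx(oracle, rel=1e-10)

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment({"x"}, {}, {"a"})
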