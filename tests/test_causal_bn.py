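import itertools

import numpy as np
import pandas as pd
import pytest

from phosflow.causal_bn import (
    BASELINE, MISSING, OVER, UNDER, bde_family_score, causal_screen, discretize,
    discretize_ratio, intervention_masks, score_pair, screen_to_frame,
)
from phosflow.core_model import KINASES, PhosphoPeptide, RatioMatrix
from phosflow.errors import ValidationError
from phosflow.synthetic_data import CausalEdge, generate_causal_cases


# ---------------------------------------------------------------------------
# sequential predictive-probability oracle for the BDe family term

def bde_oracle(child, parent=None, ess=1.0):
    """Chain rule over cases: prod (N_jk + a_jk) / (N_j + a_j)."""
    q = 3 if parent is not None else 1
    parent = parent if parent is not None else [0] * len(child)
    a_jk = ess / (q * 3)
    a_j = ess / q
    counts = {}
    n_j = {}
    logp = 0.0
    for c, j in zip(child, parent):
        logp += np.log(
            (counts.get((j, c), 0) + a_jk) / (n_j.get(j, 0) + a_j)
        )
        counts[(j, c)] = counts.get((j, c), 0) + 1
        n_j[j] = n_j.get(j, 0) + 1
    return logp


class TestDiscretize:
    @pytest.mark.parametrize(
        "ratio,state",
        [
            (0.33, UNDER),     # Elm1-column value of the worked ratio table
            (0.5, BASELINE),   # boundary: strict inequality
            (1.0, BASELINE),
            (2.0, BASELINE),   # boundary: strict inequality
            (2.3, OVER),       # Sks1-column value of the worked ratio table
        ],
    )
    def test_two_fold_boundaries(self, ratio, state):
        assert discretize_ratio(ratio) == state

    def test_matrix_discretization_preserves_missingness(self):
        keys = ["_AS(ph)R_"]
        ratio = pd.DataFrame(
            [[0.33, 2.3, np.nan, 1.0, 0.5, 2.0, 4.0, 0.1]],
            index=keys, columns=list(KINASES),
        )
        m = RatioMatrix(
            peptides=[PhosphoPeptide(keys[0], ("A",))], ratio=ratio
        )
        states = discretize(m).iloc[0].tolist()
        assert states == [UNDER, OVER, MISSING, BASELINE, BASELINE, BASELINE,
                          OVER, UNDER]


class TestBdeFamilyScore:
    def test_zero_usable_cases_scores_zero(self):
        assert bde_family_score(np.array([MISSING, MISSING])) == 0.0

    def test_four_case_toy_matches_oracle(self):
        child = [0, 1, 1, 2]
        parent = [0, 0, 1, 2]
        got = bde_family_score(np.array(child), np.array(parent))
        assert got == pytest.approx(bde_oracle(child, parent), abs=1e-12)

    def test_case_order_invariance(self):
        rng = np.random.default_rng(0)
        child = rng.integers(0, 3, 8)
        parent = rng.integers(0, 3, 8)
        base = bde_family_score(child, parent)
        for _ in range(10):
            perm = rng.permutation(8)
            assert bde_family_score(child[perm], parent[perm]) == pytest.approx(
                base, abs=1e-12
            )

    def test_exhaustive_small_tables_match_oracle(self):
        # every parent-absent multiset with <= 4 cases
        for n in range(1, 5):
            for combo in itertools.combinations_with_replacement(range(3), n):
                child = np.array(combo)
                assert bde_family_score(child) == pytest.approx(
                    bde_oracle(list(combo)), abs=1e-9
                )

    def test_invalid_ess_rejected(self):
        with pytest.raises(ValidationError):
            bde_family_score(np.array([0, 1]), prior_ess=0.0)


class TestScorePair:
    def test_observational_likelihood_equivalence(self):
        rng = np.random.default_rng(1)
        for ess in (1.0, 3.0, 9.0):
            x = rng.integers(0, 3, 8)
            y = rng.integers(0, 3, 8)
            res = score_pair(x, y, prior_ess=ess)
            assert res.log_marginal["x->y"] == pytest.approx(
                res.log_marginal["y->x"], abs=1e-10
            )
            assert res.posterior["x->y"] <= 0.5 + 1e-12

    def test_posteriors_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(2)
        x, y = rng.integers(0, 3, 8), rng.integers(0, 3, 8)
        res = score_pair(x, y)
        assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-12)

    def test_intervention_breaks_direction_tie(self):
        edge = CausalEdge("SNF1", "TGT", "+", 2.0)
        cases, mask = generate_causal_cases(edge, 8, leak=0.0, seed=4)
        res = score_pair(
            cases["source_state"].to_numpy(), cases["target_state"].to_numpy(),
            mask, None,
        )
        assert res.best_structure == "x->y"
        assert res.log_marginal["x->y"] > res.log_marginal["y->x"]

    def test_direction_recovered_across_seeds(self):
        edge = CausalEdge("SNF1", "TGT", "+", 2.0)
        wins = 0
        for seed in range(50):
            cases, mask = generate_causal_cases(edge, 8, leak=0.0, seed=seed)
            res = score_pair(
                cases["source_state"].to_numpy(),
                cases["target_state"].to_numpy(), mask, None,
            )
            wins += res.best_structure == "x->y"
        assert wins >= 45

    def test_all_missing_node_yields_sentinel(self):
        x = np.full(8, MISSING)
        y = np.zeros(8, dtype=int)
        assert score_pair(x, y) is None

    def test_sign_annotation_from_co_change_pattern(self):
        x = np.array([0, 0, 1, 1, 2, 2, 0, 2])
        res_pos = score_pair(x, x.copy())
        assert res_pos.sign_annotation == "activating"
        res_neg = score_pair(x, 2 - x)
        assert res_neg.sign_annotation == "inhibitory"


class TestCausalScreen:
    def _states(self, rows):
        df = pd.DataFrame(rows).T
        df.columns = list(KINASES)
        return df

    def test_independent_observational_data_reports_nothing(self):
        rng = np.random.default_rng(3)
        states = self._states(
            {f"p{i}": rng.integers(0, 3, 8) for i in range(3)}
        )
        mapping = {f"p{i}": frozenset({f"N{i}"}) for i in range(3)}
        _, reported = causal_screen(states, mapping, report_threshold=0.5)
        assert reported == []

    def test_planted_edge_direction_recovered_and_nulls_quiet(self):
        edge = CausalEdge("SNF1", "TGT", "+", 2.0)
        k_snf1 = KINASES.index("SNF1")
        correct = 0
        for seed in range(50):
            rng = np.random.default_rng(900 + seed)
            cases, _ = generate_causal_cases(edge, 8, leak=0.0, seed=seed)
            src = np.empty(8, int)
            tgt = np.empty(8, int)
            src[k_snf1], tgt[k_snf1] = cases["source_state"][0], cases["target_state"][0]
            rest = [j for j in range(8) if j != k_snf1]
            src[rest] = cases["source_state"].to_numpy()[1:]
            tgt[rest] = cases["target_state"].to_numpy()[1:]
            rows = {"pepS": src, "pepT": tgt}
            for i in range(4):
                rows[f"null{i}"] = rng.integers(0, 3, 8)
            states = self._states(rows)
            mapping = {
                "pepS": frozenset({"SNF1"}), "pepT": frozenset({"TGT"}),
                **{f"null{i}": frozenset({f"N{i}"}) for i in range(4)},
            }
            results, reported = causal_screen(states, mapping,
                                              report_threshold=0.5)
            planted = next(
                r for r in results if {r.node_x, r.node_y} == {"pepS", "pepT"}
            )
            correct += planted.best_structure == "x->y"
            # never-intervened complete pairs cannot resolve a direction
            for r in results:
                if "pepS" not in (r.node_x, r.node_y):
                    assert max(r.posterior["x->y"], r.posterior["y->x"]) <= 0.5 + 1e-12
        assert correct >= 45

    def test_threshold_one_reports_nothing(self):
        rng = np.random.default_rng(5)
        states = self._states({f"p{i}": rng.integers(0, 3, 8) for i in range(3)})
        mapping = {f"p{i}": frozenset({f"N{i}"}) for i in range(3)}
        _, reported = causal_screen(states, mapping, report_threshold=1.0)
        assert reported == []

    def test_screen_needs_two_peptides(self):
        states = self._states({"p0": np.zeros(8, int)})
        with pytest.raises(ValidationError):
            causal_screen(states, {"p0": frozenset({"A"})})

    def test_intervention_mask_marks_own_condition_only(self):
        states = self._states({"kpep": np.zeros(8, int), "other": np.zeros(8, int)})
        mapping = {"kpep": frozenset({"SNF1"}), "other": frozenset({"X"})}
        masks = intervention_masks(states, mapping)
        assert masks.loc["kpep", "SNF1"]
        assert masks.loc["kpep"].sum() == 1
        assert masks.loc["other"].sum() == 0

    def test_screen_frame_columns(self):
        rng = np.random.default_rng(6)
        states = self._states({f"p{i}": rng.integers(0, 3, 8) for i in range(3)})
        mapping = {f"p{i}": frozenset({f"N{i}"}) for i in range(3)}
        results, _ = causal_screen(states, mapping)
        frame = screen_to_frame(results)
        assert {"best_structure", "best_posterior", "sign"} <= set(frame.columns)
        assert len(frame) == 3
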