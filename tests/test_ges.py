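"""Scores and the greedy equivalence search against exhaustive oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from cardiocausal.ges import (
    MixedDataset,
    ScoreModel,
    Scorer,
    exhaustive_best_dag,
    ges_search,
    score_local,
)

BIC = ScoreModel(kind="bic")


def _dataset(arrays: dict[str, np.ndarray]) -> MixedDataset:
    return MixedDataset.from_dataframe(pd.DataFrame(arrays))


class TestMixedDataset:
    def test_binary_column_detected_and_preserved(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50), "label": rng.integers(0, 2, 50)})
        data = MixedDataset.from_dataframe(df, target="label")
        assert data.types == ["continuous", "binary"]
        assert set(np.unique(data.X[:, 1])) <= {0.0, 1.0}
        # continuous columns standardized
        assert abs(data.X[:, 0].mean()) < 1e-12
        assert abs(data.X[:, 0].std() - 1) < 1e-12

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            _dataset({"x": np.array([1.0, np.nan])})

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            MixedDataset.from_dataframe(pd.DataFrame({"x": [0.1, 0.3]}), target="nope")


class TestBicScore:
    def test_spurious_parent_penalized_for_independent_pair(self):
        # BIC gap for an irrelevant parent is about -(1/2) log n plus an
        # O_p(1) likelihood term, so the empty model wins with high
        # probability; check across seeds
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = _dataset(
                {"x": rng.normal(size=1000), "y": rng.normal(size=1000)}
            )
            s0 = score_local(data, "y", set(), BIC)
            s1 = score_local(data, "y", {"x"}, BIC)
            wins += int(s0 > s1)
        assert wins >= 9

    def test_true_parent_improves_score(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        data = _dataset({"x": x, "y": y})
        # analytic likelihood-ratio: n/2 * log(var(y)/var(resid)) ~ n/2*log 2,
        # dwarfing the single-parameter BIC penalty
        gain = score_local(data, "y", {"x"}, BIC) - score_local(data, "y", set(), BIC)
        assert gain > 0.25 * 500 * math.log(2)

    def test_parent_set_order_irrelevant_and_cached(self):
        rng = np.random.default_rng(0)
        data = _dataset({k: rng.normal(size=200) for k in "xyz"})
        sc = Scorer(data, BIC)
        a = score_local(data, "z", {"x", "y"}, BIC, scorer=sc)
        b = score_local(data, "z", {"y", "x"}, BIC, scorer=sc)
        assert a == b  # set semantics and bit-identical cache hits

    def test_decomposability(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = x + rng.normal(size=300)
        z = y + rng.normal(size=300)
        data = _dataset({"x": x, "y": y, "z": z})
        sc = Scorer(data, BIC)
        total = sc.total({0: frozenset(), 1: frozenset({0}), 2: frozenset({1})})
        parts = [
            sc.local(0, frozenset()),
            sc.local(1, frozenset({0})),
            sc.local(2, frozenset({1})),
        ]
        assert total == pytest.approx(sum(parts), abs=1e-12)


class TestKernelScore:
    def test_deterministic_given_fold_seed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=120)
        y = np.sin(2 * x) + 0.2 * rng.normal(size=120)
        data = _dataset({"x": x, "y": y})
        m = ScoreModel(kind="kernel", cv_folds=5, fold_seed=11)
        assert score_local(data, "y", {"x"}, m) == score_local(data, "y", {"x"}, m)

    def test_detects_nonlinear_dependence(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=250)
        y = np.sin(3 * x) + 0.2 * rng.normal(size=250)  # nearly uncorrelated
        data = _dataset({"x": x, "y": y})
        m = ScoreModel(kind="kernel", cv_folds=5)
        assert score_local(data, "y", {"x"}, m) > score_local(data, "y", set(), m)

    def test_agrees_with_bic_on_linear_gaussian_edge_presence(self):
        # both scores should make the same keep/drop decision for a strong
        # linear edge and for an independent pair, across seeds
        m = ScoreModel(kind="kernel", cv_folds=5)
        agree = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=1000)
            y = 0.8 * x + rng.normal(size=1000)
            data = _dataset({"x": x, "y": y})
            keep_k = score_local(data, "y", {"x"}, m) > score_local(data, "y", set(), m)
            keep_b = score_local(data, "y", {"x"}, BIC) > score_local(
                data, "y", set(), BIC
            )
            agree += int(keep_k == keep_b)
        assert agree >= 18  # >= 90 %

    def test_constant_node_warns_not_crashes(self):
        data = MixedDataset(
            names=["c", "x"],
            types=["continuous", "continuous"],
            X=np.column_stack(
                [np.zeros(60), np.random.default_rng(0).normal(size=60)]
            ),
        )
        m = ScoreModel(kind="kernel", cv_folds=3)
        with pytest.warns(RuntimeWarning, match="constant"):
            val = score_local(data, "c", set(), m)
        assert np.isfinite(val)


class TestGesSearch:
    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(2)
        data = _dataset({k: rng.normal(size=800) for k in "abcd"})
        g = ges_search(data, BIC)
        assert g.n_edges() == 0

    def test_chain_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = x + rng.normal(size=2000)
        z = y + rng.normal(size=2000)
        data = _dataset({"x": x, "y": y, "z": z})
        g = ges_search(data, BIC)
        oracle, _ = exhaustive_best_dag(data, BIC)
        assert g.same_structure(oracle)

    def test_collider_is_oriented(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        z = x + y + rng.normal(size=2000)
        data = _dataset({"x": x, "y": y, "z": z})
        g = ges_search(data, BIC)
        assert g.has_directed("x", "z") and g.has_directed("y", "z")
        assert not g.adjacent("x", "y")

    def test_phases_monotone_and_partitioned(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=1500)
        y = x + rng.normal(size=1500)
        z = x + y + rng.normal(size=1500)
        w = rng.normal(size=1500)
        trace: list[dict] = []
        ges_search(_dataset({"x": x, "y": y, "z": z, "w": w}), BIC, trace=trace)
        assert trace, "search accepted no move on dependent data"
        phases = [t["phase"] for t in trace]
        assert phases == sorted(phases, key=("forward", "backward").index)
        assert all(t["delta"] > 0 for t in trace)
        assert all(
            (t["op"] == "insert") == (t["phase"] == "forward") for t in trace
        )

    def test_move_budget_enforced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        data = _dataset({"x": x, "y": x + 0.1 * rng.normal(size=500)})
        with pytest.raises(RuntimeError, match="budget"):
            ges_search(data, BIC, max_moves=0)


class TestExhaustive:
    def test_single_variable_empty(self):
        data = _dataset({"x": np.random.default_rng(0).normal(size=100)})
        g, _ = exhaustive_best_dag(data, BIC)
        assert g.n_edges() == 0

    def test_two_independent_variables_prefer_empty(self):
        rng = np.random.default_rng(7)
        data = _dataset({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
        sc = Scorer(data, BIC)
        empty = sc.local(0, frozenset()) + sc.local(1, frozenset())
        edge = sc.local(0, frozenset()) + sc.local(1, frozenset({0}))
        assert empty > edge
        g, best = exhaustive_best_dag(data, BIC)
        assert g.n_edges() == 0
        assert best == pytest.approx(empty)

    def test_refuses_more_than_four_variables(self):
        rng = np.random.default_rng(0)
        data = _dataset({f"x{i}": rng.normal(size=50) for i in range(5)})
        with pytest.raises(ValueError, match="4"):
            exhaustive_best_dag(data, BIC)
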