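"""GO level computation, level-threshold features, and level-N rollup."""

import numpy as np
import pytest

from adrnet.errors import StructuralError
from adrnet.facts import build_target_facts
from adrnet.go import compute_levels, rollup_features, threshold_features
from adrnet.io import DrugTargetMap, GODag


def make_dag(parents, annotations=None, root="R"):
    terms = {t: t for t in parents}
    return GODag(terms=terms, parents={t: set(p) for t, p in parents.items()},
                 root=root, annotations=annotations or {})


def facts_for(drug_targets):
    pairs = frozenset((d, t) for d, ts in drug_targets.items() for t in ts)
    return build_target_facts(DrugTargetMap(pairs), sorted(drug_targets))


class TestComputeLevels:
    def test_root_is_level_one_and_chain_counts(self):
        dag = make_dag({"R": [], "A": ["R"], "B": ["A"]})
        levels = compute_levels(dag)
        assert levels["R"] == 1 and levels["A"] == 2 and levels["B"] == 3

    def test_diamond_uses_shortest_path(self):
        dag = make_dag({"R": [], "A": ["R"], "C": ["A", "R"]})
        assert compute_levels(dag)["C"] == 2

    def test_unreachable_term_is_error(self):
        # X's only parent link points into a 2-cycle island -> DAG check fires
        with pytest.raises(StructuralError):
            make_dag({"R": [], "X": ["Y"], "Y": ["X"]})

    def test_random_dags_match_shortest_path_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            names = ["R"] + [f"T{i}" for i in range(1, n)]
            parents = {"R": []}
            for i in range(1, n):
                k = int(rng.integers(1, min(i, 3) + 1))
                parents[names[i]] = list(
                    rng.choice(names[:i], size=k, replace=False))
            dag = make_dag(parents)
            levels = compute_levels(dag)
            # oracle: BFS-free recursive shortest path over parents
            def depth(t):
                if t == "R":
                    return 1
                return 1 + min(depth(p) for p in parents[t])
            for t in names:
                assert levels[t] == depth(t)


class TestThresholdFeatures:
    def _setup(self):
        dag = make_dag({"R": [], "t2": ["R"], "t3": ["t2"]},
                       annotations={"P1": {"t3"}, "P2": {"t2"}})
        dt = facts_for({"d1": ["P1", "P2"]})
        return dt, dag, compute_levels(dag)

    def test_min_level_one_keeps_every_annotated_term(self):
        dt, dag, levels = self._setup()
        out = threshold_features(dt, dag, levels, 1)
        assert set(out.feature_ids) == {"t2", "t3"}

    def test_threshold_filters_shallow_terms(self):
        dt, dag, levels = self._setup()
        out = threshold_features(dt, dag, levels, 3)
        assert out.feature_ids == ["t3"]
        assert out.values.tolist() == [[1]]

    def test_cell_counts_supporting_targets(self):
        dag = make_dag({"R": [], "t2": ["R"], "t3": ["t2"]},
                       annotations={"P1": {"t3"}, "P2": {"t3"}})
        dt = facts_for({"d1": ["P1", "P2"]})
        out = threshold_features(dt, dag, compute_levels(dag), 3)
        assert out.values.tolist() == [[2]]

    def test_column_nesting_across_thresholds(self):
        rng = np.random.default_rng(3)
        parents = {"R": []}
        for i in range(1, 15):
            parents[f"T{i}"] = [list(parents)[int(rng.integers(len(parents)))]]
        annotations = {f"P{j}": {f"T{int(rng.integers(1, 15))}"}
                       for j in range(6)}
        dag = make_dag(parents, annotations)
        dt = facts_for({"d1": [f"P{j}" for j in range(6)]})
        levels = compute_levels(dag)
        cols = [set(threshold_features(dt, dag, levels, n).feature_ids)
                for n in (1, 2, 3, 4)]
        for deeper, shallower in zip(cols[1:], cols):
            assert deeper <= shallower


class TestRollupFeatures:
    def test_everything_rolls_to_root_at_level_one(self):
        dag = make_dag({"R": [], "t2": ["R"], "t3": ["t2"]},
                       annotations={"P1": {"t3"}, "P2": {"t2"}, "P3": set()})
        dt = facts_for({"d1": ["P1", "P2", "P3"]})
        out = rollup_features(dt, dag, compute_levels(dag), 1)
        assert out.feature_ids == ["R"]
        assert out.values.tolist() == [[2]]  # only annotated targets count

    def test_deep_term_replaced_by_level_ancestor(self):
        dag = make_dag({"R": [], "a2": ["R"], "a3": ["a2"], "t4": ["a3"],
                        "t5": ["t4"]},
                       annotations={"P1": {"t5"}})
        dt = facts_for({"d1": ["P1"]})
        out = rollup_features(dt, dag, compute_levels(dag), 3)
        assert out.feature_ids == ["a3"]
        assert out.values.tolist() == [[1]]

    def test_per_target_dedup_of_shared_ancestor(self):
        dag = make_dag({"R": [], "a2": ["R"], "t4": ["a2"], "t4b": ["a2"]},
                       annotations={"P1": {"t4", "t4b"}})
        dt = facts_for({"d1": ["P1"]})
        out = rollup_features(dt, dag, compute_levels(dag), 2)
        assert out.feature_ids == ["a2"]
        assert out.values.tolist() == [[1]]

    def test_all_level_ancestors_kept_in_dags(self):
        # deep term with two distinct level-2 ancestors -> both columns
        dag = make_dag({"R": [], "a": ["R"], "b": ["R"], "m": ["a", "b"],
                        "deep": ["m"]},
                       annotations={"P1": {"deep"}})
        dt = facts_for({"d1": ["P1"]})
        out = rollup_features(dt, dag, compute_levels(dag), 2)
        assert set(out.feature_ids) == {"a", "b"}

    def test_rollup_matches_all_paths_enumeration(self):
        """Oracle: enumerate every upward is_a path; the level-N replacement
        set must equal the level-N terms seen on any path."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(5, 25))
            names = ["R"] + [f"T{i}" for i in range(1, n)]
            parents = {"R": []}
            for i in range(1, n):
                k = int(rng.integers(1, min(i, 3) + 1))
                parents[names[i]] = list(
                    rng.choice(names[:i], size=k, replace=False))
            annotations = {"P1": {names[int(rng.integers(1, n))]}}
            dag = make_dag(parents, annotations)
            dt = facts_for({"d1": ["P1"]})
            levels = compute_levels(dag)
            roll = int(rng.integers(1, 5))

            def paths_terms(t, acc):
                acc.add(t)
                for p in parents[t]:
                    paths_terms(p, acc)
                return acc

            (term,) = annotations["P1"]
            reach = paths_terms(term, set())
            lvl = levels[term]
            if lvl < roll:
                expected = set()
            elif lvl == roll:
                expected = {term}
            else:
                expected = {t for t in reach - {term}
                            if levels[t] == roll}
            out = rollup_features(dt, dag, levels, roll)
            got = {f for f, v in zip(out.feature_ids, out.values[0]) if v}
            assert got == expected

    def test_columns_live_at_the_roll_level(self):
        dag = make_dag({"R": [], "a2": ["R"], "t3": ["a2"], "t4": ["t3"]},
                       annotations={"P1": {"t4"}, "P2": {"t3"}})
        dt = facts_for({"d1": ["P1", "P2"]})
        levels = compute_levels(dag)
        out = rollup_features(dt, dag, levels, 3)
        assert all(levels[f] == 3 for f in out.feature_ids)
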