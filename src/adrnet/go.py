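"""GO term levels, level-threshold features, and level-N rollup features.

A term's level is 1 plus the length of the shortest is_a path to the
biological_process root (the root itself is level 1). Two feature
constructions mirror the two GO experiments:

* threshold ("LvN"): keep only terms at level >= N; a drug's cell for a
  term counts how many of its direct targets are annotated with it.
* rollup ("LvN roll up"): replace terms deeper than level N by all their
  level-N ancestors (dropping shallower terms), dedup per target, then
  count supporting targets per drug.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .errors import StructuralError
from .facts import FactsMatrix
from .io import GODag


@dataclass(frozen=True)
class TermLevelTable:
    """Shortest-path depth of every term below the root (root = 1)."""

    levels: dict[str, int]

    def __getitem__(self, go_id: str) -> int:
        return self.levels[go_id]


def compute_levels(dag: GODag) -> TermLevelTable:
    """BFS down from the root along inverted is_a links; root gets level 1."""
    children: dict[str, set[str]] = {t: set() for t in dag.terms}
    for child, ps in dag.parents.items():
        for p in ps:
            children[p].add(child)
    levels = {dag.root: 1}
    queue = deque([dag.root])
    while queue:
        t = queue.popleft()
        for c in children[t]:
            if c not in levels:
                levels[c] = levels[t] + 1
                queue.append(c)
    missing = dag.terms.keys() - levels.keys()
    if missing:
        raise StructuralError(
            f"term(s) unreachable from root {dag.root}: {sorted(missing)}")
    return TermLevelTable(levels)


def _target_annotation_sets(dt: FactsMatrix, dag: GODag) -> dict[str, set[str]]:
    return {t: set(dag.annotations.get(t, ())) for t in dt.feature_ids}


def _count_matrix(dt: FactsMatrix,
                  per_target_terms: dict[str, set[str]]) -> FactsMatrix:
    """Cell (drug, term) = number of the drug's targets carrying the term."""
    features = sorted(set().union(*per_target_terms.values())
                      if per_target_terms else set())
    col = {g: j for j, g in enumerate(features)}
    values = np.zeros((len(dt.drug_ids), len(features)), dtype=np.int64)
    for j, target in enumerate(dt.feature_ids):
        terms = per_target_terms[target]
        if not terms:
            continue
        rows = np.flatnonzero(dt.values[:, j])
        for g in terms:
            values[rows, col[g]] += 1
    return FactsMatrix(list(dt.drug_ids), features, values, feature_kind="go_term")


def threshold_features(dt: FactsMatrix, dag: GODag, levels: TermLevelTable,
                       min_level: int) -> FactsMatrix:
    """Annotation-count features restricted to terms at level >= min_level."""
    if not dt.is_binary:
        raise ValueError("threshold_features expects a binary target matrix")
    if min_level < 1:
        raise ValueError("min_level must be >= 1")
    per_target = {
        t: {g for g in gos if levels[g] >= min_level}
        for t, gos in _target_annotation_sets(dt, dag).items()
    }
    return _count_matrix(dt, per_target)


def rollup_features(dt: FactsMatrix, dag: GODag, levels: TermLevelTable,
                    roll_level: int) -> FactsMatrix:
    """Roll annotations deeper than ``roll_level`` up to level-N ancestors.

    Terms at exactly ``roll_level`` are kept; deeper terms are replaced by
    the set of ALL their ancestors at exactly that level (a DAG term may
    have several); shallower terms are dropped. The replacement set is
    deduplicated per target before counting, so a cell stays interpretable
    as the number of supporting targets.
    """
    if not dt.is_binary:
        raise ValueError("rollup_features expects a binary target matrix")
    if roll_level < 1:
        raise ValueError("roll_level must be >= 1")

    rolled_cache: dict[str, frozenset[str]] = {}

    def rolled(go_id: str) -> frozenset[str]:
        if go_id not in rolled_cache:
            lvl = levels[go_id]
            if lvl < roll_level:
                rolled_cache[go_id] = frozenset()
            elif lvl == roll_level:
                rolled_cache[go_id] = frozenset((go_id,))
            else:
                rolled_cache[go_id] = frozenset(
                    a for a in dag.ancestors(go_id) if levels[a] == roll_level)
        return rolled_cache[go_id]

    per_target = {
        t: set().union(*(rolled(g) for g in gos)) if gos else set()
        for t, gos in _target_annotation_sets(dt, dag).items()
    }
    return _count_matrix(dt, per_target)
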