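"""Convenience wiring of the full prediction pipeline.

These helpers chain the module-level pieces the way the experiments do:
facts + labels from the raw tables, one feature construction per condition
("No Net", "N Stars UP", random-network control, GO threshold/rollup), then
repeated cross-validation and the median summary.
"""

from __future__ import annotations

import numpy as np

from .evaluation import summarize_cv
from .facts import ADRClassLabels, FactsMatrix, build_adr_class_labels, \
    build_target_facts
from .go import compute_levels, rollup_features, threshold_features
from .io import ADRIcdMap, DrugADRMap, DrugTargetMap, GODag, PPINetwork
from .modeling import CVResult, ModelSpec, cross_validate
from .network import expand_one_level, filter_by_stars, randomize_network

CIRCULATORY_RANGE = ("I00", "I99")


def target_facts_and_labels(targets: DrugTargetMap, adrs: DrugADRMap,
                            icd: ADRIcdMap,
                            code_range: tuple[str, str] = CIRCULATORY_RANGE,
                            drug_universe: list[str] | None = None,
                            ) -> tuple[FactsMatrix, ADRClassLabels]:
    """Binary target facts plus the merged ADR-class labels, aligned."""
    if drug_universe is None:
        drug_universe = sorted(targets.drugs)
    dt = build_target_facts(targets, drug_universe)
    labels = build_adr_class_labels(adrs, icd, code_range, drug_universe)
    return dt, labels


def stars_up_features(dt: FactsMatrix, net: PPINetwork,
                      min_stars: int) -> FactsMatrix:
    """The "N Stars UP" condition: filter, then expand one level."""
    return expand_one_level(dt, filter_by_stars(net, min_stars))


def random_net_features(dt: FactsMatrix, net: PPINetwork, min_stars: int,
                        seed: int) -> FactsMatrix:
    """Random-network control: same topology, permuted protein labels."""
    return expand_one_level(dt, randomize_network(filter_by_stars(net, min_stars),
                                                  seed))


def go_features(dt: FactsMatrix, dag: GODag, level: int,
                mode: str = "rollup") -> FactsMatrix:
    """GO condition at one hierarchical level ("threshold" or "rollup")."""
    levels = compute_levels(dag)
    if mode == "threshold":
        return threshold_features(dt, dag, levels, level)
    if mode == "rollup":
        return rollup_features(dt, dag, levels, level)
    raise ValueError(f"unknown GO feature mode {mode!r}")


def evaluate_condition(X: FactsMatrix, y: ADRClassLabels, spec: ModelSpec,
                       folds: int = 10, repeats: int = 3,
                       alpha: float = 0.05, seed: int = 0,
                       ) -> tuple[CVResult, dict[str, float]]:
    """Run repeated CV for one condition; return the result and its medians."""
    result = cross_validate(X, y, spec, folds=folds, repeats=repeats,
                            alpha=alpha, rng=np.random.default_rng(seed))
    return result, summarize_cv(result)
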