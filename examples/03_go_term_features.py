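"""GO hierarchical levels, level-threshold features, and level-N rollup.

Term level = 1 + shortest is_a path to the biological_process root.
Threshold ("LvN") keeps terms at level >= N; rollup replaces terms deeper
than N by their level-N ancestors, deduplicated per target.
"""

from adrnet.facts import build_target_facts
from adrnet.go import compute_levels, rollup_features, threshold_features
from adrnet.io import DrugTargetMap, GODag

dag = GODag(
    terms={t: t for t in ["root", "signaling", "kinase_cascade",
                          "mapk_cascade", "ion_transport"]},
    parents={"root": set(), "signaling": {"root"},
             "kinase_cascade": {"signaling"},
             "mapk_cascade": {"kinase_cascade"},
             "ion_transport": {"root"}},
    root="root",
    annotations={"P1": {"mapk_cascade"}, "P2": {"mapk_cascade"},
                 "P3": {"ion_transport"}})

dt = build_target_facts(
    DrugTargetMap(frozenset({("drug1", p) for p in ("P1", "P2", "P3")})),
    ["drug1"])
levels = compute_levels(dag)
print("levels:", dict(sorted(levels.levels.items(), key=lambda kv: kv[1])))
print("\nthreshold Lv3 (deep terms only, counts = supporting targets):")
print(threshold_features(dt, dag, levels, 3).to_frame())
print("\nrollup Lv2 (deep terms replaced by level-2 ancestors):")
print(rollup_features(dt, dag, levels, 2).to_frame())
# The two P-targets annotated with the level-4 MAPK term collapse onto
# 'signaling' with weight 2; 'ion_transport' keeps its single supporter.
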