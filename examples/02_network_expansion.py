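"""One-level drug-target expansion in a star-rated interaction network.

A drug docking targets A and B, with interactions A-B and B-C, yields
integer weights A=2, B=2 (each seen directly and as the other's neighbour)
and C=1 (neighbour of B only) — the "repeat number" of each protein in the
expansion tree.
"""

from adrnet.facts import build_target_facts
from adrnet.io import DrugTargetMap, PPINetwork
from adrnet.network import expand_one_level, filter_by_stars

dt = build_target_facts(
    DrugTargetMap(frozenset({("drug1", "A"), ("drug1", "B")})), ["drug1"])
net = PPINetwork.from_edges([("A", "B", 4), ("B", "C", 2), ("C", "D", 5)])

print("direct facts:")
print(dt.to_frame(), "\n")
print("expanded (all stars):")
print(expand_one_level(dt, net).to_frame(), "\n")
print("expanded ('4 Stars UP', low-confidence edges dropped):")
print(expand_one_level(dt, filter_by_stars(net, 4)).to_frame())
# D never appears: expansion is one level only, and C itself is reached
# only while the 2-star B-C interaction survives the confidence filter.
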