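"""The full condition comparison: raw facts vs network expansion vs the
random-network control, with repeated cross-validation and a Welch t-test.

Each condition runs 10-fold stratified CV three times; per repeat the
out-of-fold probabilities are pooled into one AUC/ACC/SEN/SPE set and the
median over repeats is reported.
"""

from adrnet import pipeline
from adrnet.evaluation import compare_conditions
from adrnet.modeling import ModelSpec
from adrnet.simulate import SynthConfig, generate

ds = generate(SynthConfig(seed=1))
dt, labels = pipeline.target_facts_and_labels(ds.targets, ds.adrs, ds.icd)
spec = ModelSpec("svm_rbf")

conditions = {
    "No Net": dt,
    "2 Stars UP": pipeline.stars_up_features(dt, ds.ppi, 2),
    "Random Net": pipeline.random_net_features(dt, ds.ppi, 2, seed=1),
}
results = {}
for name, X in conditions.items():
    cv, med = pipeline.evaluate_condition(X, labels, spec, seed=7)
    results[name] = cv
    print(f"{name:<11} " + "  ".join(f"{k}={v:.3f}" for k, v in med.items()))

p = compare_conditions([m["auc"] for m in results["2 Stars UP"].repeat_metrics],
                       [m["auc"] for m in results["No Net"].repeat_metrics])
print(f"\nWelch t-test, '2 Stars UP' vs 'No Net' per-repeat AUCs: p = {p:.4f}")
# Expect the true network to clearly beat the raw facts, and the
# topology-preserving random network to fall in between: the gain comes
# from where the edges are, not from having more feature columns.
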