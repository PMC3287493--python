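# adrnet

Predicting a drug's adverse-reaction (ADR) class — cardiotoxicity as the
case study — from what the drug binds, enriched with where those targets
sit in a protein–protein interaction (PPI) network and what biological
processes annotate them.

`adrnet` is a systems-pharmacology toolkit for researchers who have flat
extracts of drug–target pairs (DrugBank-style), drug–ADR reports
(SIDER-style), a star-graded human PPI table (HAPPI-style) and Gene
Ontology biological-process annotations, and want to train and honestly
evaluate ADR classifiers on top of them. It also ships a synthetic-data
generator with a planted, network-mediated toxicity mechanism, so the whole
pipeline can be exercised and benchmarked without access to any licensed
database.

## The method

Let `DT_nk ∈ {0,1}` record that drug `D_n` docks target `T_k`, and
`DS_nj ∈ {0,1}` that drug `D_n` shows ADR `S_j`. All ADR names mapping to
ICD-10 circulatory-system categories I00–I99 are merged into one class
`S_H`: the label is `DS_nH = 1` iff any in-range `DS_nh = 1`.

Features are built in one of three ways:

* **No Net** — the raw binary `DT` matrix.
* **N Stars UP** — keep PPI edges graded ≥ N confidence stars (1 = weak
  functional association, 5 = high-confidence physical interaction), then
  expand each drug's targets one level: every direct target plus every
  neighbour of a direct target, with the cell value the *repeat number* of
  that protein in the expansion tree (a target seen directly and as a
  neighbour of another target counts 2).
* **GO LvN** — term level = 1 + shortest `is_a` path to the
  biological_process root. Either keep only terms at level ≥ N
  (threshold), or replace deeper terms by their level-N ancestors
  (rollup); cells count a drug's supporting targets.

Each feature column is screened against the label — Fisher's exact test
for binary columns, Wilcoxon rank-sum for integer-weighted ones — keeping
p < 0.05. The majority class is dealt into minority-sized parts; one
probability classifier (RBF-kernel SVM or unpenalized logistic regression)
is trained per part ∪ minority and the ensemble mean probability is used.
Evaluation is stratified 10-fold cross-validation repeated 3 times, with
screening and balancing performed inside each training fold; per repeat the
out-of-fold probabilities are pooled into AUC/ACC/SEN/SPE and medians over
repeats are reported. Conditions are compared with Welch's t-test or
one-way ANOVA, and a topology-preserving random network (protein labels
permuted) serves as the null control for the network contribution.

## Worked example

`examples/05_full_experiment.py` generates a 200-drug dataset whose
toxicity is planted in two PPI modules (a drug is toxic when a target is in
a toxic module or one high-confidence interaction away, with 5% label
noise), then compares three conditions with the SVM model:

```
No Net      auc=0.528  acc=0.570  sen=0.086  spe=0.981
2 Stars UP  auc=0.901  acc=0.850  sen=0.806  spe=0.888
Random Net  auc=0.653  acc=0.625  sen=0.538  spe=0.701

Welch t-test, '2 Stars UP' vs 'No Net' per-repeat AUCs: p = 0.0000
```

Raw target columns are too sparse to reach significance, so the baseline
sits near chance and calls almost nothing toxic (sen 0.09). One-level
expansion pools each module's proteins into shared columns and recovers the
planted mechanism (AUC 0.90). The random network — same topology, shuffled
protein identities — keeps the direct-target information plus some generic
aggregation and lands in between (AUC 0.65), showing the gain comes from
where the real edges are, not from the number of features. The other
examples walk through data generation, expansion weights, GO features and
feature screening individually; each prints what it computes and why.

The same pipeline is available from the shell:

```bash
adrnet simulate --out data/ --seed 1
adrnet run --facts facts.tsv --labels labels.tsv --model svm_rbf \
    --folds 10 --repeats 3 --alpha 0.05 --seed 1 --out results.csv
```

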