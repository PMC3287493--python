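# Methods

## Model and assumptions

The package treats ADR prediction as binary classification of drugs. The
underlying assumption is mechanistic: a drug causes a class of adverse
reactions because it perturbs proteins functionally close to the relevant
physiology — either its direct targets or their immediate interaction
partners. Three feature constructions encode progressively more prior
knowledge:

1. **Raw facts.** `DT` is the binary drug × target incidence matrix; `DS`
   the drug × ADR incidence. The response merges every ADR whose ICD-10
   code falls in a category range (cardiotoxicity: I00–I99) into one label.
   The in-range test uses the 3-character category only — "I08.8" tests as
   I08, a range entry "I30–I52" as its lower bound — because the class
   itself is defined at category level.
2. **One-level network expansion.** Within the PPI network restricted to
   edges with confidence ≥ `min_stars`, each drug's target set grows by its
   targets' neighbours; the cell value is the multiplicity of the protein
   in the expansion tree (no per-branch deduplication: the repeat number is
   the weight of the drug–protein relation at network level). Depth is
   fixed at one hop; multi-hop diffusion is out of scope. Note that with
   undirected edges among direct targets, a target adjacent to another
   target gains weight from both roles — the worked example in
   `examples/02_network_expansion.py` shows the counting.
3. **GO term features.** Term level is 1 + the shortest `is_a` distance to
   the biological_process root. Shortest-path depth was chosen over
   longest-path because it is deterministic, cheap, and consistent with
   the convention that the root is level 1; in a DAG neither choice is
   canonical. Threshold features keep direct annotations at level ≥ N.
   Rollup replaces a deeper term by *all* of its level-N ancestors (any
   single-ancestor choice would be arbitrary in a DAG) and deduplicates per
   target, so a cell remains "number of supporting targets". GO cells are
   integer counts, not binary, which routes them to the rank-sum branch of
   the screen — consistent with the expanded-network data type.

## Feature screening

A column with values in {0,1} is tested with a two-sided Fisher exact test
on the (feature present/absent) × (label 1/0) table; the two-sided p sums
hypergeometric point masses ≤ the observed mass with 1e-7 relative slack
against floating-point near-ties. A zero margin returns p = 1 (degenerate,
logged) rather than erroring, so constant columns are silently never
selected. Non-binary columns use a two-sided Wilcoxon rank-sum test:
exact permutation distribution of the midrank sum for pooled n ≤ 12,
tie-corrected normal approximation (no continuity correction) above.
Features pass at raw p < 0.05; no multiple-testing correction is applied,
matching the screening character of the step (the screen's purpose is
dimensionality reduction inside a resampling loop, not inference).
`alpha ≥ 1` is an explicit no-op screen and keeps p = 1 columns.

Screening runs **inside each training fold**. Selecting once on the full
data would leak validation labels into the feature set and inflate every
metric; a `global_selection` flag exists for compatibility experiments
only.

## Class balancing and classifiers

The majority class is shuffled and dealt into
`max(1, round(|major| / |minor|))` parts differing in size by at most one;
each part plus the full minority class trains one model, and the ensemble
probability is the arithmetic mean of the sub-models' class-1
probabilities — the simplest probability-preserving combination. Note the
rounding rule means a part can exceed the minority size by up to 50% when
the ratio falls just below a half-integer (140 majors over 65 minors give
two parts of 70); parts are "close to" the minority size, not bounded by
it.

Two model families are provided. The SVM uses an RBF kernel with cost 1
and gamma = 1/n_features (the conventional defaults of the reference R
implementation), with sigmoid (Platt) probability calibration fitted on
internal unshuffled stratified folds (`CalibratedClassifierCV`,
`ensemble=False`); the fold count adapts down to the smallest class when a
balanced part is tiny. Logistic regression is unpenalized (C = ∞,
L-BFGS). Cross-validation is stratified (with heavy imbalance, plain
random folds can produce single-class validation sets), 10 folds × 3
repeats by default; the validation fold is never balanced. Per repeat, all
out-of-fold probabilities are pooled into a single ROC — stabler than
fold-level metrics when the minority class is small — and ACC/SEN/SPE use
threshold 0.5 (both families emit calibrated probabilities; no threshold
tuning). Summaries are medians over the repeat-level metrics, and the even
count median is the mean of the middle two. Condition comparisons use
Welch's unequal-variance t-test (condition AUC variances differ) on
per-repeat AUCs, or one-way ANOVA across several conditions; the unit of
replication is stated in the report.

If no feature passes the screen in a fold, the fold predicts the training
prevalence for every validation drug (AUC contribution 0.5), rather than
failing.

## Synthetic data generator

The generator emulates the five inputs at sizes a workstation handles in
seconds: 200 drugs, 300 proteins in 12 modules (2 toxic), 1–5 targets per
drug, within-module edge probability 0.3 with star grades skewed high
(0.03/0.07/0.15/0.30/0.45 for 1–5 stars), between-module probability 0.01
skewed low (0.55/0.25/0.12/0.05/0.03), a GO tree of depth 7 whose three
shallow levels are shared and whose deeper chains are module-specific,
5% label noise, seed 42. Star grades correlate with module co-membership,
so confidence thresholds change how much module structure survives.

The planted mechanism marks a drug toxic when a target lies in a toxic
module, or is adjacent to a toxic-module protein through a **high-
confidence (≥ 4 star) interaction** — i.e. toxicity propagates exactly one
physical-interaction hop, mirroring the pipeline's one-level expansion.
Restricting the hop to high-confidence edges is a deliberate design
choice: with unrestricted adjacency at these sizes, roughly 40% of all
non-toxic-module proteins would border a toxic module through some weak
edge, pushing label prevalence to ~0.85 and erasing the
minority/majority structure the balancing stage exists to handle; the
high-confidence rule keeps prevalence near the direct-hit rate the module
counts imply (~0.45). Noisy labels surface as ADR names: positives get
"Cardiotoxicity_Sim" (mapped to I99), everyone gets a benign ADR mapped
outside I00–I99, so the label travels the same name → ICD-10 join real
data would.

What the generator does *not* emulate: chemical structure, dose,
scale-free degree distributions, annotation incompleteness, and the
many-to-one ADR vocabulary problems of real label data. Passing tests
therefore demonstrate that the pipeline recovers a network-mediated signal
when one exists and reports chance when none does — not that any
particular performance level transfers to DrugBank/SIDER/HAPPI-scale
inputs.

Because each module's private GO chain is linear, threshold and rollup
features one level above the leaves are column-renamings of each other on
generated data; on real ontologies (branching, multi-parent) the two
constructions genuinely differ.

## Numerical and procedural choices

* All randomness flows through seeded `numpy` generators; generated files
  are written in sorted order, so equal seeds give byte-identical outputs
  and equal cross-validation results.
* The random-network null permutes protein labels, preserving the
  adjacency structure and star multiset exactly — the strongest sense of
  "same topology" — while destroying any alignment between neighbourhoods
  and target placement. Degree-preserving rewiring is weaker and
  stochastic in structure; it is intentionally not used.
* AUC is computed by the midrank (Mann–Whitney) formulation: ties count
  half.
* Repeated unordered PPI rows keep the maximum star grade (stars are
  confidence; the maximum is the conservative choice for "N Stars UP"
  filtering); self-interactions are dropped with a logged count.
* ADR names are canonicalized (trim, collapse whitespace, case-fold)
  before any join, since label vocabularies vary in casing.

## Known limitations and behaviour under the null

On label-permuted data with the dense expanded feature matrix, median
validation AUC falls systematically *below* 0.5 (≈ 0.41): when labels
carry no signal, a feature's chance correlation inside the training folds
is exactly compensated by anti-correlation in the held-out fold, so models
fitted to screened features anti-predict. This is a general property of
in-resampling feature selection on null data, not a defect of the
implementation; the package's null check uses the sparse raw fact matrix,
where the conservative Fisher screen selects essentially nothing and
median AUC sits at 0.46–0.49. Users comparing conditions should rely on
the random-network and label-permutation controls rather than on the
absolute AUC of any single run.

Problem sizes throughout the tests and the reproduction script (200 drugs,
300 proteins, 3 × 10-fold CV) are the generator's defaults, chosen so a
full condition grid runs in seconds on one CPU while leaving every
pipeline stage statistically exercised.
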