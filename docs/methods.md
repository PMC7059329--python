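# Methods

## Problem and scope

The package models BCRP (ABCG2) inhibition as a binary classification
problem: a compound is an inhibitor (label 1) or non-inhibitor (label 0)
of the efflux transporter. Labels originate from heterogeneous
experimental read-outs — IC50/EC50, %inhibition at a fixed
concentration, or a qualitative assay outcome — so the pipeline begins
with rule-based curation and ends with diagnostics that ask not only
*whether* a model classifies well but *where* its predictions can be
trusted (applicability domain) and *which* structural features drive
them (permutation importance, fragment enrichment).

## Curation rules and their free parameters

Quantitative thresholds are strict inequalities: IC50/EC50 < 10 μM →
inhibitor, > 50 μM → non-inhibitor; %inhibition measured at exactly
10 μM, > 50% → inhibitor, < 25% → non-inhibitor. Boundary values
(exactly 10, 50 μM; exactly 25%, 50%) fall into the excluded windows,
reading the strict inequalities literally. Measurements at other
concentrations are not used. Replicated IC50/EC50 values are averaged
arithmetically on the μM scale before thresholding; "significant
discrepancy" is operationalized as max/min > 10 (`max_ratio`,
configurable) since no quantitative criterion is standard. When a
compound carries both quantitative and qualitative evidence, the
quantitative rule decides (`quantitative_precedence`, configurable):
thresholds are objective where author judgments are not.

Structure standardization strips a fixed list of common counter-ions and
keeps the remaining component only if it is a single organic fragment;
multi-organic mixtures and structures containing atoms outside the
organic-element set (H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I) are
rejected with a named reason. Structure-identical entries with
conflicting labels are removed entirely; concordant duplicates collapse
to one record. Labeling is a pure function of the records, so curation
is idempotent and deterministic.

## Features and pre-filters

Descriptors are a fixed set of 32 RDKit 2-D descriptors (constitution,
lipophilicity, topology, charge extremes) and the substructure bits are
the 167 MACCS keys. Names are namespaced (`desc:`, `fp:`) so every
downstream stage is agnostic to the feature source; commercial
descriptor sets can be swapped in without code changes, which is also
why absolute benchmark numbers obtained with other feature sets are not
comparable to this package's outputs.

The near-zero-variance filter removes single-valued features and those
with most-common/second-most-common frequency ratio above 19 (= 95/5)
and percent-unique below 10 — the cited filter's documented defaults.
The correlation filter greedily removes, from the worst remaining pair
with |Pearson r| > 0.90, the member with the larger mean absolute
correlation against all remaining features (ties break toward the
earlier column), matching the standard behavior of this filter in the
modeling literature. Both filters are idempotent.

The stratified split assigns floor(class_size × 1/5) compounds per class
to the test set. Floor rounding is the only convention that maps a
1098/1701 dataset to a 879/1361 train and 219/340 test partition at 4:1.
Normalization is z-scoring of continuous features with mean/sd computed
from training rows only (test rows are transformed with training
statistics); bits are untouched. Z-scoring was chosen over range scaling
because it keeps the KDE applicability domain's bandwidth rule
well-behaved; it is configurable at the `fit_normalizer` level.

The simple-descriptor comparison uses eight interpretable properties
(Crippen logP, a Delaney-style logS estimate, H-bond acceptor and donor
counts, rotatable bonds, the Kier molecular flexibility index
κ1·κ2/heavy atoms, aromatic atom and bond counts) with a two-sided
Mann–Whitney U test per property — non-parametric because molecular
property distributions are skewed.

## Simulated-annealing feature selection (rfSA)

One annealing chain runs per resample of a stratified k-fold × repeats
plan (defaults 5 × 5; the desk-scale demonstration configs use 3 × 1).
State is a feature subset; a move toggles 1–3 uniformly chosen features
(moves to the empty subset are rejected); fitness is random-forest
accuracy. The candidate is accepted when its internal accuracy does not
drop, otherwise with probability exp(−Δacc / T_i) under geometric
cooling T_i = T0·α^i (defaults T0 = 0.10, α = 0.99). This is the
canonical Metropolis form consistent with an acceptance rule driven by
the accuracy difference and the iteration number. Two limits serve as
built-in sanity checks: T ≡ ∞ is a random walk; T0 = 0 is greedy hill
climbing with provably non-decreasing internal accuracy.

Internal accuracy is the forest's out-of-bag estimate on the resample's
internal 4/5 — honest (no refit on evaluation data), cheap (one fit per
candidate), and monotone under the greedy limit. External accuracy is
measured on the held-out 1/5 and is never visible to the acceptance
rule; the best iteration is the argmax of the mean external accuracy
across resamples (earliest on ties). Because the search is resampled, a
single final subset must be consolidated: the chain is re-run on the
full training set up to the best iteration under the stored seed. The
recovery benchmark in the test suite additionally inspects the *best
subset* of the trace (the subset achieving the maximum external
accuracy), which is the sharper probe of whether the search finds
planted structure. RF settings (100 trees by default, 30 in the
benchmark) trade variance of the fitness signal against runtime.

## Classifiers, tuning, consensus

All seven methods sit behind `ClassifierSpec`/`train_classifier`:
Gaussian NB, k-NN with inverse-distance vote weighting, L2 logistic
regression, RBF-kernel SVM with probability calibration, stochastic
gradient boosting (subsample 0.5), XGBoost, and a feed-forward network
with the fixed settings ReLU activation, adaptive-learning-rate
optimizer (adam), and a 300-epoch cap. The network is optional in the
registry sense — the pipeline runs with any method subset.

Hyper-parameter search is two-stage: an exhaustive coarse grid, then a
seeded random search confined to the region bracketed by the grid points
adjacent to the grid optimum (numeric parameters sampled uniformly in
the bracket, discrete ones from the bracket set). The objective is mean
fivefold-CV MCC with deterministic folds, so repeated searches are
bit-identical. A sequential model-based surrogate could replace the
random stage behind the same interface; random refinement is the
guaranteed-available baseline and the search-log format is identical.

Class probability ≥ 0.5 classifies as inhibitor; exact ties go to the
positive class. Consensus1 is a majority vote over an odd number of
member label predictions (probability = vote fraction; an even count is
rejected because votes could tie); Consensus2 averages member
probabilities and thresholds. Vote fractions are not calibrated
probabilities, so no AUC is reported for Consensus1.

## Validation machinery

GA, BA and MCC are computed exactly from the confusion matrix with the
inhibitor as the positive class; a zero factor in the MCC denominator
yields 0 (the continuity convention for degenerate matrices). AUC is
rank-based with midrank tie handling and requires both classes. The
per-compound residual is the binary cross entropy −[y·ln p + (1−y)·ln(1−p)]
with natural logarithm (the machine-learning convention; the base only
rescales comparisons) and probabilities clipped to [1e−15, 1−1e−15].
Residual exceedance curves report the fraction of compounds with
residual above each grid point (1 − ECDF, hence monotone
non-increasing) — they discriminate between models that classify
identically but estimate probabilities differently.

Random fivefold CV is stratified by class. Cluster CV builds
complete-linkage clusters on 1 − Tanimoto distance over fingerprint
bits, cuts the dendrogram at 0.7 — so no cluster can contain a pair at
distance above 0.7, the interpretation adopted for the cut parameter —
and deals whole clusters, in seeded random order, to the currently
smallest fold (greedy balancing reproduces near-equal fold sizes while
keeping chemotypes intact). Two all-zero fingerprints have Tanimoto
similarity 1 by convention.

## Applicability domain

PCA retaining ≥ 95% variance followed by a Gaussian KDE with Scott
bandwidth on the projected training compounds; the inside/outside
threshold defaults to the minimum training density, so training coverage
is 100% by construction and a configurable percentile tightens the
domain monotonically. The estimator, bandwidth rule, projection variance
and threshold percentile are all configuration: the choice of a
PCA+KDE realization is this package's own, selected as the cleanest
open implementation of a non-parametric density-based domain that can
flag internal empty regions, which range/leverage approaches cannot.
The domain operates on whatever feature space the model was fitted in
(the selected subset by default).

## Interpretation

Permutation importance: one feature column is shuffled across compounds
(preserving its marginal, breaking its label association), the mean
cross-entropy loss is recomputed, and importance is the loss increase
over the unperturbed baseline, averaged over 10 distinct permutations.
The *difference* (not ratio) form is used so importances are comparable
across models with different baseline losses. Constant features are
exactly zero by the identity-permutation argument. No conservation
property is claimed for the sum of importances, and duplicated
informative features mask each other — a known, tested property of the
method, not a defect.

Fragment enrichment decomposes each compound into ring assemblies
(connected components of the ring-bond subgraph, retaining exocyclic
double-bonded atoms such as carbonyl oxygens, substituents stripped),
bridge assemblies (assemblies in which two rings share ≥ 2 bonds), and
Bemis–Murcko assemblies (the ring-plus-linker scaffold, emitted for
compounds with ≥ 2 ring systems). Presence is binary per compound;
records with identical canonical fragments merge. Information gain is
the base-2 entropy reduction from conditioning the class split on
presence/absence (0·log 0 ≡ 0), and the class frequency
F = (N_fragment,class·N_total)/(N_fragment,total·N_class) satisfies the
exact identity F1·N_inh + F2·N_non = N_total for every present fragment.
Fragments with F1 > F2 rank as inhibitor-associated, F2 > F1 as
non-inhibitor-associated, ties in neither list; statistics are computed
over the whole dataset because per-class counts only make sense against
full class sizes. Misclassification analysis keeps fragments occurring
in ≥ 2 misclassified compounds (pooled across the three kinds, kind
recorded) and reports occurrence ratios 100·count/set-size for training,
test and misclassified sets.

## Synthetic study conditions

`gen_feature_table` draws informative continuous features from
unit-variance normals with class means at ±d/2 — the effect size is a
Cohen's d, making separation analytically computable: a midpoint
threshold on one feature attains Φ(d/2) accuracy (≈ 0.933 at d = 3).
Noise features are N(0, 1) in both classes; fingerprint bits are
Bernoulli with class-dependent rates. `gen_compound_library` plants
ring-system scaffolds at class-dependent inclusion rates, joins multiple
scaffolds with short acyclic linkers (which preserves ring-assembly
identity), and decorates with methyl/chloro/methoxy substituents at
valence-permitted positions — a vocabulary small enough to keep
decomposition outcomes predictable. Ground-truth membership is returned
alongside and is exactly recountable by fragment decomposition.
`gen_activity_records` emits at least one record per curation branch
with expected dispositions riding in a separate table so curation never
sees ground truth. All generators are bit-identical under a fixed seed.

What the generators do *not* emulate: the chemical-space breadth and
source heterogeneity of literature datasets, correlated descriptor
blocks, assay noise structure, and activity cliffs. Passing tests
therefore demonstrate correctness of the machinery and qualitative
behavior (separability regimes, selection recovery, domain coverage),
not real-data performance; absolute benchmark values from commercial
descriptor sets are out of reach by design.

## Problem sizes and numerical choices

Demonstration and test configurations run at desk scale chosen as the
package's defaults: synthetic libraries of 150–400 compounds per class,
annealing benchmarks with 5 informative + 45 noise features on 100+100
compounds, 3-fold × 1-repeat resampling, 200-iteration chains, 30-tree
forests (the per-feature effect size is d = 1.0 there, so that joint
feature information — not any single feature — drives external
accuracy, which is what a selection benchmark should reward). The
annealing benchmark's pass bar (≥ 4/5 informative features in ≥ 80% of
runs) follows from these conditions. Deterministic tie-breaks: earliest
iteration on tied external accuracy; earlier column retained in the
correlation filter; exact 0.5 probability → inhibitor. Degenerate
inputs raise rather than guess: empty feature spaces, single-class
labels, zero-variance features entering normalization or correlation
filtering, fewer clusters than folds, empty residual sets.

## Known limitations

* Descriptor and fingerprint sets differ from commercial tools, so
  absolute metric values are not comparable to benchmarks computed with
  those tools; only machinery and qualitative regimes transfer.
* The annealing search is stochastic; different seeds select different
  (near-equivalent) subsets, and the consolidated full-training-set
  subset can differ from any resample's best subset.
* Probability calibration of the RBF-SVM relies on internal
  cross-validation and is known to be imperfect on small data.
* The KDE applicability domain degrades in high ambient dimension; the
  PCA step mitigates but does not remove this.
* Fragment decomposition fixes one open definition of ring-assembly
  boundaries (exocyclic double bonds retained); other toolkits draw the
  boundary differently and will count differently on carbonyl-bearing
  ring systems.
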