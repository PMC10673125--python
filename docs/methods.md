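# Methods

`metpath` implements a benchmark pipeline for predicting the metabolic
pathway involvement of small molecules from their structure.  A compound's
molfile is turned into a vector of *atom-color* counts; per-category binary
classifiers are trained and scored under repeated stratified
cross-validation; performance is aggregated with category-proportion
weights; and feature importance and presence-odds statistics connect the
predictions back to molecular substructures.  Everything is testable
end-to-end on synthetic molecules, with no database download.

## Molecular graphs

A compound is a heavy-atom graph parsed from an MDL V2000 connection table:
atoms carry an element symbol, a stereo-parity (chirality) code, and flags
for the two ambiguity markers found in KEGG-style molfiles — R-group
placeholders (`R`, `R#`, `R1` …) and repeat-unit markers (`*`).  Explicit
hydrogens are kept as written; implicit hydrogens are never synthesized, so
parsing is deterministic and round-trips exactly.  Charge and isotope
property lines are read and ignored: no downstream feature uses them.
Before featurization every marker atom's element is replaced by carbon —
the placeholder almost always attaches through carbon, and substituting C
keeps the known chemistry in the features instead of exposing models to a
pseudo-element — while the original flags are retained to drive the
ambiguous/non-ambiguous split.  A compound is *ambiguous* if it contains
either marker; such compounds are evaluated on but never trained on.

## Atom colors

An atom color at bond inclusivity *k* is a canonical string for the atom
plus its neighborhood out to *k* bonds.  At k=0 it is the element plus the
chirality code (`C0`, `O0`, `Cl0`, …), so the k=0 counts are the compound's
chemical formula (explicit hydrogens included by default, giving an `H0`
column; a flag restricts k=0 to heavy atoms).  For k ≥ 1 the neighborhood
is expanded as a tree of simple paths — cycles are traversed without
revisiting an atom on the current path — with hydrogens excluded, each
neighbor contributing a parenthesized sub-string that carries its own
recursive color and the connecting bond's order/stereo descriptor.  Sibling
sub-strings are sorted lexicographically and *n* identical siblings
collapse to an `n_`-prefixed sub-string, which makes the serialization
canonical: two rooted neighborhoods receive equal strings exactly when they
are isomorphic as labeled path trees.  The test suite checks this contract
against an independent brute-force oracle (explicit path-tree construction
plus VF2 isomorphism with categorical node/edge attributes).  The string
grammar is this package's own; it is designed for uniqueness, not
readability, and byte-compatibility with other atom-coloring
implementations is out of scope.

Feature matrices concatenate the k = 0..3 count vectors (columns ordered by
level then lexicographically).  Inclusivity stops at 3 because duplicate
feature vectors stop decreasing there while the column count grows
unmanageably.  Value-identical columns are dropped (first in column order
kept, mapping recorded); removing rows during curation can create new
duplicates, so the drop is re-run after curation.

## Dataset assembly

The assembly cascade mirrors how a KEGG-derived benchmark is built:

1. link compounds to pathway leaves and from leaves to the 12 broad
   metabolism categories (the catchall overview branch is excluded); a
   label is true iff the compound links to at least one leaf under the
   category, and compounds with no in-scope links are dropped;
2. merge entries with equivalent molfiles — byte-identity of the
   normalized serialization, or identity of the full k=0..3 color vector —
   keeping the lexicographically smallest ID and the union of labels;
3. featurize (after marker substitution) and drop duplicate columns;
4. filter compounds with fewer than a threshold number of non-hydrogen
   atoms (threshold chosen by the information-content analysis below);
5. apply curation instructions (merge / remove / keep), validated
   all-or-nothing, from a TSV template that the pipeline pre-populates
   with duplicate-feature-vector groups and compounds whose NAME/COMMENT
   metadata matches the macromolecule keywords
   (protein, enzyme, peptide, rna, dna; case-insensitive substrings).

Every step appends `(step, entries_before, entries_after)` to a provenance
ledger, and the test suite asserts the counts chain exactly.

## Information-content filtering

Very small compounds carry too little structure to classify reliably.  To
quantify this, each category's binary random forest is retrained over many
repeats; per repeat a stratified 95/5 split is drawn and only held-out
compounds accrue an outcome (in-sample prediction would understate
misclassification; an `in_sample` switch exists for comparison).  A
compound's overall misclassification rate is the mean over the defined
category rates.  A sliding window of width 5 over non-hydrogen atom count
(window at start *s* covers counts *s*..*s*+4, both ends inclusive)
averages those rates, and the selected threshold is the start of the first
local minimum — strictly below its predecessor and no greater than its
successor, first occurrence winning, 0 if the series never decreases, the
boundary with a warning if it is still falling at the end.  The default
probe model is a 30-tree random forest: small enough that thousands of
(repeat × category) fits stay cheap, stochastic enough that repeated
retraining measures instability, which is what the analysis needs.

## Models and cross-validation

Three families are benchmarked: random forest, gradient-boosted trees
(XGBoost) and a multilayer perceptron.  Tree models consume raw counts;
the MLP consumes features compressed to 10% width by a bottleneck
autoencoder.  With 12 categories and two training datasets (full and
non-ambiguous) the default enumeration is 72 classifiers.  Each task is
scored over independently drawn stratified 95/5 train/test splits (fresh
random subsamples per iteration, not a partitioned k-fold).  Training on
the full dataset, a fold's test set is scored three ways — whole fold,
ambiguous members, non-ambiguous members; training on the non-ambiguous
subset, the fold is scored plus the fixed entire ambiguous subset.  The
model is fit once per fold and each partition is scored exactly once.

Hyperparameter search spaces follow the published tuning table (XGBoost:
alpha, booster, eta, lambda, max depth 6–9, min split loss, positive-class
scale, subsample; random forest: ccp-alpha, class weight, criterion; MLP:
activation, Adam betas/epsilon, jitter, weight decay, learning rate, layer
count, class weights, augmentation size).  The search backend is seeded
random search — 25 trials by default — scored by MCC on a single stratified
80/20 inner split of the training fold.  Table-specified options without a
scikit-learn equivalent are mapped: `selu` is unavailable (space uses relu
/ tanh / logistic), and the separate bias/kernel regularization types
collapse onto the single l2 `alpha`.  Class weights for the MLP, which has
no native sample weighting, are implemented as weighted resampling;
jitter and train-set augmentation add Gaussian-perturbed copies.
MLP capacity defaults (two 128-unit layers, Adam at 3e-4, up to 2000
iterations) are sized so the family can actually exploit a cleanly
separable desk-scale task rather than being capacity-limited.

### Autoencoder

The compressor is a bottleneck MLP regressor whose encoder half is
extracted after training; the encoded width is `floor(0.10 × n_features)`
(14,656 columns → 1465).  Inputs are centered but *not* variance-rescaled:
compression operates in raw count units.  This matters — count matrices
contain hundreds of rare colors that appear in one or two compounds, and
unit-variance scaling inflates each of them to the same weight as an
informative column, squandering the 10% latent budget on noise.  With
centering only, the reconstruction objective concentrates capacity on the
columns that genuinely vary, and on separable synthetic data the encoded
pipeline matches the raw one (MCC ≥ 0.95 per fold) as the tests verify.
The default is a single linear bottleneck (deeper, nonlinear stacks are
configurable): at desk scale a linear autoencoder converges to the
principal subspace, which the tests check against a truncated-SVD oracle
on rank-limited data.

## Evaluation

Per test partition the confusion counts yield accuracy, precision, recall,
F1, MCC and unit-normalized MCC ((MCC+1)/2).  Precision/recall/F1 are
flagged invalid when their denominator is zero and invalid scores are
excluded from every aggregate; MCC uses the zero-factor convention (value
0, valid), so MCC and accuracy are always valid.  Aggregates weight each
(category, fold) score by the category's proportion of the dataset; the
weighted SD is the frequency-weighted population form
√(Σwᵢ(xᵢ−x̄w)²/Σwᵢ) — the sample-style correction is a documented
alternative that was not chosen.  Raw tree importances (library default,
gain-based) are divided by each fold's maximum and summarized per feature
by the median across folds, the median because per-feature importance
distributions are strongly skewed.  Feature–label association uses
presence odds: among positives, compounds containing a color at least once
over those lacking it; likewise among negatives; their quotient is the
odds ratio, infinite when the negative odds are zero (serialized as the
literal `inf` in TSV).

## Synthetic benchmark generator

The generator emulates the *shape* of the real dataset, not its chemistry:
1200 compounds by default, 12 categories with positive proportions between
0.03 and 0.25, an ambiguous fraction near 0.06, and a lognormal size
spectrum over 6–40 heavy atoms.  Molecules are random spanning trees with
occasional ring-closing edges, degree-capped per element so graphs look
molecule-like; no valence model is enforced because the pipeline consumes
graphs, not chemistry.  Each category owns a planted motif — a rare
element (F, Cl, Br, I, Si, Se, B, As, Ge, Sn, Sb, Te) never sampled into
the background, carried on a short common-element scaffold with a
category-specific bond-order pattern.  The scaffold emulates how real
informative substructures recur in a chemical context and gives the
compressed representation a correlated block to retain rather than a
single isolated column.

Labels: compounds at or above the signal size threshold (default 8) carry
label *c* exactly when motif *c* was planted (optionally XOR-ed with label
noise); below the threshold labels are drawn independently of structure.
Two sizing choices make the threshold recoverable by the sliding-window
analysis rather than an artifact of binning.  First, the target size is
sampled before planting and the base graph shrunk accordingly, so planted
compounds land on their sampled size and the size histogram has no hole at
the threshold (an empty bin makes adjacent windows value-identical, and
the first-local-minimum tie rule would then stop early).  Second, the
minimum size is 6, one window short of the default threshold, so every
non-empty window already mixes signal-bearing compounds and the window
series is a monotone ramp down to the threshold: a wide pure-noise size
region is flat in expectation, where sampling fluctuation alone would
create spurious early minima about half the time.  These are properties of
the estimator one should equally expect on real data — a flat stretch of
the misclassification curve makes "first local minimum" ill-determined.

The generator also seeds the bookkeeping hazards the pipeline must handle:
byte-identical duplicate molfiles whose clones carry one extra label (so
merging must union labels), atom-permuted duplicates (identical color
vectors, different bytes — merged only under color-vector equivalence),
metadata rows containing macromolecule keywords, and links to an
out-of-scope overview leaf.  Same seed, byte-identical fixtures.

What the generator does **not** emulate: valence and aromaticity, real
elemental composition statistics, correlated category co-occurrence,
hierarchy depth beyond leaf→branch, or the long right tail of metabolite
sizes.  Passing tests therefore demonstrate that the pipeline's machinery
— parsing, canonicalization, dedup/merging, filtering, CV protocol,
aggregation — behaves correctly, and that planted signal of realistic
sparsity is recovered; they say nothing about attainable accuracy on real
KEGG data, whose headline numbers require the real snapshot and are out of
scope here.

## Problem sizes used in the tests

The suite runs the threshold-recovery study at 1000 compounds × 20
misclassification repeats × 20 seeded runs; the null and separable limits
on a 400-compound task set (200 shuffled-label folds for the null); the
canonicalizer oracle on 500 random graphs of up to 12 atoms; and the
orchestration smoke run at 60 compounds.  These sizes were chosen so the
statistical claims have adequate power while a full run of the suite stays
within a coffee break on one core.

## Known limitations

- The canonical color grammar is internally consistent but not
  interchangeable with other atom-coloring tools.
- Bayesian optimization is not bundled; tuning is seeded random search
  behind the same interface.
- The MLP family approximates the published training extras (jitter,
  augmentation, class weights) within scikit-learn's MLP; exotic
  activations and per-layer regularization types are not reproduced.
- Odds ratios are reported without confidence intervals; zero cells map to
  ∞ rather than to a continuity-corrected estimate, matching the reporting
  convention the pipeline follows.
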