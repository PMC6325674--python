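# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `toxsa`. It is the design record for maintainers; the
README covers usage.

## Problem setting

Early drug discovery needs fast filters that flag candidate molecules which
are hard to synthesize or likely to be toxic before any expensive assay.
`toxsa` estimates both properties directly from a binary molecular
fingerprint, with no physicochemical descriptors:

* **SAscore** — synthetic accessibility on a 1–10 scale (1 = easy to make,
  10 = very difficult), predicted by regression.
* **Tox-score** — a probability-like toxicity score in [0, 1]
  (0 = likely non-toxic, 1 = likely toxic), predicted by classification,
  with a tunable decision cutoff (default 0.58).

A convention used throughout: the *positive* class of every classification
metric is **non-toxic** (encoded 0), toxic is encoded 1. TP therefore counts
non-toxic molecules recognized as non-toxic, and FPR is the fraction of
toxic molecules passed through as non-toxic.

## Fingerprints and curation (`chem_io`)

Molecules are encoded as 1024-bit hashed linear-path fingerprints: every
atom–bond path of 1–7 bonds is enumerated and hashed onto the bit vector
(RDKit `RDKFingerprint`, `maxPath=7`, `fpSize=1024`). Any deterministic
path-hashing of this family is equivalent for the models; the exact scheme
id (`rdkit-linear-path/1024bit/maxpath7/v1`) is stored in model metadata and
checked at prediction time, so a model can never silently score fingerprints
hashed under a different scheme. The hashing is a pure function of the
molecular graph, hence invariant to SMILES re-spelling.

Curation mirrors standard non-redundant library construction:

* molecular-weight window 100–600 Da, both bounds inclusive (the source
  range is stated without a bracket convention; inclusive is the weaker and
  therefore safer reading);
* greedy redundancy removal at Tanimoto coefficient 0.8: records are
  scanned in input order and kept iff all previously kept records are less
  similar than the cutoff. Input order is the deterministic tie-break;
  survivors are pairwise below the threshold by construction.
* Tanimoto of two all-zero fingerprints is defined as 1.0, so duplicate
  empty fingerprints are treated as redundant rather than unique.

## Resampling (`resampler`)

SAscore labels of drug-like libraries are heavily skewed (roughly 28% of
molecules fall in the 2–3 range). The balancing plan acts per unit score
range: [1,2) duplicated ×2; [2,5) uniformly undersampled to 90,000 without
replacement; [5,6) unchanged; [6,7), [7,8), [8,9), [9,10] duplicated ×2,
×5, ×20, ×100. Bin edges are half-open except the final bin, which includes
10.0. Duplication is exact whole-copy (no jitter or interpolated minority
samples), so the multiset of distinct fingerprints per bin is preserved;
the undersample cap is configurable so desk-scale datasets can exercise the
same code path. The result is always shuffled with the caller's seed.

## SAscore model (`dbn_sascore`)

A Deep Belief Network: visible layer = 1024 fingerprint bits, hidden layers
of 512, 128 and 32 sigmoid units, built as a stack of Restricted Boltzmann
Machines.

**Pretraining.** Each RBM is trained by contrastive divergence (CD-k,
default k = 1): hidden probabilities from the data (positive phase), a
sampled hidden state, then a mean-field visible reconstruction and its
hidden probabilities (negative phase). Upper layers train on the mean-field
hidden probabilities of the layer below — probabilities, not sampled
states, which lowers gradient variance at small sample sizes. The bottom
layer demands strictly binary input; upper layers accept [0, 1].
Per-epoch mean squared reconstruction error is recorded in model metadata.

**Fine-tuning.** A linear head on the top hidden layer is trained jointly
with all layers by mini-batch SGD on MSE with an L2 penalty on weights
(never biases; default strength 1e-4). The learning rate follows
inverse-time decay `lr_t = lr0 / (1 + decay·t)` over update steps — the
published recipe names the constants (lr0 = 0.01, decay = 1e-4, batch =
100, 20 pretraining epochs, 1000 fine-tuning epochs) but not the decay
formula; inverse-time is the standard choice for a named "decay rate".
A `head_only` switch freezes the pretrained layers for comparison.
Predictions are deterministic mean-field forward passes clamped to [1, 10].

**Initialization and randomness.** Weights N(0, 0.01), biases zero; weight
init, Gibbs sampling and batch order all draw from one seeded PCG64 stream,
so training is exactly reproducible. The fine-tuning stream is derived from
`seed + 1` to keep it distinct from pretraining.

Gradient correctness is verified against central finite differences on an
8-visible/4-hidden toy (tolerance 1e-4 with L2 = 0).

## Tox-score model (`et_toxscore`)

Extremely Randomized Trees: 500 trees grown on the *full* training sample
(no bootstrap), at each node 10 = log2(1024) candidate features drawn
without replacement and random cut-points, best candidate by Gini impurity
decrease; depth ≤ 70, minimum 3 samples to create and 19 to split a node;
the minimum impurity decrease to split ("Gini threshold") defaults to 0 and
is exposed in the config. The stated reading of "minimum numbers of 3 and
19 samples to create and split a leaf node" is min_samples_leaf = 3,
min_samples_split = 19.

Leaves store class fractions rather than hard votes, so the Tox-score —
the mean over trees of the leaf's toxic fraction — is a smooth probability;
with pure leaves and an 0.5 cutoff this reduces exactly to per-tree
majority voting (verified by test). Tree growing is delegated to
scikit-learn's `ExtraTreesClassifier`, whose semantics under
`bootstrap=False` match these semantics; predictions are computed
tree-by-tree so forests can also be assembled from individually trained
trees (used by the hand-built-forest oracle tests). One subtlety: trees
inside an sklearn ensemble see label-encoded classes, so the model stores
the encoder mapping and resolves the toxic column through it.

Classification: non-toxic iff Tox-score ≤ threshold, boundary inclusive —
the direction follows from positive = non-toxic. Default threshold 0.58.

## Evaluation (`metrics_eval`)

ACC, TPR, FPR, MCC, MSE and PCC are implemented from their definitions.
Conventions for degenerate inputs: a zero denominator in ACC/TPR/FPR or a
constant input to PCC returns NaN (logged) rather than raising; MCC with
any zero marginal sum returns 0, the common convention.

The ROC sweep uses every distinct score as a threshold (ties grouped),
yielding points from (0,0) to (1,1); AUC is the trapezoidal area, which
equals the Mann–Whitney concordance statistic with ties counted ½
(property-tested to 1e-9). Threshold selection scans a regular grid
(default step 0.01, matching the two-decimal reported optimum) and returns
the smallest threshold attaining the maximal MCC.

Cross-validation is stratified for binary labels (per-fold class ratios
within one instance) and plain for regression; folds partition the index
set with sizes differing by at most one, and out-of-fold predictions are
collected for pooled threshold selection — the shipped training workflow
selects the cutoff on pooled out-of-fold scores, then refits on all data.
Grid search ranks configurations by mean out-of-fold MCC, ties broken by
mean AUC, then grid order.

## Fragment comparison (`fragment_compare`)

Fragment frequency = occurrences of a fragment key / total fragment
occurrences in the set (not the fraction of molecules containing it; a
`fraction-of-molecules` alternative can be obtained by deduplicating keys
per molecule before counting). Two tables are aligned on the union of keys
(absent → 0), correlated (PCC), and fitted with a regression line; the
signed residual of the toxic frequency about the line ranks enrichment:
negative = enriched in the non-toxic set, positive = enriched in the toxic
set.

The default line is the standardized-major-axis fit (slope σ_y/σ_x through
the means, always positive). This choice is deliberate: it treats the two
sets symmetrically, so swapping their roles rescales every residual by
−σ_x/σ_y — the enrichment sign is exactly antisymmetric, which ordinary
least squares cannot guarantee for |PCC| < 1 (points between the two OLS
lines would change sign). OLS of toxic on non-toxic frequency is available
via `line="ols"` for comparison with scatter-plot figures drawn that way.
For the highly correlated profiles this analysis targets (PCC ≈ 0.98) the
two lines nearly coincide.

## Synthetic data (`synth_fixtures`)

The generators define the study conditions for all recovery tests.

**Toxicity generator.** Balanced classes (`n_per_class` each); background
bits iid Bernoulli(0.1); `n_informative_bits` positions (default 8,
recorded in metadata) set equal to the class label and then flipped with
probability `flip_noise`. At flip 0 the classes are perfectly separable on
one bit; at flip 0.5 the informative bits carry zero mutual information
with the class (tested empirically). This emulates what a fingerprint
toxicity classifier actually exploits — recurring toxicophore-like bit
patterns — but *not* the correlated substructure bits, variable molecule
sizes or class imbalance of real libraries, so passing recovery tests shows
the estimator works, not that real-data accuracy will match.

**SAscore generator.** A unit bin is drawn from `bin_weights` — default
(0.09, 0.283, 0.27, 0.15, 0.09, 0.06, 0.03, 0.017, 0.01) over [1,2)…[9,10],
placing the documented 28.3% on [2,3) with a decreasing tail above 5 — and
the score drawn uniformly within it. The fingerprint sets
`count = offset + slope·(score − 1)` random bits (offset = 2% of the
vector, slope chosen so counts stay ≤ 80% of the vector), the score is
quantized onto the grid this integer map induces so the noiseless label is
*exactly* recoverable from the bit count, and the recorded label adds
Gaussian noise (default σ = 0.5) clamped to [1, 10]. The encoding makes
signal recovery well-defined; it does not mimic the structured, correlated
bit patterns of real molecules.

## Problem sizes

Recovery checks run at desk scale by design: the toxicity recovery uses
400 molecules × 64 bits with 100 trees; the DBN recovery uses 2000
molecules × 1024 bits with hidden layers (256, 64, 16), 5 pretraining and
100 fine-tuning epochs (an 80/20 split); brute-force metric and curation
oracles use 50–200 random instances. With those sizes the whole suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* No GPU path; the DBN is plain NumPy and sized accordingly.
* No salt stripping, tautomer normalization or 3D handling; a molecule is
  its SMILES-derived graph.
* Reference SAscore labels and fragment decompositions are consumed as
  inputs; this package does not compute them.
* Headline accuracies on the curated public compound collections the
  method was originally demonstrated on require those external databases
  and are out of scope for the offline test harness.
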