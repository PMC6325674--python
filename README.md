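# toxsa

Synthetic-accessibility and toxicity prediction for small organic molecules,
directly from binary molecular fingerprints.

Early-stage drug discovery pipelines need cheap filters that discard
candidate compounds which are impractical to synthesize or likely to be
toxic before any assay is run. `toxsa` provides two such filters for
medicinal and computational chemists, plus the machinery around them:

* **SAscore** — synthetic accessibility on the 1–10 scale (1 = easy to
  make, 10 = very difficult), regressed from a 1024-bit hashed linear-path
  fingerprint by a **Deep Belief Network**: stacked Restricted Boltzmann
  Machines (1024 → 512 → 128 → 32) pretrained by contrastive divergence,
  then fine-tuned end-to-end with a linear regression head,

      ŷ = clamp₍₁,₁₀₎( w·h₃(x) + b ),   MSE = (1/N) Σᵢ (ŷᵢ − yᵢ)²

* **Tox-score** — toxicity in [0, 1] (0 = likely non-toxic), the mean over
  an **Extremely Randomized Trees** ensemble (500 trees, full-sample
  growth, log₂ 1024 = 10 random features per node) of each leaf's toxic
  class fraction. A molecule is called non-toxic iff its Tox-score ≤ τ
  (default τ = 0.58, chosen by maximizing the Matthews correlation
  coefficient over a threshold grid).

Throughout, the positive class is **non-toxic**: TP counts non-toxic
molecules recognized as non-toxic, and

    ACC = (TP+TN)/(TP+FP+TN+FN),  TPR = TP/(TP+FN),  FPR = FP/(FP+TN),
    MCC = (TN·TP − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Supporting modules: `.smi` parsing and fingerprinting (`chem_io`), dataset
curation (100–600 Da weight window, greedy Tanimoto-0.8 redundancy
removal), bin-wise over/under-sampling of skewed SAscore sets
(`resampler`), ROC/AUC/MCC evaluation with stratified cross-validation and
grid search (`metrics_eval`), fragment-composition comparison between
non-toxic and toxic sets (`fragment_compare`), and synthetic dataset
generators so everything is testable offline (`synth_fixtures`).
See `docs/methods.md` for the models and numerical conventions.

## Worked example

Train a toxicity classifier on a synthetic fixture and score molecules
(every command is deterministic given `--seed`):

```sh
toxsa simulate --kind tox --n 400 --n-bits 1024 --flip-noise 0.1 \
      --seed 42 --out tox_train.csv
toxsa train-tox --fingerprints tox_train.csv --out-model tox_model.joblib \
      --report cv.csv --folds 5 --trees 100 --seed 42
toxsa predict --fingerprints tox_train.csv --tox-model tox_model.joblib \
      --out predictions.csv
```

The training log reports the cross-validated performance and the selected
cutoff:

```
toxsa INFO: seed=42, 400 labeled molecules, 1024 bits
toxsa INFO: CV: AUC 0.998, MCC 0.980 at selected threshold 0.49
```

i.e. on this noisy but separable fixture the out-of-fold ROC area is 0.998
and a Tox-score cutoff of 0.49 maximizes the MCC at 0.980. `cv.csv` holds
the per-fold breakdown (first fold: ACC 0.94, TPR 1.0, FPR 0.125,
MCC 0.88, AUC 1.0) and `predictions.csv` one row per molecule:

```
id,toxscore,tox_label
synth-tox-0,0.7552045772854599,1
synth-tox-1,0.3503445557710264,0
synth-tox-2,0.6573894185879479,1
```

`tox_label` is 1 (toxic) when the Tox-score exceeds the cutoff embedded in
the model. With real molecules, replace `--fingerprints` by `--smiles
molecules.smi --labels labels.csv` (columns `id,tox` with 1 = toxic, or
`id,sascore`); `toxsa train-sa` trains the SAscore regressor the same way,
and `toxsa fragments non_toxic.tsv toxic.tsv --out comparison.csv` runs
the fragment-composition analysis.

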