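# afscreen

Screening for **atrial fibrillation (AF)** from single-lead ECGs using only
the distribution of **R–R intervals (RRi)** — the times between successive
heartbeats.  AF's hallmark is an irregular ventricular response: the RRi
distribution of an AF patient is visibly more spread than in sinus rhythm.
`afscreen` exploits exactly this one feature, to its maximum, with a
*distributional* support vector machine that compares whole empirical
distributions rather than fixed-size feature vectors.  The package is aimed
at researchers evaluating screening classifiers across heterogeneous ECG
corpora (different record lengths, sensors and noise levels).

## The method

For patient *n* with R-peaks at sample indices *t₁ < t₂ < …*, the feature
vector is the mean-normalized interval collection

```
x⁽ⁿ⁾ᵢ = δ⁽ⁿ⁾ᵢ / ( (1/dₙ) Σⱼ δ⁽ⁿ⁾ⱼ ),    δ⁽ⁿ⁾ᵢ = t⁽ⁿ⁾ᵢ₊₁ − t⁽ⁿ⁾ᵢ ,
```

unitless, with mean 1, and of *patient-dependent* length dₙ.  The xᵢ are
treated as i.i.d. draws from the patient's RRi distribution P⁽ⁿ⁾, which is
represented by its empirical kernel mean embedding

```
μ⁽ⁿ⁾ = (1/dₙ) Σᵢ k(·, x⁽ⁿ⁾ᵢ),      k(z₁, z₂) = exp[ −(z₁−z₂)² / σ² ].
```

Two patients are compared through the squared RKHS distance, computable in
closed form from three kernel double-sums,

```
‖μ⁽ⁿ⁾ − μ⁽ᵐ⁾‖² = (1/dₙ²) Σᵢⱼ k(xᵢ⁽ⁿ⁾,xⱼ⁽ⁿ⁾) + (1/dₘ²) Σᵢⱼ k(xᵢ⁽ᵐ⁾,xⱼ⁽ᵐ⁾)
                 − (2/dₙdₘ) Σᵢⱼ k(xᵢ⁽ⁿ⁾,xⱼ⁽ᵐ⁾),
```

and a second-level Gaussian kernel `K(μ⁽ⁿ⁾,μ⁽ᵐ⁾) = exp[−‖μ⁽ⁿ⁾−μ⁽ᵐ⁾‖² / 2γ²]`
feeds a soft-margin SVM with class-dependent misclassification costs
(`cost_AF / cost_noAF ≥ 1` trades specificity for the screening-critical
sensitivity).  Because the embedding averages over however many intervals a
record provides, the classifier accepts inputs of **any length**, at training
and at inference — the property that lets one model move between corpora
with 10 s and 60 s recordings.

Hyperparameters (σ, γ, cost ratio) are tuned by stratified 5-fold
cross-validation maximizing mean held-out AUROC over a grid.

## Worked example

```python
import numpy as np
from afscreen import (ClassModel, DistributionalSVC, GridSpec, cv_grid_search,
                      evaluate_model, gen_rri)

# two synthetic cohorts: regular sinus rhythm vs irregular AF intervals
noaf = ClassModel(label=-1, cv=0.05, length_range=(20, 60))
af = ClassModel(label=+1, cv=0.30, length_range=(20, 60))
train = gen_rri(noaf, 100, seed=1) + gen_rri(af, 100, seed=2)
test = gen_rri(noaf, 100, seed=3) + gen_rri(af, 100, seed=4)

grid = GridSpec(sigmas=(0.05, 0.1, 0.5), gammas=(0.5, 1.0),
                cost_ratios=(1.0, 4.0), n_folds=5, seed=0)
params, w, table = cv_grid_search(train, grid)
print(f"selected sigma={params.sigma} gamma={params.gamma} cost_ratio={w}")

model = DistributionalSVC(sigma=params.sigma, gamma=params.gamma, cost_ratio=w)
model.fit(train, [v.binary_label for v in train])

report, confusion = evaluate_model(model, test)
print(f"accuracy={report.accuracy:.3f} F1={report.f1:.3f} "
      f"sensitivity={report.sensitivity:.3f} specificity={report.specificity:.3f} "
      f"AUROC={report.auroc:.3f}")

# scoring works at any record length, even ones never seen in training
short = np.random.default_rng(5).lognormal(sigma=0.05, size=7)
print("score of a 7-interval query:", model.decision_function([short / short.mean()])[0].round(3))
```

Output:

```
selected sigma=0.05 gamma=0.5 cost_ratio=1.0
accuracy=1.000 F1=1.000 sensitivity=1.000 specificity=1.000 AUROC=1.000
score of a 7-interval query: -1.287
```

The two synthetic cohorts differ only in interval dispersion (coefficient of
variation 0.05 vs 0.30), which the distributional kernel separates
perfectly; the final line shows a regular 7-interval query scored by a model
trained on 20–60-interval records — the negative score means "noAF".
Overlapping dispersions (e.g. sinus arrhythmia, generated by
`gen_modulated_rri`) produce the intermediate metric values typical of real
corpora.

## Command line

Every stage is also a CLI step operating on a plain CSV of extracted RRi
vectors, so kernel/SVM stages never need the raw signals:

```bash
afscreen simulate --out pool.csv --preset easy --n-total 200 --seed 5
afscreen split    --rri pool.csv --out-prefix sp --seed 2
afscreen tune     --rri trainval.csv --out best.json --table-out cv.csv
afscreen train    --rri trainval.csv --params best.json --out model.json
afscreen evaluate --model model.json --rri sp.test.csv --out metrics.json
afscreen xds      --manifest manifest.yaml --out cross.csv
afscreen learning-curve --pool pool.csv --test sp.test.csv --out curve.csv
```

`afscreen extract` turns raw recordings (WFDB records or CSV traces) into
the RRi CSV via a pluggable peak-detector registry; a simple built-in
threshold detector ships with the package, and adapters for published
detectors (e.g. XQRS) activate when their backend package is installed.

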