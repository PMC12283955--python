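# Methods

## Model

Each patient contributes a variable-length collection of R–R intervals,
mean-normalized so the feature vector is unitless with mean 1.  The
normalization is scale-invariant, so whether intervals are measured in
sample indices or seconds is immaterial; the test suite demonstrates this
rather than assuming it.  Intervals within a patient are modeled as i.i.d.
draws from that patient's RRi distribution.  This deliberately discards
serial structure (an AV-node process is not modeled): the classifier sees
only the *distribution* of intervals, whose dispersion is the robust AF
marker being exploited.

The distribution is represented by its empirical kernel mean embedding with
a Gaussian base kernel, and patients are compared through the squared RKHS
distance of their embeddings — the biased V-statistic form of the squared
maximum mean discrepancy, expanded into three kernel double-sums including
the i=j self-terms.  Embeddings are never materialized as functions: the
double-sum expansion is the only finite computation, and all code routes
through it.  A second Gaussian kernel on this distance feeds a weighted
soft-margin SVM.

Two notational conventions are preserved exactly as used: the base kernel
is `exp[−(z₁−z₂)²/σ²]` (no factor 2 in the denominator) while the
second-level kernel is `exp[−dist²/(2γ²)]` (factor 2 present).  Since both
bandwidths are free, grid-searched hyperparameters the asymmetry is
harmless, but "fixing" it silently would change the meaning of reported
(σ, γ) values.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| σ | base-kernel bandwidth (unitless) | grid 0.01–1 | normalized RRi values cluster near 1, so sub-unit bandwidths resolve the dispersion differences that separate the classes |
| γ | second-level bandwidth | grid 0.25–2 | squared embedding distances live in [0, 2] for the Gaussian base kernel |
| cost ratio w | cost_AF / cost_noAF | grid {1, 2, 4, 8, 16} | one degree of freedom for class weighting; w > 1 buys sensitivity, the screening-critical metric |
| C | base misclassification cost | 1 | only the products C·w and C matter; the grid varies the ratio |
| min_peaks | admission filter | per-source (sph 8, diagnostick 51, cinc 20, synthetic 2) | records with too few beats carry too little distributional information; "fewer than" is strict, so a record exactly at the threshold is retained |
| solver tol | SVC stopping tolerance | 1e-6 | convergence failure raises; it is never returned as a silent partial model |

Hyperparameters are selected by stratified 5-fold cross-validation on the
merged training and validation sets, maximizing mean held-out AUROC; ties
resolve to the cell earlier in (σ, γ, w) grid order, which is deterministic
and documented.  The reported operating point is the raw decision boundary
(score 0) — no threshold tuning is performed — and a score of exactly 0
classifies as AF, since screening prefers false positives over false
negatives.  The squared-distance matrix is computed once per σ and shared
across γ, folds and cost ratios through the self-term cache; without this
the grid search recomputes quadratically many double-sums.  The cache is
keyed by the identity of the underlying sample array rather than by patient
id, because ids can legitimately collide across data sources and a
collision would silently corrupt distances.

## Data handling

Rhythm labels are collapsed to the binary task per source scheme: CinC-style
(Normal/Other → noAF, AF → AF, Noisy → discarded), SPH-style (atrial
fibrillation → AF, every other rhythm including atrial flutter → noAF),
DiagnoStick-style (AF/noAF, Unknown → discarded), or passthrough.  Discarded
items are counted and reportable, never silently dropped; retained +
discarded equals the input count at every stage, including the minimum-peak
filter.  Stratified splits (default 60/20/20) stratify on the *original*
labels before collapsing, use largest-remainder rounding per stratum with
ties toward the earlier split and strata processed in sorted name order —
deterministic across runs and platforms for a fixed seed.  Noisy/Unknown
discards happen before splitting.

Peak detection is a registry of backends.  The built-in `threshold` detector
(band-pass 5–15 Hz, squared energy, 150 ms moving average, 30% adaptive
threshold, 200 ms refractory period, peak refined to the local raw maximum)
exists so the whole pipeline runs with no optional dependencies; it is a
simple Pan–Tompkins-style detector adequate for clean traces, not a
validated clinical QRS detector.  Adapters for published detectors (XQRS
and the neurokit2 family) import their backend lazily and raise a clear
error when it is absent.  Duplicate indices returned by a backend are
removed with a warning before interval computation, guaranteeing strictly
positive intervals; no ectopic-beat or outlier rejection is applied beyond
that — robustness is delegated to the distributional representation.

The WFDB reader supports the header + format-16 signal layout that
single-lead ECG corpora ship in, returns one channel (default the first),
and attaches labels from an adjacent `REFERENCE.csv` when present.

## Synthetic data

The generator encodes the single contrast the classifier relies on: noAF
intervals with a low coefficient of variation (preset 0.05) versus AF
intervals with a high one (preset 0.30), lognormal by default (positive,
right-skewed; moment-matched so the requested CV is the CV of the raw
interval law), gamma as an alternative.  Record lengths are uniform on
20–60 intervals unless stated.  The "hard" preset adds a sinus-arrhythmia
surrogate — sinusoidally modulated, serially correlated intervals whose
dispersion approaches AF levels — for tests that must not separate
perfectly.  What passing on this data shows: the kernel, the SVM and the
protocol correctly recover a known distributional contrast at realistic
sample sizes.  What it does not show: performance under real ECG morphology,
sensor noise, detector failure modes, or rhythms (flutter, sinus
arrhythmia) whose RRi distributions genuinely overlap AF — on real corpora
those produce the intermediate metric values and label-specific confusions
this synthetic benchmark cannot emulate.

## Numerical choices

* Squared distances are clamped to 0 when negative by less than 1e-12
  (floating-point cancellation near zero); more negative values raise, as
  they indicate a bug rather than round-off.
* Double-sums are accumulated in natural index order without compensated
  summation — at d ≤ a few hundred samples the error is orders of magnitude
  below the 1e-10 oracle-agreement budget.
* Square self-Gram matrices are symmetrized exactly and given a unit
  diagonal; they are positive semi-definite up to −1e-8 on the smallest
  eigenvalue.
* Exact-zero distance for permuted copies of a sample holds only up to
  summation order; the guarantee is 1e-12, not bitwise zero.
* Model archives are JSON; Python's float repr round-trips IEEE doubles
  exactly, so serialization is bit-compatible.

## Problem sizes

The shipped study conditions are 150+150 training and 150+150 test patients
of 20–60 intervals each, with the 5×4×2 default-grid cross-validation
completing in well under a minute on one core; the data-efficiency study
uses 20 resamples per size.  These sizes were chosen so the full protocol is
exercised end to end at desk scale while leaving the per-patient interval
counts in the range real 30–60 s recordings produce.

## Known limitations

* The i.i.d. interval model ignores serial correlation; rhythms defined by
  *structured* variability are only crudely emulated by the modulated
  preset.
* The built-in peak detector is for fixtures and clean traces; real corpora
  should use a published detector through the adapter registry.
* No probability calibration is provided; decision scores are margins, not
  risks.
* AUROC is undefined (NaN, flagged) when a test set contains one class.
* The WFDB reader covers format 16 only.
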