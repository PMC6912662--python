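# Methods

This note documents the model and the numerical and design choices behind
`srqa`, in the spirit of a statistical software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Symbolization

A real-valued window is embedded into consecutive m-histories (lag 1, no
delay embedding) and each history is mapped to the permutation that sorts
it. Ties are resolved by a *stable* sort of (value, offset) pairs: equal
values keep ascending offset order, which makes the symbol unique and means
a constant history maps to the identity pattern `(0, 1, …, m−1)`. Symbols
are indexed lexicographically — for m=3: `(0,1,2)=0, (0,2,1)=1, (1,0,2)=2,
(1,2,0)=3, (2,0,1)=4, (2,1,0)=5` — so indices are deterministic and stable
across runs. Offsets are 0-based internally (half-open ranges); positions
in user-facing output (plot axes) are 1-based.

The symbolization depends only on rank order, so it is invariant under any
strictly increasing transform of the series and insensitive to amplitude
drift and outliers — the property that motivates using it on noisy,
non-stationary RR data.

The admissibility rule `5·m! ≤ w` requires each of the m! symbols to have
expected frequency at least 5 under independence in a w-beat window; it
bounds m from above (w=30 → m≤3). The default m is 3 everywhere. The
library allows larger m but the CLI refuses an inadmissible combination
unless `--force-embedding` is given.

## Recurrence measures

The recurrence matrix stores the shared symbol index per cell with a
sentinel (−1) for non-recurrent pairs, so the indicator matrix SR and every
SR(π) are recovered from one array and the decomposition `SR = Σ_π SR(π)`
holds exactly by construction.

Conventions, chosen where the definitions admit freedom:

* **SRR includes the main diagonal** (the defining sum runs over all t, s);
  the main diagonal is excluded only from diagonal-*line* counting. Hence
  `SRR ≥ 1/n` always.
* **Diagonal lines** are maximal runs of recurrent cells of length ≥ 2 on
  the global SR matrix — symbols may change along a run — counted on both
  triangles. Each structure is therefore counted twice, which is
  consistent because determinism normalizes by the full-matrix recurrence
  mass `n²·SRR`.
* **Vertical lines** are counted per symbol δ on SR(δ), per column,
  *including* main-diagonal cells: a vertical run expresses one ordinal
  pattern persisting in time, and the cell (t, t) carries that symbol.
  Only the strictly increasing and strictly decreasing patterns can repeat
  at consecutive t (overlapping histories share m−1 values), so vertical
  measures are computed for those two symbols only; for any other symbol
  the distribution is empty by construction.
* **`rline_v(δ)`** has no canonical closed form in the recurrence
  literature for the symbolic setting; it is defined here as
  `Σ_l l·n(l) / (n²·SRR(δ))` — the fraction of δ's recurrence mass lying on
  vertical lines — mirroring the determinism formula. This is a documented
  convention of this package.
* **Entropies** are Shannon entropies of the line-length histograms in
  nats. Any fixed base is equivalent up to a rescaling of the logistic
  coefficients. Empty or single-length distributions have entropy 0.
* **Degenerate values:** trapping time of an empty distribution is 0 (not
  NaN), and `rline_v` is 0 when `SRR(δ) = 0`, so feature vectors are always
  complete and finite.

## Windowing, labels and covariates

Windows are consecutive and non-overlapping (stride = w); the trailing
remainder of a record is dropped. A window is AF iff strictly more than
half of its beats are annotated AF; every other rhythm (normal sinus,
flutter, junctional → `OTHER`) counts toward non-AF, and windows spanning a
rhythm transition are labelled by the same beat-count rule, never
discarded.

The covariate vector has 18 entries: the six `SRR(π)`, determinism `D` and
diagonal entropy, `rline_v` / vertical entropy / trapping time for the
increasing and decreasing symbols, and mean, median, CV and VMe of the raw
RR intervals. CV uses the sample (n−1) standard deviation; the even-length
median is the mean of the central pair. CV and VMe are scale-invariant;
mean and median carry the heart-rate level in ms.

## Classifier

Plain maximum-likelihood logistic regression (no regularization), fit by
Newton scoring with convergence tolerance 1e−8 and at most 100 iterations,
with Wald standard errors from the observed information. Internally the
design is z-standardized for the optimizer — covariate scales span
milliseconds (≈800) to unit fractions — and the coefficients and covariance
are transformed back exactly, so estimates equal those of an
unstandardized fit to machine precision. Zero-variance covariates are
dropped with a warning. Under perfect separation the Newton step is
undefined (singular Hessian); the fit then falls back to BFGS, keeps the
last iterate — which still separates the classes for prediction — and
flags the model non-converged with a warning. Significance is starred at
5% (\*) and 1% (\*\*).

Threshold selection evaluates the strict rule `p > τ` on the 1001-point
grid τ = 0, 0.001, …, 1 and picks the τ minimizing the squared distance to
the ROC corner (0, 1); ties resolve to the smallest τ, for determinism.
Note that with the strict rule, probabilities exactly equal to a grid value
are classified negative at that τ.

Cross-validation is stratified (preserving class balance in small folds;
`group_by_record=True` switches to record-grouped folds for per-patient
generalization checks) and seeded. The per-fold τ is selected on the
training folds only — selecting it on the held-out fold would leak — so
reported per-fold operating points are honest but may differ from a
protocol that tunes τ globally. Quartiles use numpy's linear-interpolation
percentiles.

## Surrogate data generator

The generator exists so the entire pipeline is exercisable without any
external download. It emulates the two rhythm classes at the level of RR
statistics, not physiology:

* **Sinus**: `RR_t = 800 + 40·sin(2πt/4) + N(0, 10)` ms. The 4-beat
  modulation coarsely mimics respiratory sinus arrhythmia and guarantees
  non-monotone ordinal patterns occur, so all six symbol rates are
  exercised; the noise floor keeps windows non-degenerate.
* **AF**: i.i.d. uniform intervals on [400, 1100] ms, matching the
  characterization of AF as a near-random interval sequence with high
  beat-to-beat variability, and making symbol frequencies analytically
  uniform (1/6 each) for tests. An optional lag-1 correlation (≤ 0.3) is
  realised through a Gaussian copula so the uniform marginal is preserved.
* **Mixed records** concatenate labelled segments to exercise the
  window-majority rule across rhythm transitions.

All randomness flows through numpy's seeded PCG64 generator passed
explicitly; there is no global random state, and identical seeds give
bit-identical records across platforms.

**What passing tests on surrogates do and do not show.** The two surrogate
classes are separated by an order of magnitude in CV/VMe, far more cleanly
than real Holter data, where ectopy, annotation noise and borderline
rhythms blur the margin. Surrogate cross-validation accuracies near 1.0
therefore validate the *pipeline* (features are computed correctly, the
model and threshold machinery work, accuracy does not degrade with window
size) — they are not an estimate of clinical performance. External
validation against the PhysioNet MIT-BIH Atrial Fibrillation Database is
supported via `scripts/validate_afdb.py` (optional `wfdb` dependency and a
download; beats before the first rhythm annotation are imported as `OTHER`,
a conservative non-AF choice).

## Problem sizes in the shipped checks

The acceptance script and end-to-end tests use 400 windows per class per
window size (w ∈ {30, 60, 120, 200}) with 10-fold CV, brute-force oracle
comparisons on 1000 random symbol sequences of length ≤ 12, coefficient
recovery at n = 5000, and Wald-calibration over 200 null replicates of
n = 400 — sizes chosen to make Monte-Carlo error small relative to the
asserted tolerances while keeping a full run in the tens of seconds.

## Known limitations

* Lag-1 embedding only; no multivariate or delay-embedded symbolization.
* No ectopic-beat filtering or RR preprocessing (the method is designed to
  need none, but annotation errors propagate directly into features).
* Per-window decisions only; no aggregation into per-patient or episode
  calls, and no probability calibration.
* The `simulate` CLI subcommand alternates sinus and AF records (even
  indices sinus) so a single invocation yields both classes for the
  downstream commands.
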