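# srqa — symbolic recurrence analysis of RR intervals for AF detection

`srqa` detects atrial fibrillation (AF) in beat-annotated RR-interval
series using **symbolic recurrence quantification analysis (SRQA)** and a
logistic classifier. It is aimed at researchers working with Holter /
ambulatory ECG annotations (e.g. PhysioNet-style beat and rhythm files) who
want an AF window classifier built from a small, interpretable feature set,
with no waveform processing and essentially no preprocessing of the RR
series.

## The method

A window of `w` RR intervals is embedded into overlapping *m*-histories
`x̄_t = (x_t, …, x_{t+m−1})` (default `m = 3`). Each history is mapped to
its **ordinal pattern**: the permutation `π = (i_1, …, i_m) ∈ S_m` with
`x_{t+i_1} ≤ … ≤ x_{t+i_m}`, ties broken toward the smaller offset. Two
histories *recur symbolically* when they share a pattern, giving the
indicator matrices

    SR_ts = 1{S(x̄_t) = S(x̄_s)},     SR_ts(π) = 1{S(x̄_t) = S(x̄_s) = π},

with `SR = Σ_π SR(π)`. From these the package computes, per window:

* the global and per-symbol **symbolic recurrence rates**
  `SRR = n⁻² Σ_{t,s} SR_ts` and `SRR(π)`;
* **determinism** `D = Σ_d d·n(d) / (n² SRR)` from the distribution of
  diagonal lines of length ≥ 2 (main diagonal excluded) and its Shannon
  entropy `ent(d)`;
* per monotone symbol δ (the only patterns that can persist through
  consecutive histories): the **trapping time** `v̄_δ` (mean vertical line
  length), the fraction of δ-recurrence mass on vertical lines
  `rline_{v_δ}`, and the vertical-length entropy `ent(v_δ)`;
* four RR distribution summaries: mean, median, the coefficient of
  variation `CV = sd/mean`, and the coefficient of variation of the median
  `VMe = Σ|RR_i − Me(RR)| / Σ RR_i`.

A window is labelled AF when strictly more than half of its beats carry the
AF annotation. A maximum-likelihood logistic regression of the label on
these 18 covariates gives `P(AF)`; the decision threshold `τ` is chosen on a
0.001-step grid as the ROC point closest to the ideal corner,
`τ = argmin { FPR² + (1 − Se)² }`, and robustness is summarized by
stratified 10-fold cross-validation (P25 / median / P75 of τ, Se, Sp, ACC).

The embedding dimension must satisfy `5·m! ≤ w` so every symbol has expected
frequency ≥ 5; a 30-beat window therefore admits at most `m = 3`.

## Worked example

The seven-value series `{3, 9, 7, 6, 5, 10, 4}` has five 3-histories:

```python
>>> from srqa import symbolize_window, compute_measures
>>> seq = symbolize_window([3, 9, 7, 6, 5, 10, 4], m=3)
>>> [str(s) for s in seq.symbols]
['(0,2,1)', '(2,1,0)', '(2,1,0)', '(1,0,2)', '(2,0,1)']
>>> m = compute_measures(seq)
>>> m.srr, m.srr_by_symbol[5], m.vbar[5]
(0.28, 0.16, 2.0)
```

The fourth history `(6, 5, 10)` is of `(1,0,2)`-type: its middle value is
the smallest, its last the largest. Of the 25 matrix cells, 7 are recurrent
(5 self-recurrences plus the symmetric pair of decreasing histories), hence
`SRR = 0.28`; the decreasing symbol alone contributes `SRR((2,1,0)) = 0.16`,
and its two-cell vertical run gives trapping time 2.0.

End-to-end on surrogate data from the command line:

```console
$ srqa --seed 7 simulate --out-dir records --n-records 4 --n-beats 2000
wrote 4 records to records
$ srqa --window 60 extract-features records/*.tsv --out features.csv
132 windows (66 AF) -> features.csv
$ srqa --seed 1 cv features.csv --k 10 --out cv_summary.csv
10-fold CV on 132 windows -> cv_summary.csv
       p25  median    p75
tau  0.001   0.001  0.001
se   1.000   1.000  1.000
sp   1.000   1.000  1.000
acc  1.000   1.000  1.000
```

The surrogate sinus and AF rhythms differ starkly in beat-to-beat
variability, so every held-out window is classified correctly and the
ROC-selected threshold sits at the bottom of the grid. Real Holter data are
far less separable; see `scripts/validate_afdb.py` for an optional external
validation against the PhysioNet MIT-BIH Atrial Fibrillation Database
(requires `wfdb` and a download).

`srqa plot-srp records/ns000.tsv --out srp.png` renders the symbolic
recurrence plot of a window, one colour per ordinal pattern.

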