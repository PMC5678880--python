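# hyporules

Association-rule analysis of a three-marker immunohistochemistry (IHC)
panel — HIF-1α, PDK1 and PHD3 — for classifying the hypoxic status of
neuroblastoma tumors.

Tumor hypoxia is a strong adverse prognostic factor in neuroblastoma,
but the microarray signatures that measure it need fresh-frozen tissue.
IHC on paraffin-embedded sections is available for essentially every
tumor: HIF-1α and PDK1 are induced by prolonged hypoxia while PHD3 is
suppressed, so the three stains carry the same signal. `hyporules`
implements the analysis that turns semiquantitative IHC scores into
plain-language classification rules: dichotomize each marker, mine
marker-state → hypoxia-status association rules with APRIORI, score
them with five interestingness metrics, and report the top rules per
polarity. It is aimed at biostatisticians and tumor-biology groups who
want the pipeline as a reusable, tested library rather than a one-off
analysis.

## The model

Each tumor carries a binary hypoxia label (from a prior expression
cluster, treated as ground truth) and, per marker, a percentage-
positivity bin from {<1%, 1–20%, 21–50%, 51–70%, 71–100%}. Bins map to
levels L/M/H (the two low bins → L, the two high bins → H, 21–50% → M);
M scores resolve to binary high/low by staining intensity
(strong/moderate → high, weak → low by default) or by an explicit
recorded resolution. Every tumor then becomes a transaction over items
`HIF1A=high|low`, `PDK1=high|low`, `PHD3=high|low`, `HYPOXIA=high|low`,
and APRIORI enumerates frequent itemsets level-wise.

For a rule A→B with N transactions, n(A), n(B) and n(A∧B) occurrence
counts, the five metrics are

- confidence = n(A∧B)/n(A) (precision),
- coverage = n(A∧B)/n(B) (consequent recall — note this is *not* the
  antecedent-support quantity the same word often denotes elsewhere),
- lift = confidence / (n(B)/N),
- leverage = n(A∧B)/N − n(A)n(B)/N²,
- conviction = n(A)·(N−n(B)) / (N·(n(A)−n(A∧B)+1)), a +1-smoothed
  variant that keeps confidence-1 rules finite; the classical unsmoothed
  form is available via `variant="classical"`.

All metrics are computed in exact rational arithmetic from the integer
counts. The selection step takes, per consequent polarity, the union of
the top-k rules by lift and the top-k by conviction (k = 7 by default).

## Worked example

```python
from hyporules import RunConfig, run_pipeline
from hyporules.render import render_text

report = run_pipeline(RunConfig(use_fixture=True, k=7))
print(render_text(report))
```

prints the 14-rule panel for the packaged 25-tumor cohort (8 hypoxic,
17 normoxic), beginning

```
Rule  if HIF1A is  if PDK1 is  if PHD3 is  then                n(A)  n(A^B)  Coverage  Confidence  Lift  Leverage  Conviction
-----------------------------------------------------------------------------------------------------------------------------
R1    high                                 ==> HYPOXIA = high  11    8       1         0.73        2.27  0.18      1.87
R2                 high                    ==> HYPOXIA = high  9     7       0.88      0.78        2.43  0.16      2.04
R3                             low         ==> HYPOXIA = high  10    8       1         0.8         2.5   0.19      2.27
R4    high         high                    ==> HYPOXIA = high  8     7       0.88      0.88        2.73  0.18      2.72
R5    high                     low         ==> HYPOXIA = high  8     8       1         1           3.13  0.22      5.44
```

R1 reads: 11 of the 25 tumors stain high for HIF-1α and 8 of those are
in the hypoxic cluster — every hypoxic tumor is captured (coverage 1)
but confidence is only 0.73, so the single marker errs on three
normoxic tumors. R5 shows the point of the panel: requiring HIF-1α high
*and* PHD3 low keeps coverage at 1 while raising confidence to 1 — the
marker combination identifies the hypoxic cluster exactly.

The same pipeline is available from the shell:

```
hyporules report --fixture            # the table above
hyporules resolve-audit --fixture     # exhaustive audit of the six ambiguous 21–50% scores
hyporules simulate --n 100 --prevalence 0.32 --se 0.9 --sp 0.9 --seed 1 --out cohort.csv
hyporules report --input cohort.csv
```

Short narrative scripts for each capability live in `examples/`.

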