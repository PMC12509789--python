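# methodfail

Failure-aware method comparison for simulation and benchmark studies.

When a method under comparison *fails* on some data sets — an error, a
non-converged fit, a crash, an output of 0 or ∞ — its performance value
there is **undefined**, not missing: the quantity one wished to record does
not exist. Treating such cells as missing data (imputing them, or silently
dropping the affected data sets) changes what a study measures, often
enough to reorder the methods. This package gives researchers the
bookkeeping and the handling strategies to deal with that honestly, plus
two fully synthetic illustration studies in which the effect can be
watched end to end.

## What is in the box

- **`methodfail.core`** — a `ResultsTable` (datasets × methods grid in
  which every cell is a value or a typed failure record), the handling
  strategies found in the applied literature (discard for the failing
  methods only, discard for all methods, worst-value / row-mean /
  column-mean / 20%-threshold-hybrid / failure-weighted imputation),
  fallback **pipelines** ("use method A if it produces an output, method B
  otherwise") evaluated as single entities, average-rank comparison, and a
  three-part "slimmed-down" report that never separates aggregates from
  failure proportions.
- **`methodfail.datagen`** — seeded generators: multinomial 2×2
  outcome–exposure tables with an exact inclusion–exclusion oracle for the
  probability of a sampling zero; binary-response classification data on
  which a depth-limited tree sometimes has nothing to split; small fictive
  results grids.
- **`methodfail.or_study`** — five odds-ratio estimators (cross-product,
  add-0.5 Woolf, Jewell small-sample, conditional MLE, mid-p
  median-unbiased) with explicit failure semantics under sampling zeros,
  the Haldane–Anscombe correction, and the nine-pipeline comparison on
  log-scale bias.
- **`methodfail.ci_study`** — naive vs variance-corrected resampled
  t-intervals for the generalization AUC (correction constant `c`
  inflating the variance for train/test overlap), the zero-variance
  failure of the naive interval, and a coverage study over four handlings.
- **`methodfail.report` / `methodfail.cli`** — failure reports, run
  manifests, and a `methodfail` console script.

The two interval methods, for 15 subsampling repetitions with AUC values
$\widehat{AUC}_i$, mean $\overline{AUC}$ and sample variance $S^2$:

$$\overline{AUC} \;\pm\; t_{0.975,\,14}\,\sqrt{\left(\tfrac{1}{15} + c\right) S^2},$$

with $c = 0.25$ (the 4:1 test/train ratio) for the corrected method and
$c = 0$ for the naive one — which, implemented via an off-the-shelf
t-test, errors out whenever all 15 AUCs coincide.

## Worked example

```python
from methodfail import (PerformanceSpec, Measure, Orientation,
                        fictive_overview_table, slimmed_report)

table = fictive_overview_table()   # 4 repetitions x 3 methods, truth 4, two failures
spec = PerformanceSpec(Measure.BIAS_RAW, Orientation.LOWER_IS_BETTER)
rep = slimmed_report(table, spec)
print(rep.conditional)             # per-method bias over its own successes
print(rep.failure_proportions)
```

prints

```
             value  n_used
Method 1 -0.193333       3
Method 2  0.072500       4
Method 3  0.140000       3
Method 1    0.25
Method 2    0.00
Method 3    0.25
Name: failure_proportion, dtype: float64
```

Method 2 never fails, so its conditional bias 0.07 is also its
unconditional bias; Methods 1 and 3 each fail on one repetition, so their
numbers condition on non-failure and are not comparable to Method 2's —
which is exactly what the attached caveat string says.

## The analysis scripts

Numbered drivers under `analysis/` run the studies and write tables under
`results/`:

1. `01_sampling_zeros.py` — sampling-zero proportions per scenario,
   simulated (100 000 draws) vs exact; e.g. scenario (OR=5, px=0.25) gives
   11.91% both ways.
2. `02_or_study.py` — the full odds-ratio study. In its rank table the two
   discarding regimes disagree visibly (Woolf ranks 1st under
   per-method discarding in every scenario but 4th under all-method
   discarding in scenario 2), while the nine fallback pipelines allow an
   unconditional comparison; residual failures of pipelines that fall back
   on the small-sample estimator (16 of 100 000 tables in scenario 1) are
   flagged, not hidden.
3. `03_ci_coverage.py` — the coverage study (1000 iterations): naive-method
   failure proportion ≈ 0.32, coverage 0.41 / 0.60 / 0.73 under
   impute-as-noncovering / discarding / zero-width repair, corrected
   method ≈ 0.94 throughout and never failing.
4. `04_slim_report.py` — the three-part minimal report on the fictive grid.

Or from the command line:

```sh
methodfail or-study zeros --config or.yaml
methodfail ci-study run --config ci.yaml --out out/
methodfail report slim --results table.csv --measure bias_raw
```

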