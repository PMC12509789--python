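# Methods

## The problem being modeled

A comparison study evaluates methods `m = 1..M` on data sets `d = 1..N`
(simulation repetitions or benchmark data sets) and aggregates a
performance measure per method. Method failure leaves the cell `(d, m)`
*undefined*: the estimate or performance value does not exist, so the
desired comparison of unconditional performance (over all `N` data sets)
is not available for the failing methods. Every operation in this package
is organized around keeping that distinction explicit rather than papering
over it.

### Failure taxonomy

A failing cell carries one reason from {`error`, `nonconvergence`,
`timeout`, `memory`, `invalid_value`} plus a free-text message captured at
evaluation time. `evaluate_methods` converts any raised exception to
`error` and any non-finite or non-numeric return to `invalid_value`;
nothing propagates, so the grid is always complete. Estimator-specific
failures (an odds-ratio estimate of 0 or ∞) are classified as
`invalid_value` because a value was produced but is non-meaningful;
root-bracketing exhaustion maps to `nonconvergence`.

### Handling strategies

Let `f_m` be method *m*'s failure proportion.

- **Discard for the failing methods only** (`aggregate_conditional`): each
  method is aggregated over its own successes. Different methods are then
  scored on different data sets.
- **Discard for all methods** (`aggregate_complete_case`): one shared
  subset with no failures anywhere; its size is reported and identical
  across methods, and an empty intersection leaves every aggregate
  undefined rather than raising.
- **Imputation** (`impute_outcomes`): worst value; row mean over the other
  methods' defined values (a row where *every* method fails is
  unresolvable and keeps its failures, with a warning); the method's own
  column mean; or the 20%-threshold hybrid — worst value when
  `f_m > 0.20`, else the column mean. The hybrid's literature original
  samples from a normal fitted to the successful values below the
  threshold; the column mean is used instead so the operation is
  deterministic, and the `seed` parameter is retained only for interface
  stability.
- **Failure-weighted value** (`aggregate_with_handling` with
  `impute_weighted`): `(1 - f_m) * conditional + f_m * worst`. This is an
  aggregate-level rule — for bias-type measures it cannot be phrased as
  filling cells — so `impute_outcomes` rejects it and points to the
  aggregate path. Its endpoints are identities: `f = 0` gives the
  conditional aggregate, `f = 1` the worst value.

On coverage-type tables (cells 0/1) the handlings satisfy exact
arithmetic: worst-value imputation comes out to
`conditional * (1 - f)`, and setting each failed cell to "covering"
adds `f` back.

### Pipelines

A `PipelineSpec` is an ordered list of method ids, primary first, with a
bounded number of fallbacks. The induced column takes, per data set, the
first non-failing step's value; it fails only where every step fails, so
its failure set is the intersection of the steps' failure sets and its
failure proportion can never exceed the primary's. When all steps fail the
reported reason is the *primary* step's reason — the convention adopted
here for the genuinely open question of labeling multi-cause pipeline
failures — and the per-dataset index of the chosen step is recorded.
All-steps-fail rows are never dropped silently; studies flag them.

### Ranking

`rank_methods` gives average ranks (rank 1 = best) via the standard
midrank convention; bias-type measures rank on |aggregate| while the
signed values remain reported. Undefined aggregates are refused with an
instruction to resolve failures first — aggregating around undefined
values is precisely what the package exists to prevent.

## Study 1: odds-ratio estimation under sampling zeros

### Data-generating mechanism

A scenario is `(n_obs, true OR, px, p0)`: each table is one multinomial
draw of size `n_obs` over cell probabilities
`(px·p1, px·(1−p1), (1−px)·p0, (1−px)·(1−p0))`, where `p0 = P(Y=1|X=0)`
and `p1` follows from the odds ratio. The four canonical scenarios fix
`n_obs = 50`, `p0 = 0.5`, `OR ∈ {2, 5}`, `px ∈ {0.25, 0.5}`. `p0` is not
part of the canonical scenario description; 0.5 is adopted because the
exact sampling-zero probabilities it implies (1.30%, 11.91%, 0.011%,
1.29%) match the reported proportions (1.28%, 12.0%, 0.01%, 1.27%) within
the Monte-Carlo error of a single 100 000-draw run. The exact probability
is computed by inclusion–exclusion over the four cells,
`Σ_{S≠∅} (−1)^{|S|+1} (1 − Σ_{c∈S} p_c)^{n_obs}`, and is cross-checked in
the tests against direct enumeration of all compositions for small
`n_obs`.

Seeding: one root seed; scenario *i* uses the substream
`(seed·1009 + i) mod (2³¹−1)`, so runs are reproducible scenario by
scenario.

### Estimators and failure semantics

Failure is *output-based*: an estimate that is non-finite, ≤ 0, or absent
counts as failure regardless of whether an exception occurred.

| id | estimate | fails iff |
|---|---|---|
| `manual` | `n11·n00/(n10·n01)` | any cell of the table is 0 |
| `woolf` | `(n11+.5)(n00+.5)/((n10+.5)(n01+.5))` | never |
| `small` | `n11·n00/((n10+1)(n01+1))` | `n11·n00 = 0` (estimate 0) |
| `fisher` | conditional MLE | `n11` at a support bound |
| `midp` | mid-p median-unbiased | `n11` at a support bound |

With both margins fixed, the exposed-case count follows the noncentral
hypergeometric law on `a ∈ [max(0, r−m0), min(r, m1)]`. `fisher` solves
`E_ψ[A] = n11`, `midp` solves `P_ψ(A > n11) + 0.5·P_ψ(A = n11) = 0.5`;
both by monotone bisection in log ψ on the bracket [−12, 12], expanded
(doubled) at most twice, with 64 halvings (final uncertainty far below
the 1e−8 working tolerance). The solver runs once per *distinct* table
and is broadcast back, which keeps 100 000-draw scenarios at seconds of
runtime. Note these support-bound failure sets coincide exactly with
"the table contains a sampling zero", the same set on which `manual`
fails — a property the exhaustive small-table enumeration in the tests
verifies.

Whether `small`'s returned 0 is a failure or a valid output is genuinely
ambiguous (it "handles zeros internally", yet 0 is non-meaningful and
cannot enter a log-scale bias); both behaviors are available via
`zero_is_failure`, and failure is the default because the study's
performance measure is log-scale bias.

The Woolf point estimate used here is numerically identical to "manual on
the Haldane–Anscombe-corrected table" (`ha`). Both ids are kept because
they represent different user behaviors (a deliberate estimator choice vs
a fallback correction); pipelines differing only in that step coincide in
value and share average ranks.

### Design of the comparison

Per scenario, log-scale bias `mean(log ψ̂) − log(OR)` is compared under
three regimes: the two discarding regimes over the five pure estimators,
and the nine fallback pipelines (Manual/HA; Midp and Fisher each with HA,
Small, Woolf; Small; Woolf alone) evaluated as single entities. Ranks use
|log bias|.

Known limitation, flagged by the study rather than repaired: pipelines
terminating in `small` (Midp/Small, Fisher/Small, and `small` itself)
retain a structural failure mode — on a table with no exposed cases or no
unexposed non-cases, both the primary and `small` fail. In scenario 1
this has probability ≈ 1.1 × 10⁻⁴ (expected ≈ 11 tables per 100 000
draws), so "zero residual failures for all nine pipelines" is not
attainable at full scale; the residuals are reported per pipeline and the
pipeline aggregate is computed conditionally on them.

## Study 2: CI coverage for the generalization AUC

### Generator

Each iteration draws a binary-response data set with `n = 1000`
observations and 10 standard-normal features; with probability
`pi_null = 0.3` it carries no signal, otherwise feature 0 has a
standardized mean shift `d = 2` between classes. Labels are
Bernoulli(0.5), redrawn (bounded retries) if a class is absent. These
sizes are the package's stand-in for a real benchmark data set whose
post-preprocessing dimensions are unknown; what is emulated is only the
failure-relevant structure — a tunable fraction of data sets on which a
depth-limited tree has nothing to split. Real data would add correlated
features, imbalance, and a signal that varies continuously rather than
being present-or-absent; passing tests therefore establish the *handling
arithmetic* and the failure mechanism, not tree performance on real
psychometric data.

### Models, intervals, design

The learner is a Gini CART (scikit-learn) with `max_depth = 2`,
`min_samples_leaf = 10`, `min_impurity_decrease = 0.07`. The threshold is
the calibrated operating point at the study's subsample size (160
training points): a null data set clears it in ~1% of cases while a
`d = 2` signal always splits, so the naive method's failure proportion
tracks `pi_null`. AUC is the Mann–Whitney pair statistic with ties
counted 0.5 (all-equal scores give exactly 0.5).

Per iteration: an 80% test part approximates the true AUC of a tree
trained on the remaining 20% (the deliberately inverted split keeps the
truth approximation accurate); 15 random 80/20 subsampling splits of that
20% give the AUC values entering both intervals. The corrected interval
uses `c = 0.25`; the constant is exposed in the config, and the
test/train ratio of the subsampling split is its default construction.
The naive interval is the `c = 0` one-sample t-procedure and *fails* by
contract when `s² = 0`; the corrected implementation computes mean and
variance directly and returns the zero-width interval `[mean, mean]`
instead. Coverage uses the closed tolerance
`lower − ε ≤ trueAUC ≤ upper + ε`, `ε = 1e−12`, so a zero-width interval
at exactly the true value counts as covering — in the null regime the
constant tree's subsampled AUCs and the true AUC are all exactly 0.5,
which is what makes the zero-width repair add exactly the failure
proportion to the imputed coverage.

Handlings compared: discard failing iterations for the naive method only;
discard for both methods; impute failures as "not covering"; replace
failures by the zero-width interval. The ordering
`impute ≤ discard ≤ zero-width` is an arithmetic consequence of the
identities above, and the corrected interval strictly contains the naive
one whenever both exist (width ratio exactly `sqrt(1 + 15c)`).

## Numerical and design choices, in brief

- Ties in ranks: average midranks (deterministic, standard).
- Degenerate inclusion–exclusion terms (`1 − Σp` slightly negative from
  floating-point) are clamped at 0.
- The bias-measure worst value has no natural default and must be
  user-supplied; coverage-type worst value is 0 ("not covering").
- `simulate_tables` returns an `(n_sims, 4)` integer array rather than
  object rows, for vectorization; `ContingencyTable(*row)` lifts a row.
- Problem sizes used by the shipped analyses: 100 000 tables per scenario
  (odds-ratio study) and 1000 iterations (coverage study) — the studies'
  canonical sizes; both run in well under a minute each on one CPU.
- The CLI is one console script (`methodfail`) rather than separate
  `or-study`/`ci-study`/`report` executables, to avoid claiming generic
  command names; `cli_dispatch(argv)` exposes the same surface
  programmatically.

## Known limitations

- No general missing-data machinery (multiple imputation etc.) is, or
  will be, included: undefined values are not missing values.
- Figure-style rank *trajectories* are not drawn; the rank tables the
  plots would need are emitted as CSV.
- Gray-area failure (near-separation, partial failure such as a point
  estimate without a standard error) is out of scope; failure here is
  binary per cell.
- The residual failure mode of Small-terminated pipelines (above) is
  inherent to the estimator set, not a bug; studies flag it.
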