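"""Failure-aware bookkeeping for method comparison studies.

A comparison study evaluates a set of methods on a collection of (real or
simulated) data sets.  When a method fails on a data set — an error, a
non-converged fit, a crash, a non-meaningful output — its performance value
there is *undefined*, not merely missing: the quantity we wished to record
does not exist.  This module provides the containers and operations needed
to keep working honestly in that situation:

* :class:`MethodOutcome` / :class:`ResultsTable` — a datasets x methods grid
  in which every cell is either a value or a typed failure record;
* the handling strategies found in the applied literature (discarding for
  the failing methods only, discarding for all methods, several imputation
  rules) as explicit, named operations;
* fallback *pipelines* ("use method A if it produces an output, method B
  otherwise"), evaluated as single entities so that unconditional
  performance is defined;
* failure-proportion reporting and a three-part "slimmed-down" summary that
  never separates aggregates from the failure proportions that qualify them.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "FailureReason",
    "MethodOutcome",
    "ResultsTable",
    "Measure",
    "Orientation",
    "PerformanceSpec",
    "HandlingKind",
    "HandlingStrategy",
    "PipelineSpec",
    "PipelineColumn",
    "SlimReport",
    "UNCONDITIONAL_CAVEAT",
    "evaluate_methods",
    "failure_proportions",
    "aggregate_conditional",
    "aggregate_complete_case",
    "aggregate_with_handling",
    "impute_outcomes",
    "apply_pipeline",
    "pipeline_table",
    "rank_methods",
    "slimmed_report",
    "results_to_csv",
    "results_from_csv",
]


class FailureReason(str, enum.Enum):
    """Why a method produced no usable value on a data set."""

    NONE = "none"
    ERROR = "error"
    NONCONVERGENCE = "nonconvergence"
    TIMEOUT = "timeout"
    MEMORY = "memory"
    INVALID_VALUE = "invalid_value"


@dataclass(frozen=True)
class MethodOutcome:
    """One method-on-dataset result: a value, or a typed failure record.

    Exactly one of the two states holds: ``value`` is a finite real and
    ``failure_reason`` is ``NONE``, or ``value`` is ``None`` and
    ``failure_reason`` names why the method failed.
    """

    value: float | None
    failure_reason: FailureReason = FailureReason.NONE
    message: str = ""

    def __post_init__(self) -> None:
        defined = self.value is not None
        if defined and not math.isfinite(self.value):  # type: ignore[arg-type]
            raise ValueError("a defined outcome must be finite; encode "
                             "non-finite output as failure_reason=invalid_value")
        if defined != (self.failure_reason is FailureReason.NONE):
            raise ValueError(
                "value is defined iff failure_reason is NONE "
                f"(got value={self.value!r}, reason={self.failure_reason})"
            )

    @property
    def failed(self) -> bool:
        return self.failure_reason is not FailureReason.NONE


class Measure(str, enum.Enum):
    BIAS_RAW = "bias_raw"
    BIAS_LOG = "bias_log"
    COVERAGE = "coverage"
    MEAN_VALUE = "mean_value"


class Orientation(str, enum.Enum):
    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


_BIAS_MEASURES = frozenset({Measure.BIAS_RAW, Measure.BIAS_LOG})


@dataclass(frozen=True)
class PerformanceSpec:
    """What is aggregated and how methods are compared on it.

    ``worst_value`` is the measure's worst achievable value on the aggregate
    scale (e.g. 0 for coverage); it must be supplied before any worst-value
    imputation and for unbounded measures such as bias it has no natural
    default.  For bias-type measures the orientation applies to the absolute
    value (signed aggregates are still reported).
    """

    measure: Measure = Measure.MEAN_VALUE
    orientation: Orientation = Orientation.HIGHER_IS_BETTER
    worst_value: float | None = None

    @property
    def is_bias_like(self) -> bool:
        return self.measure in _BIAS_MEASURES


class HandlingKind(str, enum.Enum):
    DISCARD_FAILING_ONLY = "discard_failing_only"
    DISCARD_ALL = "discard_all"
    IMPUTE_WORST = "impute_worst"
    IMPUTE_MEAN_OTHER_METHODS = "impute_mean_other_methods"
    IMPUTE_METHOD_MEAN = "impute_method_mean"
    IMPUTE_HYBRID_THRESHOLD = "impute_hybrid_threshold"
    IMPUTE_WEIGHTED = "impute_weighted"


@dataclass(frozen=True)
class HandlingStrategy:
    """A named way of coping with failures before aggregation.

    ``threshold`` is consulted only by the hybrid rule (impute the worst
    value when a method's failure proportion exceeds it, else the method's
    own mean over its successful data sets); the 0.20 default follows the
    20% rule used by Bischl et al. and Herrmann et al.
    """

    kind: HandlingKind
    threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class PipelineSpec:
    """An ordered fallback rule: first step is the primary method."""

    steps: tuple[str, ...]
    max_fallbacks: int = 2

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        if not 1 <= len(steps) <= 1 + self.max_fallbacks:
            raise ValueError(
                f"pipeline must have between 1 and {1 + self.max_fallbacks} steps"
            )
        if len(set(steps)) != len(steps):
            raise ValueError("pipeline steps must be distinct")

    @property
    def primary(self) -> str:
        return self.steps[0]

    @property
    def name(self) -> str:
        return "/".join(self.steps)


_NO_REASON = FailureReason.NONE.value


class ResultsTable:
    """A complete datasets x methods grid of :class:`MethodOutcome`.

    Stored columnar for speed: ``values`` is a float frame with NaN in
    failing cells, ``reasons`` a string frame that is ``"none"`` exactly
    where ``values`` is defined.  ``truth`` optionally carries the per-dataset
    true value of the estimand (needed for bias-type measures).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        reasons: pd.DataFrame | None = None,
        truth: pd.Series | None = None,
        messages: pd.DataFrame | None = None,
    ) -> None:
        values = values.astype(float)
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("dataset and method identifiers must be unique")
        if reasons is None:
            reasons = pd.DataFrame(
                np.where(values.isna(), FailureReason.ERROR.value, _NO_REASON),
                index=values.index, columns=values.columns,
            )
        reasons = reasons.reindex(index=values.index, columns=values.columns)
        bad = (values.isna() != (reasons != _NO_REASON)).to_numpy()
        if bad.any():
            raise ValueError("grid invariant violated: a cell is defined iff "
                             "its failure reason is 'none'")
        for r in np.unique(reasons.to_numpy()):
            FailureReason(r)  # raises on unknown vocabulary
        if truth is not None:
            truth = pd.Series(truth, index=values.index, dtype=float)
        self.values = values
        self.reasons = reasons
        self.truth = truth
        self.messages = messages

    # -- structure ---------------------------------------------------------
    @property
    def dataset_ids(self) -> list:
        return list(self.values.index)

    @property
    def method_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_datasets(self) -> int:
        return len(self.values.index)

    @property
    def failure_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def outcome(self, dataset, method) -> MethodOutcome:
        v = self.values.at[dataset, method]
        r = FailureReason(self.reasons.at[dataset, method])
        msg = ""
        if self.messages is not None:
            msg = str(self.messages.at[dataset, method])
        if r is FailureReason.NONE:
            return MethodOutcome(float(v), r, msg)
        return MethodOutcome(None, r, msg)

    def select_methods(self, methods: Sequence) -> "ResultsTable":
        return ResultsTable(
            self.values[list(methods)].copy(),
            self.reasons[list(methods)].copy(),
            None if self.truth is None else self.truth.copy(),
        )

    def copy(self) -> "ResultsTable":
        return ResultsTable(
            self.values.copy(), self.reasons.copy(),
            None if self.truth is None else self.truth.copy(),
            None if self.messages is None else self.messages.copy(),
        )

    def __repr__(self) -> str:  # pragma: no cover
        nf = int(self.failure_mask.to_numpy().sum())
        return (f"<ResultsTable {self.n_datasets} datasets x "
                f"{len(self.method_ids)} methods, {nf} failures>")


# ---------------------------------------------------------------------------
# evaluation


def evaluate_methods(
    methods: Mapping[str, Callable],
    datasets: Sequence,
    dataset_ids: Sequence | None = None,
    truth: Sequence[float] | None = None,
) -> ResultsTable:
    """Run every method on every data set, capturing failures.

    Any raised exception becomes a failure with reason ``error`` and the
    exception text as message; a non-finite or non-numeric return becomes
    ``invalid_value``.  No exception escapes, so the grid is always complete.
    """
    if not isinstance(methods, Mapping) or not methods:
        raise ValueError("methods must be a non-empty mapping of id -> callable")
    datasets = list(datasets)
    if not datasets:
        raise ValueError("datasets must be non-empty")
    if dataset_ids is None:
        dataset_ids = list(range(1, len(datasets) + 1))
    if len(dataset_ids) != len(datasets):
        raise ValueError("dataset_ids must match datasets in length")

    vals = np.full((len(datasets), len(methods)), np.nan)
    reas = np.full(vals.shape, _NO_REASON, dtype=object)
    msgs = np.full(vals.shape, "", dtype=object)
    for j, (mid, fn) in enumerate(methods.items()):
        for i, ds in enumerate(datasets):
            try:
                out = fn(ds)
            except Exception as exc:  # noqa: BLE001 - capture is the contract
                reas[i, j] = FailureReason.ERROR.value
                msgs[i, j] = f"{type(exc).__name__}: {exc}"
                continue
            try:
                x = float(out)
            except (TypeError, ValueError):
                reas[i, j] = FailureReason.INVALID_VALUE.value
                msgs[i, j] = f"non-numeric output {out!r}"
                continue
            if math.isfinite(x):
                vals[i, j] = x
            else:
                reas[i, j] = FailureReason.INVALID_VALUE.value
                msgs[i, j] = f"non-finite output {x!r}"
    cols = list(methods)
    truth_s = None if truth is None else pd.Series(list(truth), index=dataset_ids, dtype=float)
    return ResultsTable(
        pd.DataFrame(vals, index=dataset_ids, columns=cols),
        pd.DataFrame(reas, index=dataset_ids, columns=cols),
        truth_s,
        pd.DataFrame(msgs, index=dataset_ids, columns=cols),
    )


def failure_proportions(table: ResultsTable) -> pd.Series:
    """Per-method fraction of data sets on which the method failed."""
    return table.failure_mask.mean(axis=0).rename("failure_proportion")


# ---------------------------------------------------------------------------
# aggregation


def _aggregate_values(values: pd.Series, truth: pd.Series | None, spec: PerformanceSpec) -> float:
    """Aggregate one method's defined values (NaN already dropped upstream)."""
    if spec.measure is Measure.BIAS_RAW:
        return float((values - truth.loc[values.index]).mean())
    if spec.measure is Measure.BIAS_LOG:
        t = truth.loc[values.index]
        if (values <= 0).any() or (t <= 0).any():
            raise ValueError("bias_log requires positive values and truth")
        return float((np.log(values) - np.log(t)).mean())
    return float(values.mean())


def _check_truth(table: ResultsTable, spec: PerformanceSpec) -> None:
    if spec.is_bias_like and table.truth is None:
        raise ValueError(f"measure {spec.measure.value} needs per-dataset truth")


def aggregate_conditional(table: ResultsTable, spec: PerformanceSpec) -> pd.DataFrame:
    """Aggregate each method over *its own* non-failing data sets.

    This is "discard data sets for the failing methods only": each method's
    aggregate conditions on its own non-failure, so different methods may be
    summarized over different data sets.  A method failing everywhere gets an
    undefined (NaN) aggregate.  Returns a frame with columns ``value`` and
    ``n_used``.
    """
    _check_truth(table, spec)
    rows = {}
    for m in table.method_ids:
        col = table.values[m].dropna()
        val = _aggregate_values(col, table.truth, spec) if len(col) else np.nan
        rows[m] = (val, len(col))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["value", "n_used"])
    out["n_used"] = out["n_used"].astype(int)
    return out


def aggregate_complete_case(table: ResultsTable, spec: PerformanceSpec) -> pd.DataFrame:
    """Aggregate all methods over the data sets on which *no* method fails.

    The retained subset is identical across methods ("discard data sets
    associated with failure for all methods"); an empty intersection leaves
    every aggregate undefined.
    """
    _check_truth(table, spec)
    keep = ~table.failure_mask.any(axis=1)
    n = int(keep.sum())
    rows = {}
    for m in table.method_ids:
        col = table.values.loc[keep, m]
        val = _aggregate_values(col, table.truth, spec) if n else np.nan
        rows[m] = (val, n)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["value", "n_used"])
    out["n_used"] = out["n_used"].astype(int)
    return out


def _require_worst(spec: PerformanceSpec) -> float:
    if spec.worst_value is None:
        raise ValueError("worst_value must be set on the PerformanceSpec for "
                         "worst-value imputation")
    return float(spec.worst_value)


def impute_outcomes(
    table: ResultsTable,
    strategy: HandlingStrategy,
    spec: PerformanceSpec,
    seed: int | None = None,
) -> ResultsTable:
    """Return a copy of the table with failing cells filled per ``strategy``.

    The original table is untouched.  ``impute_mean_other_methods`` cannot
    resolve a data set on which *every* method fails; such rows keep their
    failures and are flagged with a warning.  ``impute_weighted`` acts on the
    aggregate, not on cells — use :func:`aggregate_with_handling`.  ``seed``
    is accepted for interface stability; every implemented rule is
    deterministic.
    """
    del seed
    kind = strategy.kind
    if kind in (HandlingKind.DISCARD_FAILING_ONLY, HandlingKind.DISCARD_ALL):
        raise ValueError(f"{kind.value} is a discarding strategy, not an imputation")
    if kind is HandlingKind.IMPUTE_WEIGHTED:
        raise ValueError("impute_weighted replaces the aggregate, not the cells; "
                         "use aggregate_with_handling")

    values = table.values.copy()
    reasons = table.reasons.copy()
    mask = table.failure_mask

    if kind is HandlingKind.IMPUTE_WORST:
        fill = pd.DataFrame(_require_worst(spec), index=values.index, columns=values.columns)
    elif kind is HandlingKind.IMPUTE_MEAN_OTHER_METHODS:
        # row mean over the other methods' defined values
        n_def = values.notna().sum(axis=1)
        row_sum = values.sum(axis=1)
        fill = pd.DataFrame(
            np.where(n_def.to_numpy() > 0,
                     (row_sum / n_def.replace(0, np.nan)).to_numpy(), np.nan)[:, None]
            * np.ones((1, values.shape[1])),
            index=values.index, columns=values.columns,
        )
        unresolved = n_def == 0
        if unresolved.any():
            bad = list(values.index[unresolved])
            warnings.warn(
                f"impute_mean_other_methods cannot resolve data sets {bad}: "
                "every method failed there; failures retained",
                stacklevel=2,
            )
            fill.loc[unresolved] = np.nan
    elif kind is HandlingKind.IMPUTE_METHOD_MEAN:
        fill = pd.DataFrame(
            np.ones((values.shape[0], 1)) * values.mean(axis=0).to_numpy()[None, :],
            index=values.index, columns=values.columns,
        )
    elif kind is HandlingKind.IMPUTE_HYBRID_THRESHOLD:
        f = failure_proportions(table)
        col_mean = values.mean(axis=0)
        worst = _require_worst(spec)
        per_method = np.where(f.to_numpy() > strategy.threshold, worst, col_mean.to_numpy())
        fill = pd.DataFrame(
            np.ones((values.shape[0], 1)) * per_method[None, :],
            index=values.index, columns=values.columns,
        )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown handling kind {kind!r}")

    filled = mask & fill.notna()
    values = values.where(~filled, fill)
    reasons = reasons.where(~filled, _NO_REASON)
    return ResultsTable(values, reasons, None if table.truth is None else table.truth.copy())


def aggregate_with_handling(
    table: ResultsTable,
    spec: PerformanceSpec,
    strategy: HandlingStrategy,
) -> pd.DataFrame:
    """Aggregate per method after applying a handling strategy.

    Dispatches to conditional aggregation (discard for failing methods
    only), complete-case aggregation (discard for all), cell imputation
    followed by aggregation over all data sets, or — for the weighted rule —
    the aggregate-level formula ``(1 - f) * conditional + f * worst`` with
    ``f`` the method's failure proportion.
    """
    kind = strategy.kind
    if kind is HandlingKind.DISCARD_FAILING_ONLY:
        return aggregate_conditional(table, spec)
    if kind is HandlingKind.DISCARD_ALL:
        return aggregate_complete_case(table, spec)
    if kind is HandlingKind.IMPUTE_WEIGHTED:
        worst = _require_worst(spec)
        cond = aggregate_conditional(table, spec)
        f = failure_proportions(table)
        out = cond.copy()
        weighted = (1.0 - f) * cond["value"] + f * worst
        # a method failing everywhere has no conditional part; f = 1 leaves worst
        out["value"] = np.where(f.to_numpy() >= 1.0, worst, weighted.to_numpy())
        out["n_used"] = table.n_datasets
        return out
    imputed = impute_outcomes(table, strategy, spec)
    return aggregate_conditional(imputed, spec)


# ---------------------------------------------------------------------------
# pipelines


@dataclass(frozen=True)
class PipelineColumn:
    """The single-method column a fallback pipeline induces.

    ``chosen_step[i]`` is the index (into ``spec.steps``) of the first
    non-failing step on data set i, or -1 when every step fails; the failure
    reason is then taken from the primary step.
    """

    spec: PipelineSpec
    values: pd.Series
    reasons: pd.Series
    chosen_step: pd.Series

    @property
    def failure_mask(self) -> pd.Series:
        return self.values.isna()


def apply_pipeline(pipeline: PipelineSpec, table: ResultsTable) -> PipelineColumn:
    """Evaluate a fallback pipeline on an existing results grid.

    Per data set, the outcome of the first non-failing step is used; the
    pipeline fails only where every step fails.  Consequently the pipeline's
    failure set is the intersection of its steps' failure sets.
    """
    missing = [s for s in pipeline.steps if s not in table.values.columns]
    if missing:
        raise KeyError(f"pipeline steps not in table: {missing}")
    vals = pd.Series(np.nan, index=table.values.index, dtype=float)
    reas = pd.Series(table.reasons[pipeline.primary].to_numpy(copy=True),
                     index=table.values.index)
    chosen = pd.Series(-1, index=table.values.index, dtype=int)
    for k, step in enumerate(pipeline.steps):
        col = table.values[step]
        use = vals.isna() & (chosen == -1) & col.notna()
        vals[use] = col[use]
        chosen[use] = k
    ok = chosen >= 0
    reas[ok] = _NO_REASON
    return PipelineColumn(pipeline, vals.rename(pipeline.name),
                          reas.rename(pipeline.name), chosen.rename(pipeline.name))


def pipeline_table(
    table: ResultsTable, pipelines: Sequence[PipelineSpec]
) -> ResultsTable:
    """Assemble the pipeline columns into a ResultsTable of their own."""
    cols = [apply_pipeline(p, table) for p in pipelines]
    values = pd.concat([c.values for c in cols], axis=1)
    reasons = pd.concat([c.reasons for c in cols], axis=1)
    return ResultsTable(values, reasons,
                        None if table.truth is None else table.truth.copy())


# ---------------------------------------------------------------------------
# ranking and reporting


def rank_methods(
    values: pd.Series | Mapping[str, float],
    orientation: Orientation = Orientation.LOWER_IS_BETTER,
    absolute: bool = False,
) -> pd.Series:
    """Rank methods (1 = best), averaging tied positions.

    ``absolute=True`` ranks on |value| — the convention for bias-type
    measures, where the best method is the one closest to zero.  Undefined
    values are refused: aggregate-level failures must be resolved (via a
    handling strategy or pipelines) before a ranking is meaningful.
    """
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        bad = list(s.index[s.isna()])
        raise ValueError(
            f"cannot rank methods with undefined aggregates {bad}; resolve "
            "method failure first (handling strategy or fallback pipeline)"
        )
    keys = s.abs() if absolute else s
    if Orientation(orientation) is Orientation.HIGHER_IS_BETTER:
        keys = -keys
    return pd.Series(rankdata(keys.to_numpy(), method="average"),
                     index=s.index, name="rank")


UNCONDITIONAL_CAVEAT = (
    "Aggregating performance despite undefined values does not assess "
    "unconditional performance: each summary conditions on some pattern of "
    "non-failure."
)


@dataclass(frozen=True)
class SlimReport:
    """The three-part minimal analysis: never one part without the others."""

    conditional: pd.DataFrame
    complete_case: pd.DataFrame
    failure_proportions: pd.Series
    caveat: str = field(default=UNCONDITIONAL_CAVEAT)


def slimmed_report(table: ResultsTable, spec: PerformanceSpec) -> SlimReport:
    """Emit (i) per-failing-method discarding, (ii) all-method discarding,
    and (iii) failure proportions, plus the fixed caveat, as one object."""
    return SlimReport(
        conditional=aggregate_conditional(table, spec),
        complete_case=aggregate_complete_case(table, spec),
        failure_proportions=failure_proportions(table),
    )


# ---------------------------------------------------------------------------
# CSV round-trip

_FAIL_PREFIX = "FAIL:"
_TRUTH_COL = "truth"
_INDEX_COL = "dataset_id"


def results_to_csv(table: ResultsTable, path) -> None:
    """Write the grid as UTF-8 CSV, failures encoded as ``FAIL:<reason>``."""
    out = pd.DataFrame(index=table.values.index)
    for m in table.method_ids:
        col = table.values[m].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        fails = table.failure_mask[m]
        col[fails] = _FAIL_PREFIX + table.reasons.loc[fails, m].astype(str)
        out[m] = col
    if table.truth is not None:
        out[_TRUTH_COL] = table.truth.map(lambda v: repr(float(v)))
    out.index.name = _INDEX_COL
    out.to_csv(path, encoding="utf-8")


def results_from_csv(path) -> ResultsTable:
    """Read a grid written by :func:`results_to_csv`."""
    raw = pd.read_csv(path, index_col=_INDEX_COL, dtype=str, keep_default_na=False)
    truth = None
    if _TRUTH_COL in raw.columns:
        truth = raw.pop(_TRUTH_COL).astype(float)
    vals = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    reas = pd.DataFrame(_NO_REASON, index=raw.index, columns=raw.columns, dtype=object)
    for m in raw.columns:
        is_fail = raw[m].str.startswith(_FAIL_PREFIX)
        vals.loc[~is_fail, m] = raw.loc[~is_fail, m].astype(float)
        reas.loc[is_fail, m] = raw.loc[is_fail, m].str[len(_FAIL_PREFIX):]
    return ResultsTable(vals, reas, truth)
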