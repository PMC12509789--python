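"""Coverage of resampling-based confidence intervals for the
generalization AUC, and the zero-variance failure mode of the naive one.

A model's generalization AUC is estimated by Monte-Carlo cross-validation
(subsampling): the data are split ``reps`` = 15 times into 80% training /
20% evaluation, giving AUC values whose mean and sample variance feed a
t-interval

    mean +- t_{0.975, reps-1} * sqrt((1/reps + c) * s2).

The *corrected* method (C) uses the variance-inflation constant c > 0 of
Nadeau and Bengio, which accounts for the overlap between the resampled
training sets; here c defaults to the test/train size ratio of the 4:1
split, c = 0.25.  The *naive* method (N) sets c = 0 — and, as implemented
with an off-the-shelf one-sample t-test, *fails* outright whenever the 15
AUC values are identical ("data are essentially constant").  That happens
exactly when the depth-limited classification tree makes no split in any
repetition, i.e. every AUC is 0.5.

The coverage study repeats, per iteration: generate a data set; hold out a
large test part (80%) to approximate the true AUC of a model trained on
the remaining 20%; run subsampling on that 20%; build both intervals; and
record whether each covers the approximated truth.  Failures of N flow
into a :class:`~methodfail.core.ResultsTable`, on which the handling
strategies (discarding, impute-as-noncovering, zero-width fix) operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist
from sklearn.tree import DecisionTreeClassifier

from .core import (
    FailureReason,
    HandlingKind,
    HandlingStrategy,
    Measure,
    Orientation,
    PerformanceSpec,
    ResultsTable,
    aggregate_complete_case,
    aggregate_conditional,
    aggregate_with_handling,
    failure_proportions,
)
from .datagen import generate_classification_dataset

__all__ = [
    "TreeParams",
    "SubsamplingEstimate",
    "CIResult",
    "CoverageConfig",
    "CoverageStudyResult",
    "COVERAGE_HANDLINGS",
    "train_tree",
    "auc",
    "subsampling_aucs",
    "ci_naive",
    "ci_corrected",
    "covers",
    "coverage_by_handling",
    "run_coverage_study",
]

#: tolerance of the coverage comparison: a zero-width interval sitting
#: exactly at the true value counts as covering
COVER_EPS = 1e-12

COVERAGE_HANDLINGS = ("discard_n_only", "discard_both",
                      "impute_noncovering", "zero_width_fix")


@dataclass(frozen=True)
class TreeParams:
    """Bounds of the Gini CART learner.

    ``min_impurity_decrease`` governs the no-split event: when no root
    split clears it, the fitted tree is a constant predictor and every AUC
    downstream is exactly 0.5.
    """

    max_depth: int = 2
    min_samples_leaf: int = 10
    min_impurity_decrease: float = 0.07


@dataclass(frozen=True)
class SubsamplingEstimate:
    """AUC values over the subsampling repetitions, their mean and
    sample variance (divisor reps - 1)."""

    auc_values: tuple[float, ...]
    mean: float
    s2: float

    @classmethod
    def from_values(cls, values) -> "SubsamplingEstimate":
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError("need at least two subsampling repetitions")
        return cls(tuple(arr.tolist()), float(arr.mean()), float(arr.var(ddof=1)))


@dataclass(frozen=True)
class CIResult:
    """A confidence interval, or an undefined marker when the method failed.

    ``c`` records the variance-correction constant used (0 for the naive
    method).
    """

    lower: float | None
    upper: float | None
    c: float
    defined: bool

    def __post_init__(self) -> None:
        if self.defined:
            if self.lower is None or self.upper is None or self.lower > self.upper:
                raise ValueError("a defined interval needs lower <= upper")
        elif self.lower is not None or self.upper is not None:
            raise ValueError("an undefined interval has no bounds")

    @property
    def width(self) -> float | None:
        return None if not self.defined else self.upper - self.lower


def train_tree(features, labels, tree_params: TreeParams = TreeParams(),
               seed: int = 0) -> DecisionTreeClassifier:
    """Fit a depth-limited Gini classification tree.

    When no root split achieves an impurity decrease above the threshold,
    the fitted tree is a single leaf — a constant predictor whose scores
    are all equal.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels must contain both classes")
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_depth=tree_params.max_depth,
        min_samples_leaf=tree_params.min_samples_leaf,
        min_impurity_decrease=tree_params.min_impurity_decrease,
        random_state=seed,
    )
    tree.fit(np.asarray(features), labels)
    return tree


def tree_scores(tree: DecisionTreeClassifier, features) -> np.ndarray:
    """Predicted probability of the positive class."""
    proba = tree.predict_proba(np.asarray(features))
    if proba.shape[1] == 1:  # pragma: no cover - guarded by train_tree
        return proba[:, 0]
    return proba[:, 1]


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 0.5.

    Computed from the rank-sum of the positive class; identical scores give
    exactly 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _split_indices(rng, n: int, train_fraction: float, labels, max_retries: int = 100):
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError("train fraction leaves an empty split")
    for _ in range(max_retries):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if (len(np.unique(labels[tr])) == 2 and len(np.unique(labels[te])) == 2):
            return tr, te
    raise RuntimeError(
        f"no split with both classes on both sides after {max_retries} tries "
        f"(n={n}, n_train={n_train})"
    )


def subsampling_aucs(
    features,
    labels,
    tree_params: TreeParams = TreeParams(),
    reps: int = 15,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SubsamplingEstimate:
    """``reps`` random train/evaluation splits; one AUC per repetition."""
    if reps < 2:
        raise ValueError("reps must be at least 2")
    features = np.asarray(features)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(reps):
        tr, te = _split_indices(rng, len(labels), train_fraction, labels)
        tree = train_tree(features[tr], labels[tr], tree_params)
        values.append(auc(tree_scores(tree, features[te]), labels[te]))
    return SubsamplingEstimate.from_values(values)


def ci_corrected(estimate: SubsamplingEstimate, c: float = 0.25,
                 level: float = 0.95) -> CIResult:
    """The variance-corrected t-interval; zero variance gives a zero-width
    interval at the mean rather than an error."""
    if c < 0:
        raise ValueError("correction constant c must be non-negative")
    reps = len(estimate.auc_values)
    q = t_dist.ppf(0.5 + level / 2.0, reps - 1)
    half = q * np.sqrt((1.0 / reps + c) * estimate.s2)
    return CIResult(estimate.mean - half, estimate.mean + half, c, True)


def ci_naive(estimate: SubsamplingEstimate, level: float = 0.95) -> CIResult:
    """The c = 0 interval via a plain one-sample t-procedure.

    By contract it *fails* (returns an undefined interval) when the sample
    variance is zero, reproducing the "data are essentially constant"
    error of off-the-shelf t-test implementations.
    """
    if estimate.s2 == 0.0:
        return CIResult(None, None, 0.0, False)
    return ci_corrected(estimate, c=0.0, level=level)


def covers(ci: CIResult, true_value: float, eps: float = COVER_EPS) -> bool | None:
    """Whether the interval covers ``true_value``; None when undefined."""
    if not ci.defined:
        return None
    return bool(ci.lower - eps <= true_value <= ci.upper + eps)


# ---------------------------------------------------------------------------
# the study


@dataclass(frozen=True)
class CoverageConfig:
    """Study conditions.

    The 1000-iteration default matches the illustration's scale; the
    generator emulates a benchmark data set on which a depth-limited tree
    sometimes (probability ``pi_null``) has nothing to split on.
    """

    n_iterations: int = 1000
    n_samples: int = 1000
    n_features: int = 10
    d: float = 2.0
    pi_null: float = 0.3
    test_fraction: float = 0.8
    subsample_reps: int = 15
    subsample_train_fraction: float = 0.8
    c: float = 0.25
    level: float = 0.95
    tree: TreeParams = field(default_factory=TreeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_fraction", "subsample_train_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.subsample_reps < 2:
            raise ValueError("subsample_reps must be at least 2")
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")


@dataclass(frozen=True)
class CoverageStudyResult:
    """Per-iteration records, the coverage table and failure proportions.

    ``coverage`` is indexed by handling with one column per method
    ('naive', 'corrected'); ``iterations`` holds one row per simulation
    iteration (true AUC, subsampling mean/variance, CI bounds or failure,
    coverage indicators).
    """

    coverage: pd.DataFrame
    failure_proportions: pd.Series
    iterations: pd.DataFrame
    table: ResultsTable


def coverage_by_handling(table: ResultsTable, zero_width_covers: pd.Series,
                         handlings=COVERAGE_HANDLINGS) -> pd.DataFrame:
    """Apply the four handlings to a coverage indicator table.

    ``table`` holds 0/1 coverage indicators with failures where a method
    produced no interval; ``zero_width_covers`` is the per-dataset
    indicator a zero-width repair would contribute where a cell failed.
    """
    spec = PerformanceSpec(Measure.COVERAGE, Orientation.HIGHER_IS_BETTER,
                           worst_value=0.0)
    rows = {}
    for h in handlings:
        if h == "discard_n_only":
            rows[h] = aggregate_conditional(table, spec)["value"]
        elif h == "discard_both":
            rows[h] = aggregate_complete_case(table, spec)["value"]
        elif h == "impute_noncovering":
            rows[h] = aggregate_with_handling(
                table, spec, HandlingStrategy(HandlingKind.IMPUTE_WORST))["value"]
        elif h == "zero_width_fix":
            values = table.values.copy()
            for m in table.method_ids:
                fails = table.failure_mask[m]
                values.loc[fails, m] = zero_width_covers[fails].astype(float)
            rows[h] = values.mean(axis=0)
        else:
            raise ValueError(f"unknown handling {h!r}")
    return pd.DataFrame(rows).T


def run_coverage_study(config: CoverageConfig,
                       handlings=COVERAGE_HANDLINGS) -> CoverageStudyResult:
    """Estimate the empirical coverage of the naive and corrected intervals
    under every requested handling of the naive method's failures."""
    rng = np.random.default_rng(config.seed)
    records = []
    for it in range(config.n_iterations):
        ds_seed = int(rng.integers(0, 2**31 - 1))
        ds = generate_classification_dataset(
            config.n_samples, config.n_features, config.d, config.pi_null,
            seed=ds_seed)
        # large held-out test part approximates the true AUC of a model
        # trained on the small train part
        te, tr = _split_indices(rng, config.n_samples, config.test_fraction,
                                ds.labels)
        model = train_tree(ds.features[tr], ds.labels[tr], config.tree)
        true_auc = auc(tree_scores(model, ds.features[te]), ds.labels[te])
        est = subsampling_aucs(
            ds.features[tr], ds.labels[tr], config.tree,
            reps=config.subsample_reps,
            train_fraction=config.subsample_train_fraction,
            seed=int(rng.integers(0, 2**31 - 1)))
        ci_n = ci_naive(est, level=config.level)
        ci_c = ci_corrected(est, c=config.c, level=config.level)
        records.append({
            "iteration": it, "is_null": ds.is_null, "true_auc": true_auc,
            "mean_auc": est.mean, "s2": est.s2,
            "naive_defined": ci_n.defined,
            "naive_lower": ci_n.lower, "naive_upper": ci_n.upper,
            "corrected_lower": ci_c.lower, "corrected_upper": ci_c.upper,
            "naive_covers": covers(ci_n, true_auc),
            "corrected_covers": covers(ci_c, true_auc),
            "zero_width_covers": abs(est.mean - true_auc) <= COVER_EPS,
        })
    iters = pd.DataFrame(records).set_index("iteration")

    values = pd.DataFrame({
        "naive": iters["naive_covers"].map(
            lambda v: np.nan if v is None else float(v)),
        "corrected": iters["corrected_covers"].astype(float),
    })
    reasons = pd.DataFrame(
        np.where(values.isna(), FailureReason.ERROR.value,
                 FailureReason.NONE.value),
        index=values.index, columns=values.columns)
    table = ResultsTable(values, reasons)
    coverage = coverage_by_handling(table, iters["zero_width_covers"], handlings)
    return CoverageStudyResult(
        coverage=coverage,
        failure_proportions=failure_proportions(table),
        iterations=iters,
        table=table,
    )
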