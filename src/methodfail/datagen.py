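"""Seeded generators for everything the illustration studies consume.

Three kinds of inputs are produced here, so the whole repository runs from
nothing but a seed:

* multinomial 2x2 outcome-exposure tables for the odds-ratio study, with an
  exact inclusion-exclusion oracle for the probability of a sampling zero;
* binary-response classification data sets in which a depth-limited tree
  sometimes makes no split (the zero-variance failure mode of the CI study);
* small fictive results grids in the style used throughout when introducing
  the handling strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import FailureReason, ResultsTable

__all__ = [
    "Scenario2x2",
    "ContingencyTable",
    "ClassificationDataset",
    "TABLE5_SCENARIOS",
    "simulate_tables",
    "sampling_zero_probability_exact",
    "generate_classification_dataset",
    "generate_fictive_results_table",
    "fictive_overview_table",
]


class ContingencyTable(NamedTuple):
    """2x2 counts: exposed-case, exposed-noncase, unexposed-case, unexposed-noncase."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def n_obs(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def has_sampling_zero(self) -> bool:
        return min(self) == 0


@dataclass(frozen=True)
class Scenario2x2:
    """A simulation scenario for 2x2 outcome-exposure tables.

    One table is a single multinomial draw of size ``n_obs`` over the four
    cell probabilities implied by the exposure probability ``px``, the
    baseline outcome probability ``p0`` = P(Y=1 | X=0) and the true odds
    ratio (``p1`` = P(Y=1 | X=1) follows from the odds ratio).  ``p0``
    defaults to 0.5, the value under which the exact sampling-zero
    probabilities agree with the study's reported proportions.
    """

    n_obs: int
    true_or: float
    px: float
    p0: float = 0.5

    def __post_init__(self) -> None:
        if self.n_obs <= 0:
            raise ValueError("n_obs must be positive")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not 0.0 < self.px < 1.0 or not 0.0 < self.p0 < 1.0:
            raise ValueError("px and p0 must lie in (0, 1)")

    @property
    def p1(self) -> float:
        """P(Y=1 | X=1) implied by the odds ratio and baseline probability."""
        odds0 = self.p0 / (1.0 - self.p0)
        return self.true_or * odds0 / (1.0 + self.true_or * odds0)

    @property
    def cell_probs(self) -> np.ndarray:
        """Probabilities of (n11, n10, n01, n00); they sum to one."""
        p1, px, p0 = self.p1, self.px, self.p0
        return np.array([px * p1, px * (1.0 - p1),
                         (1.0 - px) * p0, (1.0 - px) * (1.0 - p0)])


#: The four canonical scenarios (fixed n_obs = 50, p0 = 0.5).
TABLE5_SCENARIOS: tuple[Scenario2x2, ...] = (
    Scenario2x2(50, 2.0, 0.25),
    Scenario2x2(50, 5.0, 0.25),
    Scenario2x2(50, 2.0, 0.5),
    Scenario2x2(50, 5.0, 0.5),
)


def simulate_tables(scenario: Scenario2x2, n_sims: int, seed: int) -> np.ndarray:
    """Draw ``n_sims`` tables; returns an (n_sims, 4) integer array.

    Columns are (n11, n10, n01, n00); each row sums to ``scenario.n_obs``
    and converts to a :class:`ContingencyTable` via ``ContingencyTable(*row)``.
    Identical (scenario, n_sims, seed) give identical output.
    """
    if n_sims <= 0:
        raise ValueError("n_sims must be positive")
    rng = np.random.default_rng(seed)
    return rng.multinomial(scenario.n_obs, scenario.cell_probs, size=n_sims)


def sampling_zero_fraction(tables: np.ndarray) -> float:
    """Fraction of simulated tables with at least one empty cell."""
    return float((np.asarray(tables).min(axis=1) == 0).mean())


def sampling_zero_probability_exact(scenario: Scenario2x2) -> float:
    """P(at least one empty cell) by inclusion-exclusion over the four cells.

    For every non-empty subset S of cells, the probability that all cells in
    S are empty is (1 - sum of their probabilities)^n_obs; alternating signs
    over subset sizes give the union probability exactly.
    """
    p = scenario.cell_probs
    n = scenario.n_obs
    total = 0.0
    for k in range(1, 5):
        for subset in combinations(range(4), k):
            rest = max(1.0 - p[list(subset)].sum(), 0.0)  # guard fp underflow
            total += (-1) ** (k + 1) * rest**n
    return min(max(total, 0.0), 1.0)


# ---------------------------------------------------------------------------
# classification data for the CI study


@dataclass(frozen=True)
class ClassificationDataset:
    """A binary-response data set with at most one informative feature.

    With probability ``pi_null`` the data set carries no signal (features
    independent of labels); otherwise feature 0 has a standardized mean
    shift ``signal`` between the classes.  Labels are balanced in
    expectation and always contain both classes.
    """

    features: np.ndarray
    labels: np.ndarray
    signal: float
    pi_null: float
    is_null: bool


def generate_classification_dataset(
    n_samples: int,
    n_features: int,
    d: float,
    pi_null: float,
    seed: int,
    max_retries: int = 1000,
) -> ClassificationDataset:
    """Generate one data set; see :class:`ClassificationDataset`."""
    if n_samples < 40:
        raise ValueError("n_samples must be at least 40")
    if n_features < 1:
        raise ValueError("n_features must be at least 1")
    if d < 0:
        raise ValueError("effect size d must be non-negative")
    if not 0.0 <= pi_null <= 1.0:
        raise ValueError("pi_null must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_null = bool(rng.random() < pi_null)
    for _ in range(max_retries):
        labels = rng.integers(0, 2, size=n_samples)
        if labels.any() and not labels.all():
            break
    else:  # pragma: no cover - P(degenerate) = 2^-n_samples per try
        raise RuntimeError("could not draw labels containing both classes")
    features = rng.standard_normal((n_samples, n_features))
    effective_d = 0.0 if is_null else float(d)
    features[:, 0] += effective_d * labels
    return ClassificationDataset(features, labels, effective_d, pi_null, is_null)


# ---------------------------------------------------------------------------
# fictive results grids

# the printed overview grid: four repetitions x three methods, truth 4,
# with two failures ("NA" cells)
_FICTIVE_VALUES = [
    [3.89, 4.23, 4.08],
    [3.78, 4.13, 4.11],
    [np.nan, 3.69, 4.23],
    [3.75, 4.24, np.nan],
]


def fictive_overview_table() -> ResultsTable:
    """The named fixture: the printed 4x3 overview grid with truth 4."""
    idx = pd.Index([1, 2, 3, 4], name="repetition")
    cols = ["Method 1", "Method 2", "Method 3"]
    values = pd.DataFrame(_FICTIVE_VALUES, index=idx, columns=cols)
    reasons = pd.DataFrame(
        np.where(values.isna(), FailureReason.NONCONVERGENCE.value,
                 FailureReason.NONE.value),
        index=idx, columns=cols,
    )
    return ResultsTable(values, reasons, pd.Series(4.0, index=idx))


def generate_fictive_results_table(
    seed: int,
    n_datasets: int = 4,
    n_methods: int = 3,
    failure_prob: float = 0.25,
    truth: float = 4.0,
    scale: float = 0.2,
) -> ResultsTable:
    """A random small grid in the fictive-study style.

    Values are Normal(truth, scale); each cell independently fails with
    probability ``failure_prob`` (reason ``nonconvergence``).  Same seed,
    same table.
    """
    rng = np.random.default_rng(seed)
    vals = rng.normal(truth, scale, size=(n_datasets, n_methods))
    fail = rng.random((n_datasets, n_methods)) < failure_prob
    vals[fail] = np.nan
    idx = pd.Index(range(1, n_datasets + 1), name="repetition")
    cols = [f"Method {j + 1}" for j in range(n_methods)]
    values = pd.DataFrame(vals, index=idx, columns=cols)
    reasons = pd.DataFrame(
        np.where(fail, FailureReason.NONCONVERGENCE.value, FailureReason.NONE.value),
        index=idx, columns=cols,
    )
    return ResultsTable(values, reasons, pd.Series(float(truth), index=idx))
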