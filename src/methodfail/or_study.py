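"""Odds-ratio estimation under sampling zeros: estimators, failure
semantics, fallback pipelines, and the simulation study around them.

Five point estimators of the odds ratio psi of a 2x2 table are compared:

``manual``
    The cross-product ratio n11*n00 / (n10*n01).  An empty off-diagonal
    cell makes it infinite, an empty diagonal cell makes it zero — both
    non-meaningful, so both count as failure.
``woolf``
    The add-0.5 cross-product (every cell + 0.5), applied unconditionally.
    Always finite and positive; shrinks toward 1 relative to ``manual``.
``small``
    Jewell's small-sample estimator n11*n00 / ((n10+1)(n01+1)).  Survives
    zeros in the off-diagonal cells; returns 0 when n11*n00 = 0, which by
    default is flagged as failure (a zero odds ratio cannot enter a
    log-scale comparison).
``fisher``
    The conditional MLE under the noncentral hypergeometric model obtained
    by conditioning on both margins; fails when n11 sits at a bound of the
    conditional support (the MLE is then 0 or infinite).
``midp``
    The median-unbiased estimate: the psi at which the mid-distribution
    function P(A > n11) + 0.5 P(A = n11) of the same conditional model
    equals one half; fails at the support bounds (no finite root).

A sixth pseudo-method ``ha`` re-estimates with the manual formula on the
Haldane-Anscombe-corrected table (+0.5 on all cells) and never fails; it is
the natural fallback a practitioner reaches for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import (
    FailureReason,
    Measure,
    Orientation,
    PerformanceSpec,
    PipelineSpec,
    ResultsTable,
    aggregate_complete_case,
    aggregate_conditional,
    failure_proportions,
    pipeline_table,
    rank_methods,
)
from .datagen import (
    ContingencyTable,
    Scenario2x2,
    sampling_zero_fraction,
    sampling_zero_probability_exact,
    simulate_tables,
)

__all__ = [
    "OREstimate",
    "ORStudyConfig",
    "ORStudyResult",
    "ESTIMATOR_IDS",
    "or_manual",
    "or_woolf",
    "or_small",
    "or_fisher_cmle",
    "or_midp",
    "haldane_anscombe",
    "estimate_batch",
    "evaluate_estimators",
    "build_pipelines",
    "log_bias",
    "run_or_study",
]

ESTIMATOR_IDS = ("manual", "fisher", "midp", "small", "woolf")

#: Bisection bracket in log psi; expanded (doubled) at most twice.
_BRACKET = 12.0
_MAX_EXPANSIONS = 2
_BISECT_ITERS = 64  # final bracket width 96 / 2^64 << the 1e-8 tolerance


@dataclass(frozen=True)
class OREstimate:
    """A single odds-ratio point estimate or a typed failure."""

    psi_hat: float | None
    estimator_id: str
    failed: bool
    failure_reason: FailureReason = FailureReason.NONE
    message: str = ""


def _ok(psi: float, estimator_id: str) -> OREstimate:
    return OREstimate(float(psi), estimator_id, False)


def _fail(estimator_id: str, reason: FailureReason, message: str) -> OREstimate:
    return OREstimate(None, estimator_id, True, reason, message)


def _counts(table) -> tuple[int, int, int, int]:
    n11, n10, n01, n00 = (int(x) for x in table)
    if min(n11, n10, n01, n00) < 0:
        raise ValueError("cell counts must be non-negative")
    return n11, n10, n01, n00


# ---------------------------------------------------------------------------
# closed-form estimators


def or_manual(table) -> OREstimate:
    """Cross-product ratio; fails on any empty cell (estimate 0 or inf)."""
    n11, n10, n01, n00 = _counts(table)
    if n10 == 0 or n01 == 0:
        return _fail("manual", FailureReason.INVALID_VALUE,
                     "division by zero: infinite odds-ratio estimate")
    psi = (n11 * n00) / (n10 * n01)
    if psi == 0.0:
        return _fail("manual", FailureReason.INVALID_VALUE,
                     "zero odds-ratio estimate")
    return _ok(psi, "manual")


def haldane_anscombe(table) -> tuple[float, float, float, float]:
    """Add 0.5 to every cell; the corrected table never breaks ``manual``."""
    n11, n10, n01, n00 = _counts(table)
    return (n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5)


def or_woolf(table) -> OREstimate:
    """Add-0.5 cross-product, applied unconditionally; never fails."""
    n11, n10, n01, n00 = _counts(table)
    psi = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
    return _ok(psi, "woolf")


def or_small(table, zero_is_failure: bool = True) -> OREstimate:
    """Jewell's estimator n11*n00 / ((n10+1)(n01+1)).

    Defined for zeros in the off-diagonal cells; a zero numerator gives a
    non-meaningful estimate of 0, flagged as failure by default.
    """
    n11, n10, n01, n00 = _counts(table)
    psi = (n11 * n00) / ((n10 + 1) * (n01 + 1))
    if psi == 0.0 and zero_is_failure:
        return _fail("small", FailureReason.INVALID_VALUE,
                     "zero odds-ratio estimate (empty diagonal cell)")
    return _ok(psi, "small")


# ---------------------------------------------------------------------------
# conditional model (both margins fixed): vectorized solver

_NEG_INF = -np.inf


def _support(a, m1, m0, r):
    """Conditional support bounds for the exposed-case count."""
    lo = np.maximum(0, r - m0)
    hi = np.minimum(r, m1)
    return lo, hi


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


class _CondModel:
    """Noncentral-hypergeometric machinery, vectorized over B tables.

    The conditional probability of observing A = a exposed cases given both
    margins is proportional to C(m1, a) C(m0, r - a) psi^a over the support
    a in [max(0, r - m0), min(r, m1)].
    """

    def __init__(self, tables: np.ndarray) -> None:
        t = np.asarray(tables, dtype=np.int64)
        self.a = t[:, 0]
        self.m1 = t[:, 0] + t[:, 1]
        self.m0 = t[:, 2] + t[:, 3]
        self.r = t[:, 0] + t[:, 2]
        self.lo, self.hi = _support(self.a, self.m1, self.m0, self.r)
        width = int((self.hi - self.lo).max()) + 1 if len(t) else 1
        grid = self.lo[:, None] + np.arange(width)[None, :]
        self.mask = grid <= self.hi[:, None]
        grid_c = np.clip(grid, 0, self.m1[:, None])
        rest_c = np.clip(self.r[:, None] - grid, 0, self.m0[:, None])
        logw = (_log_binom(self.m1[:, None], grid_c)
                + _log_binom(self.m0[:, None], rest_c))
        self.logw = np.where(self.mask, logw, _NEG_INF)
        self.grid = np.where(self.mask, grid, 0)

    @property
    def at_bound(self) -> np.ndarray:
        """True where the observed count sits at a support bound (degenerate
        single-point supports included)."""
        return (self.a == self.lo) | (self.a == self.hi)

    def _weights(self, log_psi: np.ndarray):
        logits = self.logw + self.grid * log_psi[:, None]
        top = logits.max(axis=1, keepdims=True)
        w = np.exp(logits - top)
        w[~self.mask] = 0.0
        return w, w.sum(axis=1)

    def mean_residual(self, log_psi: np.ndarray) -> np.ndarray:
        """E_psi[A] - n11; strictly increasing in psi on interior tables."""
        w, z = self._weights(log_psi)
        return (self.grid * w).sum(axis=1) / z - self.a

    def midp_residual(self, log_psi: np.ndarray) -> np.ndarray:
        """P(A > n11) + 0.5 P(A = n11) - 0.5; increasing in psi."""
        w, z = self._weights(log_psi)
        above = (w * (self.grid > self.a[:, None])).sum(axis=1)
        at = (w * (self.grid == self.a[:, None])).sum(axis=1)
        return (above + 0.5 * at) / z - 0.5


def _bisect(model: _CondModel, residual, solve: np.ndarray):
    """Monotone bisection in log psi on the rows selected by ``solve``.

    Returns (log_psi, converged) for all rows; unsolved rows hold NaN.
    """
    b = len(model.a)
    out = np.full(b, np.nan)
    converged = np.zeros(b, dtype=bool)
    idx = np.flatnonzero(solve)
    if idx.size == 0:
        return out, converged
    lo = np.full(idx.size, -_BRACKET)
    hi = np.full(idx.size, _BRACKET)
    sub = _CondModel.__new__(_CondModel)
    for name in ("a", "m1", "m0", "r", "lo", "hi", "mask", "logw", "grid"):
        setattr(sub, name, getattr(model, name)[idx])
    g = lambda x: residual(sub, x)  # noqa: E731
    for _ in range(_MAX_EXPANSIONS):
        bad_lo = g(lo) > 0
        bad_hi = g(hi) < 0
        if not (bad_lo.any() or bad_hi.any()):
            break
        lo[bad_lo] *= 2.0
        hi[bad_hi] *= 2.0
    bracketed = (g(lo) <= 0) & (g(hi) >= 0)
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        high = g(mid) > 0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    out[idx[bracketed]] = (0.5 * (lo + hi))[bracketed]
    converged[idx[bracketed]] = True
    return out, converged


def _conditional_batch(tables: np.ndarray, residual):
    """Solve the conditional model on every table; vectorized with padding.

    Returns (psi_hat with NaN at failures, reasons array of str).
    """
    t = np.asarray(tables, dtype=np.int64)
    model = _CondModel(t)
    reasons = np.full(len(t), FailureReason.NONE.value, dtype=object)
    bound = model.at_bound
    reasons[bound] = FailureReason.INVALID_VALUE.value
    log_psi, converged = _bisect(model, residual, ~bound)
    reasons[~bound & ~converged] = FailureReason.NONCONVERGENCE.value
    psi = np.where(converged, np.exp(log_psi), np.nan)
    return psi, reasons


def cmle_batch(tables: np.ndarray):
    """Conditional MLE for a batch of tables (NaN where failed)."""
    return _conditional_batch(tables, _CondModel.mean_residual)


def midp_batch(tables: np.ndarray):
    """Mid-p median-unbiased estimate for a batch of tables."""
    return _conditional_batch(tables, _CondModel.midp_residual)


def _scalar_conditional(table, batch, estimator_id: str) -> OREstimate:
    n11, n10, n01, n00 = _counts(table)
    psi, reasons = batch(np.array([[n11, n10, n01, n00]]))
    reason = FailureReason(reasons[0])
    if reason is FailureReason.NONE:
        return _ok(psi[0], estimator_id)
    if reason is FailureReason.INVALID_VALUE:
        msg = "observed count at conditional support bound (estimate 0 or inf)"
    else:
        msg = "root bracketing failed after bound expansion"
    return _fail(estimator_id, reason, msg)


def or_fisher_cmle(table) -> OREstimate:
    """Conditional MLE of the odds ratio (both margins fixed).

    Solves E_psi[A] = n11 by monotone bisection in log psi; the solution is
    located to well below 1e-8 absolute in log psi.
    """
    return _scalar_conditional(table, cmle_batch, "fisher")


def or_midp(table) -> OREstimate:
    """Median-unbiased mid-p estimate under the conditional model."""
    return _scalar_conditional(table, midp_batch, "midp")


# ---------------------------------------------------------------------------
# batch evaluation and pipelines


def estimate_batch(tables: np.ndarray, zero_is_failure: bool = True) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """All five estimators plus ``ha`` on an (n, 4) array of tables.

    Returns per method a (values, reasons) pair; values hold NaN at
    failures.  The ``fisher``/``midp`` solvers run once per *distinct*
    table and are broadcast back, which keeps 100k-draw scenarios cheap.
    """
    t = np.asarray(tables, dtype=np.int64)
    a, b, c, d = (t[:, k].astype(float) for k in range(4))
    none = FailureReason.NONE.value
    invalid = FailureReason.INVALID_VALUE.value
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    with np.errstate(divide="ignore", invalid="ignore"):
        manual = (a * d) / (b * c)
    man_fail = (b == 0) | (c == 0) | (a * d == 0)
    out["manual"] = (np.where(man_fail, np.nan, manual),
                     np.where(man_fail, invalid, none).astype(object))

    uniq, inverse = np.unique(t, axis=0, return_inverse=True)
    for mid, batch in (("fisher", cmle_batch), ("midp", midp_batch)):
        psi_u, reas_u = batch(uniq)
        out[mid] = (psi_u[inverse], reas_u[inverse])

    small = (a * d) / ((b + 1) * (c + 1))
    small_fail = (small == 0) & zero_is_failure
    out["small"] = (np.where(small_fail, np.nan, small),
                    np.where(small_fail, invalid, none).astype(object))

    woolf = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    out["woolf"] = (woolf, np.full(len(t), none, dtype=object))
    out["ha"] = (woolf.copy(), np.full(len(t), none, dtype=object))
    return out


def evaluate_estimators(
    tables: np.ndarray,
    true_or: float | None = None,
    zero_is_failure: bool = True,
) -> ResultsTable:
    """Build the datasets x methods grid for a batch of simulated tables."""
    est = estimate_batch(tables, zero_is_failure=zero_is_failure)
    idx = pd.RangeIndex(len(np.asarray(tables)), name="table")
    values = pd.DataFrame({m: v for m, (v, _) in est.items()}, index=idx)
    reasons = pd.DataFrame({m: r for m, (_, r) in est.items()}, index=idx)
    truth = None if true_or is None else pd.Series(float(true_or), index=idx)
    return ResultsTable(values, reasons, truth)


def build_pipelines() -> list[PipelineSpec]:
    """The canonical nine compared entities: pure methods and pipelines.

    ``manual`` falls back only on the Haldane-Anscombe correction (a user
    computing the odds ratio by hand will not reach for conditional
    inference); ``midp`` and ``fisher`` each get the correction, ``small``
    or ``woolf`` as alternatives; ``small`` and ``woolf`` handle zeros
    internally and stand alone.
    """
    return [
        PipelineSpec(("manual", "ha"), max_fallbacks=1),
        PipelineSpec(("midp", "ha"), max_fallbacks=1),
        PipelineSpec(("midp", "small"), max_fallbacks=1),
        PipelineSpec(("midp", "woolf"), max_fallbacks=1),
        PipelineSpec(("fisher", "ha"), max_fallbacks=1),
        PipelineSpec(("fisher", "small"), max_fallbacks=1),
        PipelineSpec(("fisher", "woolf"), max_fallbacks=1),
        PipelineSpec(("small",), max_fallbacks=1),
        PipelineSpec(("woolf",), max_fallbacks=1),
    ]


def log_bias(estimates, true_or: float) -> float:
    """mean(log psi_hat) - log(true odds ratio) over defined estimates.

    Accepts floats or :class:`OREstimate`; any failure or non-positive
    value is refused — the caller must resolve failures first.
    """
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    vals = []
    for e in estimates:
        if isinstance(e, OREstimate):
            if e.failed:
                raise ValueError("log_bias got a failed estimate; handle failures first")
            e = e.psi_hat
        e = float(e)
        if e <= 0:
            raise ValueError("log_bias requires positive estimates")
        vals.append(e)
    if not vals:
        raise ValueError("no estimates given")
    return float(np.mean(np.log(vals)) - np.log(true_or))


# ---------------------------------------------------------------------------
# the study


@dataclass(frozen=True)
class ORStudyConfig:
    scenarios: tuple[Scenario2x2, ...]
    n_sims: int = 100_000
    seed: int = 0
    zero_is_failure: bool = True
    pipelines: tuple[PipelineSpec, ...] = field(
        default_factory=lambda: tuple(build_pipelines()))


@dataclass(frozen=True)
class ORStudyResult:
    """Long-format study output.

    ``zeros`` has one row per scenario (empirical and exact sampling-zero
    proportion); ``regimes`` one row per (scenario, regime, method) with the
    log-scale bias, the number of data sets it used, the method's failure
    proportion, and its within-regime rank on |log bias|.  For the pipeline
    regime the failure proportion is the *residual* failure proportion after
    fallbacks, and any residual failures are listed in
    ``residual_failures``.
    """

    zeros: pd.DataFrame
    regimes: pd.DataFrame
    residual_failures: pd.DataFrame


def _scenario_seed(seed: int, index: int) -> int:
    # per-scenario substream; kept below 2^31 for portability
    return (seed * 1009 + index) % (2**31 - 1)


def run_or_study(config: ORStudyConfig) -> ORStudyResult:
    """Simulate every scenario and compare the estimators under three
    regimes: discarding for the failing methods only, discarding for all
    methods, and the nine fallback pipelines."""
    if not config.scenarios:
        raise ValueError("config needs at least one scenario")
    spec = PerformanceSpec(Measure.BIAS_LOG, Orientation.LOWER_IS_BETTER)
    zero_rows = []
    regime_rows = []
    residual_rows = []
    for i, scn in enumerate(config.scenarios, start=1):
        tables = simulate_tables(scn, config.n_sims, _scenario_seed(config.seed, i))
        zero_rows.append({
            "scenario": i, "true_or": scn.true_or, "px": scn.px,
            "n_obs": scn.n_obs, "n_sims": config.n_sims,
            "sampling_zero_prop": sampling_zero_fraction(tables),
            "sampling_zero_prob_exact": sampling_zero_probability_exact(scn),
        })
        full = evaluate_estimators(tables, true_or=scn.true_or,
                                   zero_is_failure=config.zero_is_failure)
        pure = full.select_methods(list(ESTIMATOR_IDS))
        fprop = failure_proportions(pure)

        for regime, agg in (
            ("discard_failing_only", aggregate_conditional(pure, spec)),
            ("discard_all", aggregate_complete_case(pure, spec)),
        ):
            ranks = rank_methods(agg["value"], Orientation.LOWER_IS_BETTER,
                                 absolute=True)
            for m in pure.method_ids:
                regime_rows.append({
                    "scenario": i, "regime": regime, "method": m,
                    "log_bias": agg.at[m, "value"],
                    "n_used": int(agg.at[m, "n_used"]),
                    "failure_proportion": float(fprop[m]),
                    "rank": float(ranks[m]),
                })

        ptab = pipeline_table(full, list(config.pipelines))
        pagg = aggregate_conditional(ptab, spec)
        pfail = failure_proportions(ptab)
        pranks = rank_methods(pagg["value"], Orientation.LOWER_IS_BETTER,
                              absolute=True)
        for p in config.pipelines:
            name = p.name
            regime_rows.append({
                "scenario": i, "regime": "fallback_pipelines", "method": name,
                "log_bias": pagg.at[name, "value"],
                "n_used": int(pagg.at[name, "n_used"]),
                "failure_proportion": float(pfail[name]),
                "rank": float(pranks[name]),
            })
            if pfail[name] > 0:
                residual_rows.append({
                    "scenario": i, "pipeline": name,
                    "n_residual_failures": int(pfail[name] * config.n_sims + 0.5),
                    "residual_proportion": float(pfail[name]),
                })
    residual = pd.DataFrame(
        residual_rows,
        columns=["scenario", "pipeline", "n_residual_failures", "residual_proportion"],
    )
    return ORStudyResult(pd.DataFrame(zero_rows), pd.DataFrame(regime_rows), residual)
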