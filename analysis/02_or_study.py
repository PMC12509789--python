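#!/usr/bin/env python
"""The odds-ratio comparison study: how the handling of sampling-zero
failures reshuffles the method ranking.

Runs the full study (100 000 simulated tables per scenario, five
estimators) and compares log-scale bias under three regimes:

* discarding failing data sets for the failing methods only,
* discarding them for all methods,
* nine fallback pipelines evaluated as single entities.

Findings to look for in the output: the two discarding regimes disagree
on the ranking even at ~1% sampling zeros (Woolf profits from being
scored on all tables in one regime and only on the shared zero-free
subset in the other); the pipeline regime makes the comparison
unconditional — except for a handful of flagged residual failures in
pipelines that fall back on the small-sample estimator, which itself
returns a non-meaningful zero when a table has no exposed cases.
"""

import argparse
from pathlib import Path

from methodfail.datagen import TABLE5_SCENARIOS
from methodfail.or_study import ORStudyConfig, run_or_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20250923)
    parser.add_argument("--n-sims", type=int, default=100_000)
    args = parser.parse_args()

    res = run_or_study(ORStudyConfig(
        scenarios=TABLE5_SCENARIOS, n_sims=args.n_sims, seed=args.seed))

    RESULTS.mkdir(exist_ok=True)
    res.zeros.to_csv(RESULTS / "or_sampling_zeros.csv", index=False)
    res.regimes.to_csv(RESULTS / "or_regimes.csv", index=False)
    res.residual_failures.to_csv(RESULTS / "or_residual_failures.csv", index=False)

    ranks = res.regimes.pivot_table(
        index=["regime", "method"], columns="scenario", values="rank")
    print("per-scenario ranks on |log bias| (1 = best):")
    print(ranks.to_string(float_format=lambda v: f"{v:.1f}"))
    if len(res.residual_failures):
        print("\nresidual pipeline failures after fallbacks (flagged, not hidden):")
        print(res.residual_failures.to_string(index=False))
    else:
        print("\nno residual pipeline failures: fallbacks covered every failure.")
    print(f"\nwrote {RESULTS / 'or_regimes.csv'}")


if __name__ == "__main__":
    main()
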