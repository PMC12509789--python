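#!/usr/bin/env python
"""Coverage of the naive vs variance-corrected t-interval for the
generalization AUC, under four handlings of the naive method's failures.

Per iteration a synthetic binary-response data set is generated (30% of
data sets carry no signal, so a depth-limited tree makes no split and
all 15 subsampled AUCs equal 0.5); the naive interval then fails with a
zero sample variance while the corrected interval degrades gracefully.

Findings to look for: the naive method's failure proportion sits near
0.3; its coverage depends strongly on the handling (imputing failures as
non-covering < discarding < zero-width repair — the repair adds exactly
the failure proportion because the no-split AUC of 0.5 is also the true
AUC there); the corrected interval covers at a much higher rate and
never fails.
"""

import argparse
from pathlib import Path

from methodfail.ci_study import CoverageConfig, run_coverage_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20250923)
    parser.add_argument("--n-iterations", type=int, default=1000)
    args = parser.parse_args()

    res = run_coverage_study(CoverageConfig(
        n_iterations=args.n_iterations, seed=args.seed))

    RESULTS.mkdir(exist_ok=True)
    res.coverage.to_csv(RESULTS / "ci_coverage.csv")
    res.failure_proportions.to_csv(RESULTS / "ci_failure_proportions.csv")

    print("empirical coverage by handling:")
    print(res.coverage.to_string(float_format=lambda v: f"{v:.3f}"))
    print("\nfailure proportions (reported alongside, always):")
    print(res.failure_proportions.to_string(float_format=lambda v: f"{v:.3f}"))
    print(f"\nwrote {RESULTS / 'ci_coverage.csv'}")


if __name__ == "__main__":
    main()
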