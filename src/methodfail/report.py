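"""Failure reporting and run manifests.

Reporting the occurrence and proportion of method failure is itself part of
the analysis: the failure proportion is treated as an additional
performance measure, and the circumstances of each failure (which method,
which data set, why) are the evidence a reader needs to judge a method's
usability.  Every study run also emits a manifest tying outputs to the
seed and configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import scipy
import sklearn

from . import __version__
from .core import PerformanceSpec, ResultsTable, SlimReport, failure_proportions

__all__ = ["FailureReport", "RunManifest", "report_failures",
           "log_failures", "slim_report_text", "slim_report_json"]

logger = logging.getLogger("methodfail")


@dataclass(frozen=True)
class FailureReport:
    """Per-method failure proportions plus free-text cause annotations."""

    proportions: pd.Series
    counts: pd.Series
    n_datasets: int
    annotations: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_datasets": self.n_datasets,
            "methods": {
                str(m): {
                    "failure_proportion": float(self.proportions[m]),
                    "n_failures": int(self.counts[m]),
                    "annotation": self.annotations.get(str(m), ""),
                }
                for m in self.proportions.index
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"Method failure report ({self.n_datasets} data sets)"]
        for m in self.proportions.index:
            line = (f"  {m}: failure proportion "
                    f"{self.proportions[m]:.4g} ({int(self.counts[m])} failures)")
            note = self.annotations.get(str(m), "")
            if note:
                line += f" — {note}"
            lines.append(line)
        return "\n".join(lines)


def report_failures(table: ResultsTable,
                    annotations: dict[str, str] | None = None) -> FailureReport:
    """Failure proportions as an additional performance measure.

    ``annotations`` carries the author's description of the interplay
    causing each method's failures; the text is passed through verbatim to
    both the machine-readable and the human-readable rendering.
    """
    props = failure_proportions(table)
    counts = table.failure_mask.sum(axis=0)
    return FailureReport(props, counts, table.n_datasets, dict(annotations or {}))


def log_failures(table: ResultsTable) -> int:
    """Emit one structured log record per failing cell; returns the count.

    Each record names the data set, the method, the failure reason, and any
    captured message — the minimal evidence for investigating the
    method-data interplay behind the failure.
    """
    n = 0
    mask = table.failure_mask
    for m in table.method_ids:
        for ds in table.values.index[mask[m]]:
            out = table.outcome(ds, m)
            logger.warning(
                "method failure: dataset=%r method=%r reason=%s message=%r",
                ds, m, out.failure_reason.value, out.message)
            n += 1
    return n


def slim_report_json(report: SlimReport) -> str:
    """The three-part summary as JSON; the caveat is always included."""
    payload = {
        "discard_failing_only": {
            str(m): {"value": _none_if_nan(report.conditional.at[m, "value"]),
                     "n_used": int(report.conditional.at[m, "n_used"])}
            for m in report.conditional.index
        },
        "discard_all": {
            str(m): {"value": _none_if_nan(report.complete_case.at[m, "value"]),
                     "n_used": int(report.complete_case.at[m, "n_used"])}
            for m in report.complete_case.index
        },
        "failure_proportions": {
            str(m): float(v) for m, v in report.failure_proportions.items()
        },
        "caveat": report.caveat,
    }
    return json.dumps(payload, indent=2)


def slim_report_text(report: SlimReport) -> str:
    lines = ["(i) discard data sets for the failing methods only:"]
    for m in report.conditional.index:
        lines.append(f"    {m}: {report.conditional.at[m, 'value']:.4g} "
                     f"(n={int(report.conditional.at[m, 'n_used'])})")
    lines.append("(ii) discard data sets with any failure for all methods:")
    for m in report.complete_case.index:
        lines.append(f"    {m}: {report.complete_case.at[m, 'value']:.4g} "
                     f"(n={int(report.complete_case.at[m, 'n_used'])})")
    lines.append("(iii) failure proportions:")
    for m, v in report.failure_proportions.items():
        lines.append(f"    {m}: {v:.4g}")
    lines.append(f"NOTE: {report.caveat}")
    return "\n".join(lines)


def _none_if_nan(v: float):
    return None if pd.isna(v) else float(v)


@dataclass(frozen=True)
class RunManifest:
    """What produced a set of outputs: seed, config digest, versions.

    Two runs with the same digest, seed, and versions produce identical
    outputs; the timestamp is informational and excluded from the digest.
    """

    seed: int
    config_digest: str
    created: str
    versions: dict[str, str]

    @classmethod
    def create(cls, seed: int, config: dict) -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        return cls(
            seed=seed,
            config_digest=digest,
            created=datetime.now(timezone.utc).isoformat(),
            versions={
                "methodfail": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
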