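import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methodfail.core import FailureReason, ResultsTable
from methodfail.datagen import fictive_overview_table

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def overview_table() -> ResultsTable:
    """The printed 4x3 fictive grid (truth 4, two failures)."""
    return fictive_overview_table()


def make_table(values, truth=None, reason=FailureReason.ERROR.value) -> ResultsTable:
    """Build a ResultsTable from a nested-list/frame spec; NaN cells fail."""
    values = pd.DataFrame(values, dtype=float)
    reasons = pd.DataFrame(
        values.isna().to_numpy(), index=values.index, columns=values.columns
    ).replace({True: reason, False: FailureReason.NONE.value})
    t = None if truth is None else pd.Series(truth, index=values.index, dtype=float)
    return ResultsTable(values, reasons, t)
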