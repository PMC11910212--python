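import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regensig.ranking import FoldChangeTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_fc(experiment_id: str, values: dict) -> FoldChangeTable:
    """Fold-change table from a {gene: log2fc} dict (test helper)."""
    s = pd.Series(values, dtype=float).rename("log2fc")
    n = pd.Series(1, index=s.index, name="n_probes")
    return FoldChangeTable(experiment_id=experiment_id, log2fc=s, n_probes=n)


@pytest.fixture
def worked_study():
    """The 6-gene, 3-experiment study whose aggregate ranks are hand-computed.

    E3 ties A and B at log2fc 1, so both receive the average rank 2.5 there.
    """
    return [
        make_fc("E1", {"A": 3, "B": 2, "C": 1, "D": 0, "E": -1, "F": -2}),
        make_fc("E2", {"A": 2, "B": 3, "C": 0, "D": 1, "E": -2, "F": -1}),
        make_fc("E3", {"A": 1, "B": 1, "C": 2, "D": -1, "E": 0, "F": -3}),
    ]


WORKED_MEAN_RANKS = {
    "A": (1 + 2 + 2.5) / 3,
    "B": (2 + 1 + 2.5) / 3,
    "C": (3 + 4 + 1) / 3,
    "D": (4 + 3 + 5) / 3,
    "E": (5 + 6 + 4) / 3,
    "F": (6 + 5 + 6) / 3,
}
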