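import numpy as np
import pandas as pd
import pytest

from morscore import synthetic_data as synth
from morscore.signature_selection import default_mor_panel


@pytest.fixture(scope="session")
def table2():
    """Packaged 25-patient reference cohort (marker −ΔCq, ΔVAS, metadata)."""
    return synth.table2_fixture()


@pytest.fixture(scope="session")
def table2_delta_cq(table2):
    """Table 2 marker values converted to the internal ΔCq convention."""
    panel = default_mor_panel()
    return -table2[list(panel.assays)]


@pytest.fixture(scope="session")
def table2_scores():
    return synth.table2_expected_scores()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_vas_frame(records: dict[str, dict[int, float]]) -> pd.DataFrame:
    rows = [(pid, day, vas) for pid, recs in records.items() for day, vas in recs.items()]
    return pd.DataFrame(rows, columns=["patient", "day", "vas_mm"])
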