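import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mitebn import COMPONENTS, PanelTable

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")


def make_panel(rows: list[dict]) -> PanelTable:
    """Build a PanelTable from sparse row dicts (unlisted components = 0)."""
    records = []
    for i, row in enumerate(rows):
        rec = {"id": row.get("id", f"P{i:03d}"), "age": row.get("age", 10.0),
               "tIgE": row.get("tIgE", 100.0)}
        for comp in COMPONENTS:
            rec[comp] = row.get(comp, 0.0)
        records.append(rec)
    return PanelTable(pd.DataFrame(records, columns=["id", "age", "tIgE", *COMPONENTS]))


@pytest.fixture
def small_panel() -> PanelTable:
    """Three patients: a multi-sensitized child, a mono-sensitized adult and
    a negative child."""
    return make_panel(
        [
            {"id": "A", "age": 5.0, "Der f 1": 12.5, "Der f 2": 3.2, "Der p 23": 0.31},
            {"id": "B", "age": 40.0, "Der p 2": 0.8},
            {"id": "C", "age": 2.0, "tIgE": 55.0},
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
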