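import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

from crpcohort.config import GeneratorConfig, RunConfig
from crpcohort.simulate import generate

BASE = pd.Timestamp("2015-06-01")


def d(offset_days: int) -> pd.Timestamp:
    """A date *offset_days* after the toy baseline date."""
    return BASE + pd.Timedelta(days=offset_days)


def crp_df(rows):
    """Toy raw-CRP frame from (patient_id, day_offset, value) triples."""
    return pd.DataFrame({
        "patient_id": [r[0] for r in rows],
        "date": [d(r[1]) for r in rows],
        "value": [float(r[2]) for r in rows],
    })


def event_df(rows, code_col, code="X"):
    """Toy event frame from (patient_id, day_offset[, code]) tuples."""
    return pd.DataFrame({
        "patient_id": [r[0] for r in rows],
        "date": [d(r[1]) for r in rows],
        code_col: [(r[2] if len(r) > 2 else code) for r in rows],
    })


def empty_events(code_col):
    return pd.DataFrame({"patient_id": [], "date": pd.Series([], dtype="datetime64[ns]"),
                         code_col: []})


@pytest.fixture(scope="session")
def small_run():
    """A moderate synthetic cohort shared across read-only tests."""
    cfg = RunConfig(generator=GeneratorConfig(n_patients=800, seed=7))
    store, truth = generate(cfg)
    return cfg, store, truth
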