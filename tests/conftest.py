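"""Shared fixtures: small synthetic cohorts and hand-built timelines."""

import numpy as np
import pandas as pd
import pytest

from ehrisk.events import DIAG, LAB_ABN, MED
from ehrisk.synthetic import CodeSpec, SimulationConfig, generate_cohort_stream

EPOCH = pd.Timestamp("2010-01-01")


def day(offset: int) -> pd.Timestamp:
    return EPOCH + pd.Timedelta(days=int(offset))


def timeline(pid: str, events: list[tuple[int, str, str]]) -> pd.DataFrame:
    """Build a per-patient timeline from (day_offset, code_type, code)."""
    rows = sorted(events)
    return pd.DataFrame(
        {
            "patient_id": pid,
            "date": [day(d) for d, _, _ in rows],
            "code_type": [t for _, t, _ in rows],
            "code": [c for _, _, c in rows],
        }
    )


def small_catalog(prevalence: float = 0.15, n: int = 12) -> list[CodeSpec]:
    types = [DIAG, MED, LAB_ABN]
    return [CodeSpec(f"C{i:02d}", types[i % 3], prevalence) for i in range(n)]


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient cohort with two planted effects, shared across tests."""
    cfg = SimulationConfig(
        n_patients=300,
        code_catalog=small_catalog(),
        effects={"C00": 1.0, "C01": -1.0},
        baseline_logit=-1.0,
        seed=42,
    )
    stream, truth = generate_cohort_stream(cfg)
    return cfg, stream, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
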