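"""Event-stream container conventions and I/O.

An event stream is a pandas DataFrame with one row per (patient, date,
code_type, code) and ISO-8601 dates. Code types distinguish diagnoses,
medications, abnormal-lab flags, and (after Method-2 substitution) protein
targets.
"""

from __future__ import annotations

import pandas as pd

DIAG = "DIAG"
MED = "MED"
LAB_ABN = "LAB_ABN"
TARGET = "TARGET"

CODE_TYPES = (DIAG, MED, LAB_ABN, TARGET)

STREAM_COLUMNS = ["patient_id", "date", "code_type", "code"]

# Reserved clinical codes the cohort rules key on. The synthetic generator
# plants these; real streams map their own code sets via CohortSpec.
AD_CODE = "AD_DX"
PSYCHOSIS_CODE = "PSYCHOSIS_DX"
ANTIPSYCHOTIC_CODE = "ANTIPSYCH_RX"
DELIRIUM_CODE = "DELIRIUM_DX"


def empty_stream() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "date": pd.Series(dtype="datetime64[ns]"),
            "code_type": pd.Series(dtype=str),
            "code": pd.Series(dtype=str),
        }
    )


def validate_stream(stream: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STREAM_COLUMNS if c not in stream.columns]
    if missing:
        raise ValueError(f"event stream missing columns: {missing}")
    bad = set(stream["code_type"].unique()) - set(CODE_TYPES)
    if bad:
        raise ValueError(f"unknown code_type values: {sorted(bad)}")
    return stream


def write_stream(stream: pd.DataFrame, path) -> None:
    out = stream.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[STREAM_COLUMNS].to_csv(path, index=False)


def read_stream(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "code_type": str, "code": str})
    df["date"] = pd.to_datetime(df["date"])
    return validate_stream(df[STREAM_COLUMNS])
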