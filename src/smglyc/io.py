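"""Format reference and CSV helpers for the four input streams.

All files are UTF-8 CSV with "." as the decimal mark and ISO-8601 dates.
Column names are fixed here; every reader validates the header before
returning a DataFrame so downstream stages can rely on the schema.

Input streams
-------------
patients.csv  patient_id, rurality_code (0=rural, 1=urban), age, income_band
              (0 = < $35k, 1 = >= $35k), visits
hba1c.csv     patient_id, date (ISO-8601), value (HbA1c %)
messages.csv  patient_id, thread_id, timestamp (ISO-8601), sender
              ("patient"/"team"), plus one 0/1 column per health topic
dsmq.csv      patient_id, item_01 .. item_16 (0-3, blank = missing)
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError

TOPICS = (
    "diabetes",
    "blood_pressure",
    "cholesterol",
    "physical_activity",
    "diet_nutrition",
    "mental_health",
)

PATIENTS_COLUMNS = ["patient_id", "rurality_code", "age", "income_band", "visits"]
HBA1C_COLUMNS = ["patient_id", "date", "value"]
MESSAGES_COLUMNS = ["patient_id", "thread_id", "timestamp", "sender", *TOPICS]
DSMQ_COLUMNS = ["patient_id"] + [f"item_{i:02d}" for i in range(1, 17)]

SENDER_VALUES = ("patient", "team")


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PATIENTS_COLUMNS, "patients")
    bad = set(df["rurality_code"].dropna().unique()) - {0, 1}
    if bad:
        raise ValidationError(f"patients: rurality_code must be 0/1, found {sorted(bad)}")
    return df


def read_hba1c(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, HBA1C_COLUMNS, "hba1c")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


def read_messages(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, MESSAGES_COLUMNS, "messages")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    bad = set(df["sender"].unique()) - set(SENDER_VALUES)
    if bad:
        raise ValidationError(f"messages: sender must be one of {SENDER_VALUES}, found {sorted(bad)}")
    return df


def read_dsmq(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, DSMQ_COLUMNS, "dsmq")
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
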