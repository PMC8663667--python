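"""Scoring for the 16-item Diabetes Self-Management Questionnaire (DSMQ).

Responses run from 0 ("does not apply to me") to 3 ("applies to me very
much").  Reverse-worded items are transformed r -> 3 - r, each subscale is
scaled to 0-10 as ``sum / (3 * n_answered) * 10`` (prorating over answered
items), and the composite -- the mediator in the structural analysis -- is
the arithmetic mean of the four subscale scores, again 0-10 with higher
values indicating more self-management.

A subscale is scored only if strictly more than half of its items were
answered; otherwise that subscale, and therefore the composite, are
returned as missing (NaN), never as an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

SUBSCALE_NAMES = (
    "glucose_management",
    "dietary_control",
    "physical_activity",
    "health_care_use",
)

ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, 17)]


@dataclass(frozen=True)
class Instrument:
    """A configurable DSMQ scoring key (item map, reverse flags, missing rule)."""

    name: str
    n_items: int
    response_min: int
    response_max: int
    subscales: dict  # subscale name -> tuple of 1-based item numbers
    reverse_items: frozenset
    min_answered_fraction: float

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Instrument":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw["name"],
            n_items=int(raw["n_items"]),
            response_min=int(raw["response_min"]),
            response_max=int(raw["response_max"]),
            subscales={k: tuple(v) for k, v in raw["subscales"].items()},
            reverse_items=frozenset(raw["reverse_items"]),
            min_answered_fraction=float(raw["min_answered_fraction"]),
        )

    @property
    def max_transformed(self) -> int:
        return self.response_max - self.response_min


@lru_cache(maxsize=1)
def default_instrument() -> Instrument:
    ref = resources.files("smglyc").joinpath("data/dsmq_instrument.yaml")
    with resources.as_file(ref) as path:
        return Instrument.from_yaml(path)


@dataclass(frozen=True)
class DSMQScore:
    patient_id: object
    subscale_scores: dict  # subscale name -> float or NaN
    composite: float  # NaN if any subscale is missing


def transform_items(items, instrument: Instrument) -> np.ndarray:
    """Validate and reverse-code a 16-vector of raw responses (NaN = missing)."""
    arr = np.asarray(items, dtype=float)
    if arr.shape != (instrument.n_items,):
        raise ValidationError(
            f"items: expected {instrument.n_items} responses, got shape {arr.shape}"
        )
    answered = ~np.isnan(arr)
    bad = answered & (
        (arr < instrument.response_min)
        | (arr > instrument.response_max)
        | (arr != np.round(arr))
    )
    if bad.any():
        idx = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(
            f"items: item_{idx:02d} value {arr[idx - 1]} outside "
            f"{{{instrument.response_min}..{instrument.response_max}}}"
        )
    out = arr.copy()
    for i in instrument.reverse_items:
        if answered[i - 1]:
            out[i - 1] = instrument.response_max - arr[i - 1]
    return out


def score_dsmq(patient_id, items, instrument: Instrument | None = None) -> DSMQScore:
    """Score one respondent's 16 item responses into subscales and composite."""
    instrument = instrument or default_instrument()
    t = transform_items(items, instrument)
    sub = {}
    for name, item_nums in instrument.subscales.items():
        vals = t[[i - 1 for i in item_nums]]
        answered = vals[~np.isnan(vals)]
        if len(answered) / len(item_nums) <= instrument.min_answered_fraction:
            sub[name] = float("nan")
            continue
        sub[name] = float(
            answered.sum() / (instrument.max_transformed * len(answered)) * 10.0
        )
    scores = [sub[name] for name in instrument.subscales]
    composite = float("nan") if any(math.isnan(s) for s in scores) else float(np.mean(scores))
    return DSMQScore(patient_id=patient_id, subscale_scores=sub, composite=composite)


def score_all(dsmq: pd.DataFrame, instrument: Instrument | None = None) -> pd.DataFrame:
    """Score a dsmq.csv-shaped table (patient_id, item_01..item_16)."""
    instrument = instrument or default_instrument()
    rows = []
    for _, row in dsmq.iterrows():
        s = score_dsmq(row["patient_id"], row[ITEM_COLUMNS].to_numpy(dtype=float), instrument)
        rows.append(
            dict(patient_id=s.patient_id, **s.subscale_scores, composite=s.composite)
        )
    return pd.DataFrame(rows, columns=["patient_id", *instrument.subscales, "composite"])
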