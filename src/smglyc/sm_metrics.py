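"""Secure-messaging exposure metrics and portal-use eligibility rules.

The exposure of interest is months-with-use: the number of calendar months
in a year (0-12) during which the patient sent at least one secure message.
Only patient-sent messages count toward exposure; team-sent messages are
retained for thread topic coding, since a patient "engages in" a thread by
reading and receiving as well as sending.

Timestamps are compared naively in a single timezone; month boundaries are
calendar months of that timezone.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io import TOPICS

CURRENT_USE_WINDOW = (dt.date(2016, 1, 1), dt.date(2017, 6, 30))  # inclusive
SUSTAINED_USE_YEARS = (2013, 2014, 2015)
SUSTAINED_MIN_SM_PER_YEAR = 2
SUSTAINED_MIN_QUALIFYING_YEARS = 2
CURRENT_MIN_SM = 4


def _patient_sent(messages: pd.DataFrame, patient_id=None) -> pd.DataFrame:
    df = messages
    if patient_id is not None:
        df = df[df["patient_id"] == patient_id]
    return df[df["sender"] == "patient"]


def months_with_message(messages: pd.DataFrame, patient_id, year: int) -> int:
    """Distinct calendar months of ``year`` containing >= 1 patient-sent message."""
    df = _patient_sent(messages, patient_id)
    ts = pd.to_datetime(df["timestamp"])
    in_year = ts[ts.dt.year == year]
    return int(in_year.dt.month.nunique())


def is_current_user(messages: pd.DataFrame, patient_id) -> bool:
    """Recent-use rule: >= 4 patient-sent messages in Jan 2016 - Jun 2017 inclusive."""
    df = _patient_sent(messages, patient_id)
    ts = pd.to_datetime(df["timestamp"])
    lo, hi = CURRENT_USE_WINDOW
    in_window = (ts.dt.date >= lo) & (ts.dt.date <= hi)
    return int(in_window.sum()) >= CURRENT_MIN_SM


@dataclass(frozen=True)
class PortalActivityYear:
    """Per-year portal activity flags used by the sustained-use rule."""

    year: int
    used_refills: bool
    viewed_downloaded: bool
    n_sm: int


def is_sustained_user(activity: list[PortalActivityYear]) -> bool:
    """Repeated-use rule over 2013-2015.

    True iff at least 2 years in the window satisfy, within the same year,
    all of: prescription refills used, health information viewed or
    downloaded, and >= 2 secure messages.  Years missing from ``activity``
    count as all-false.
    """
    by_year = {a.year: a for a in activity}
    qualifying = 0
    for year in SUSTAINED_USE_YEARS:
        a = by_year.get(year)
        if a is None:
            continue
        if a.used_refills and a.viewed_downloaded and a.n_sm >= SUSTAINED_MIN_SM_PER_YEAR:
            qualifying += 1
    return qualifying >= SUSTAINED_MIN_QUALIFYING_YEARS


def collapse_thread_topics(thread: pd.DataFrame) -> dict:
    """Thread-level topic flags: OR over the thread's messages.

    If any message in a thread touches a topic, the whole thread is coded
    for that topic.
    """
    if len(thread) == 0:
        raise ValidationError("thread: empty thread has no topic coding")
    if thread["thread_id"].nunique() > 1:
        raise ValidationError("thread: messages span multiple thread_ids")
    return {t: bool(thread[t].astype(bool).any()) for t in TOPICS}


def patient_topic_indicator(messages: pd.DataFrame, patient_id) -> dict:
    """Per-topic OR over a patient's thread-level flags (no threads: all False)."""
    df = messages[messages["patient_id"] == patient_id]
    if len(df) == 0:
        return {t: False for t in TOPICS}
    thread_flags = df.groupby("thread_id")[list(TOPICS)].any()
    return {t: bool(thread_flags[t].any()) for t in TOPICS}


def summarize_patient(messages: pd.DataFrame, patient_id, year: int) -> dict:
    """SMUsageSummary row for one patient-year."""
    df = messages[messages["patient_id"] == patient_id]
    ts = pd.to_datetime(df["timestamp"])
    in_year = df[ts.dt.year == year]
    topics = patient_topic_indicator(in_year, patient_id)
    return dict(
        patient_id=patient_id,
        year=year,
        months_with_message=months_with_message(messages, patient_id, year),
        n_messages=int(len(in_year)),
        n_threads=int(in_year["thread_id"].nunique()),
        **{f"topic_{t}": topics[t] for t in TOPICS},
    )


def summarize_all(messages: pd.DataFrame, patient_ids, year: int) -> pd.DataFrame:
    """SM usage summary for every patient in ``patient_ids``.

    Vectorized equivalent of calling :func:`summarize_patient` per patient;
    a patient with no in-year messages gets months_with_message 0,
    zero counts and all-false topic indicators.
    """
    patient_ids = list(patient_ids)
    ts = pd.to_datetime(messages["timestamp"])
    in_year = messages[ts.dt.year == year].copy()
    in_year["_month"] = pd.to_datetime(in_year["timestamp"]).dt.month

    sent = in_year[in_year["sender"] == "patient"]
    months = sent.groupby("patient_id")["_month"].nunique()
    n_messages = in_year.groupby("patient_id").size()
    n_threads = in_year.groupby("patient_id")["thread_id"].nunique()
    if len(in_year):
        thread_flags = in_year.groupby(["patient_id", "thread_id"])[list(TOPICS)].any()
        patient_flags = thread_flags.groupby(level="patient_id").any()
    else:
        patient_flags = pd.DataFrame(columns=list(TOPICS))

    out = pd.DataFrame({"patient_id": patient_ids, "year": year})
    out["months_with_message"] = (
        out["patient_id"].map(months).fillna(0).astype(int)
    )
    out["n_messages"] = out["patient_id"].map(n_messages).fillna(0).astype(int)
    out["n_threads"] = out["patient_id"].map(n_threads).fillna(0).astype(int)
    for t in TOPICS:
        col = patient_flags[t] if t in patient_flags.columns else pd.Series(dtype=bool)
        out[f"topic_{t}"] = col.reindex(patient_ids, fill_value=False).to_numpy(dtype=bool)
    return out
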