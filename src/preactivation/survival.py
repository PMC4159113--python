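"""Kaplan-Meier estimation, Mantel-Cox (log-rank) tests, responder fractions.

Product-limit estimation and the two-group log-rank test are delegated to
lifelines; this module fixes the record types, validation and output
conventions used by the rest of the pipeline (events precede censorings at
tied times, chi-square form without continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalRecord",
    "ResponseRecord",
    "RESPONSE_CATEGORIES",
    "RESPONDER_CATEGORIES",
    "km_curve",
    "logrank_test",
    "response_fraction",
]

RESPONSE_CATEGORIES = ("complete", "partial", "stable_progressive")
RESPONDER_CATEGORIES = frozenset({"complete", "partial"})


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time on study, event indicator, stratum."""

    sample_id: str
    time: float
    event: bool
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(
                f"negative survival time {self.time} for {self.sample_id!r}"
            )


@dataclass(frozen=True)
class ResponseRecord:
    """One sample's therapy response category and stratum."""

    sample_id: str
    category: str
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.category not in RESPONSE_CATEGORIES:
            raise ValueError(
                f"unknown response category {self.category!r}; "
                f"expected one of {RESPONSE_CATEGORIES}"
            )


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return times, events


def km_curve(records: Sequence[SurvivalRecord]) -> list[tuple[float, float]]:
    """Product-limit survival estimate as ordered (time, S(time)) pairs.

    The first pair is (0, 1); one pair follows per distinct event time with
    the post-event survival.  Censored times shrink the risk set only.
    """
    records = list(records)
    if not records:
        raise ValueError("no survival records")
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    event_times = tbl.index[tbl["observed"] > 0]
    sf = kmf.survival_function_[kmf.survival_function_.columns[0]]
    curve = [(0.0, 1.0)]
    for t in event_times:
        curve.append((float(t), float(sf.loc[t])))
    return curve


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel-Cox test of survival difference between two groups.

    Returns (chi-square statistic with 1 df, p-value).  No continuity
    correction is applied.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def response_fraction(records: Sequence[ResponseRecord]) -> dict[str, float]:
    """Fraction of responders (complete + partial) per stratum."""
    records = list(records)
    if not records:
        raise ValueError("no response records")
    counts: dict[str, list[int]] = {}
    for r in records:
        if r.stratum is None:
            raise ValueError(f"record {r.sample_id!r} has no stratum")
        tot_resp = counts.setdefault(r.stratum, [0, 0])
        tot_resp[0] += 1
        if r.category in RESPONDER_CATEGORIES:
            tot_resp[1] += 1
    return {stratum: resp / tot for stratum, (tot, resp) in counts.items()}


def survival_records_from_frame(
    df: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    stratum_col: str | None = "stratum",
) -> list[SurvivalRecord]:
    """Build records from a table indexed by sample id."""
    out = []
    for sid, row in df.iterrows():
        stratum = None
        if stratum_col is not None and stratum_col in df.columns:
            stratum = str(row[stratum_col])
        out.append(
            SurvivalRecord(
                sample_id=str(sid),
                time=float(row[time_col]),
                event=bool(row[event_col]),
                stratum=stratum,
            )
        )
    return out


def response_records_from_frame(
    df: pd.DataFrame,
    category_col: str = "response",
    stratum_col: str = "stratum",
) -> list[ResponseRecord]:
    """Build response records from a table indexed by sample id."""
    return [
        ResponseRecord(
            sample_id=str(sid),
            category=str(row[category_col]),
            stratum=str(row[stratum_col]),
        )
        for sid, row in df.iterrows()
    ]
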