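"""Behavioral endpoints of the courtship assay.

Four endpoints summarize each male's hour with a virgin female:

* **courtship latency** — seconds from observation start to the first wing
  vibration (the conventional marker of courtship initiation); males that do
  not initiate within 10 minutes are excluded from latency/CI analyses;
* **courtship index (CI)** — percentage of the first 10 minutes spent in any
  courtship component (orientation, tapping, following, wing
  extension/vibration, licking, attempted copulation), overlaps counted once;
* **copulation success** — the male mounted the female continuously for more
  than one minute within the one-hour window;
* **reproduction success** — offspring were recovered after the mating,
  summarized per stratum (angle class × female genotype × mating duration).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .detect import CopulationCall

__all__ = [
    "COURTSHIP_COMPONENTS",
    "EventLog",
    "CourtshipMetrics",
    "courtship_latency",
    "courtship_index",
    "copulation_success",
    "summarize_groups",
    "format_rate",
]

#: the six pre-copulation courtship components scored in the assay
COURTSHIP_COMPONENTS = (
    "orientation",
    "tapping",
    "following",
    "wing_vibration",
    "licking",
    "attempted_copulation",
)

_EVENT_TYPES = COURTSHIP_COMPONENTS + ("copulation",)
_LOG_COLUMNS = ["assay_id", "fly", "event_type", "start_s", "end_s", "truncated"]


@dataclass
class EventLog:
    """Typed, timestamped behavioral intervals for one assay.

    Backed by a DataFrame with columns ``assay_id, fly, event_type, start_s,
    end_s, truncated``.  ``fly`` is ``male``, ``female`` or ``pair``
    (copulation involves both).
    """

    df: pd.DataFrame
    assay_id: str = "assay"

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _LOG_COLUMNS:
            if col not in df.columns:
                if col == "assay_id":
                    df[col] = self.assay_id
                elif col == "fly":
                    df[col] = "male"
                elif col == "truncated":
                    df[col] = 0
                else:
                    raise ValueError(f"event log missing column {col!r}")
        bad = set(df["event_type"]) - set(_EVENT_TYPES) - {"idle"}
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")
        if (df["end_s"] < df["start_s"]).any():
            raise ValueError("event with end_s < start_s")
        self.df = df[_LOG_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, float, float]], assay_id: str = "assay"
    ) -> "EventLog":
        rows = [
            {"assay_id": assay_id, "fly": "pair" if ev == "copulation" else "male",
             "event_type": ev, "start_s": s, "end_s": e, "truncated": 0}
            for ev, s, e in intervals
        ]
        df = pd.DataFrame(rows, columns=_LOG_COLUMNS)
        return cls(df=df, assay_id=assay_id)

    def events(self, event_type: str) -> pd.DataFrame:
        return self.df[self.df["event_type"] == event_type]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, assay_id: str | None = None) -> "EventLog":
        df = pd.read_csv(path)
        aid = assay_id or (str(df["assay_id"].iloc[0]) if len(df) else "assay")
        return cls(df=df, assay_id=aid)


@dataclass(frozen=True)
class CourtshipMetrics:
    """Per-assay endpoint bundle; ``excluded_reason`` is None when included."""

    assay_id: str
    latency_s: float | None
    courtship_index_pct: float | None
    copulation_success: bool
    copulation_window_s: float
    excluded_reason: str | None


def courtship_latency(log: EventLog, initiation_window_s: float = 600.0) -> float | None:
    """Latency to the first wing vibration, or None (excluded).

    A male that does not start wing vibration within the initiation window
    (10 minutes by default) is excluded from the latency and CI analyses.
    """
    wv = log.events("wing_vibration")
    if len(wv) == 0:
        return None
    first = float(wv["start_s"].min())
    return first if first <= initiation_window_s else None


def _union_length(intervals: Sequence[tuple[float, float]]) -> float:
    """Total length of the union of possibly-overlapping intervals."""
    if not intervals:
        return 0.0
    ivs = sorted(intervals)
    total = 0.0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def courtship_index(log: EventLog, window_s: float = 600.0) -> float | None:
    """Percentage of the observation window spent in any courtship component.

    Component intervals are clipped to ``[0, window_s]`` and their union taken,
    so simultaneous components are counted once and the CI never exceeds 100.
    Copulation itself is not a courtship component and does not enter the
    numerator.  A male with no courtship initiation is excluded (None).
    """
    df = log.df[log.df["event_type"].isin(COURTSHIP_COMPONENTS)]
    if len(df) == 0:
        return None
    clipped = [
        (max(0.0, s), min(window_s, e))
        for s, e in zip(df["start_s"], df["end_s"])
        if e > 0 and s < window_s
    ]
    return 100.0 * _union_length([iv for iv in clipped if iv[1] > iv[0]]) / window_s


class ConflictingSourcesError(ValueError):
    """Raised when detector call and event log disagree on copulation success."""


def copulation_success(
    call: CopulationCall | None = None,
    log: EventLog | None = None,
    window_s: float = 3600.0,
    min_duration_s: float = 60.0,
) -> bool:
    """Whether a qualifying copulation started within the observation window.

    Accepts either a detector :class:`CopulationCall` or a ground-truth
    :class:`EventLog` (if both are given they must agree).  A mount qualifies
    when it lasts strictly more than ``min_duration_s``; a mount still in
    progress at the nominal end counts on its full (extended) span.
    """
    if call is None and log is None:
        raise ValueError("either a copulation call or an event log is required")

    verdicts = {}
    if call is not None:
        verdicts["call"] = any(
            e - s > min_duration_s and s <= window_s for s, e, _ in call.intervals
        )
    if log is not None:
        cop = log.events("copulation")
        verdicts["log"] = bool(
            ((cop["end_s"] - cop["start_s"] > min_duration_s) & (cop["start_s"] <= window_s)).any()
        )
    if len(verdicts) == 2 and verdicts["call"] != verdicts["log"]:
        raise ConflictingSourcesError(
            f"detector says {verdicts['call']}, event log says {verdicts['log']}"
        )
    return next(iter(verdicts.values()))


def assay_metrics(
    log: EventLog,
    call: CopulationCall | None = None,
    initiation_window_s: float = 600.0,
    ci_window_s: float = 600.0,
    assay_window_s: float = 3600.0,
) -> CourtshipMetrics:
    """Compute the full per-assay endpoint bundle from one event log."""
    latency = courtship_latency(log, initiation_window_s)
    if latency is None:
        reason = "no courtship initiation within window"
        ci = None
    else:
        reason = None
        ci = courtship_index(log, ci_window_s)
    copulated = copulation_success(
        call=call, log=None if call is not None else log, window_s=assay_window_s
    )
    return CourtshipMetrics(
        assay_id=log.assay_id,
        latency_s=latency,
        courtship_index_pct=ci,
        copulation_success=copulated,
        copulation_window_s=assay_window_s,
        excluded_reason=reason,
    )


def format_rate(successes: int, n: int) -> str:
    """Render a success rate in percent to 3 significant figures.

    Matches the conventional mixed reporting style: 66.2, 7.14, 1.96, 100, 0.
    """
    if n <= 0:
        raise ValueError("empty stratum")
    rate = 100.0 * successes / n
    if rate == 0:
        return "0"
    return f"{rate:.3g}"


_STRATA = ["angle_class", "female_genotype", "mating_days"]


def summarize_groups(records: pd.DataFrame, outcome: str = "offspring") -> pd.DataFrame:
    """Success rates per stratum of an outcome table.

    ``records`` is a per-male outcome table; strata are whichever of
    ``angle_class``, ``female_genotype``, ``mating_days`` are present.
    Returns one row per stratum with ``n``, ``successes``, exact ``rate_pct``
    and a 3-significant-figure rendering ``rate_str``.
    """
    if len(records) == 0:
        raise ValueError("empty outcome table")
    keys = [c for c in _STRATA if c in records.columns]
    if not keys:
        raise ValueError(f"no stratum columns among {_STRATA}")
    grouped = records.groupby(keys, sort=True, observed=True)[outcome]
    out = grouped.agg(n="count", successes="sum").reset_index()
    out["successes"] = out["successes"].astype(int)
    out["rate_pct"] = 100.0 * out["successes"] / out["n"]
    out["rate_str"] = [format_rate(s, n) for s, n in zip(out["successes"], out["n"])]
    return out
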