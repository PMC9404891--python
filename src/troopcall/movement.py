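"""Collective-movement event analytics.

A group movement is a departure event: one individual initiates (walks
over 10 m within 30 s) and others join; the event closes once five
minutes pass without a new joiner, and counts as successful when at least
three individuals (initiator included) took part.  This module segments a
time-sorted join stream into such events, scores each participant's
joining-order index 1 - (I-1)/(N-1), classifies initiator/follower
displacement observations, and tallies how often events involved
vocalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MovementEvent",
    "DisplacementObservation",
    "MovementError",
    "VocalSummary",
    "segment_events",
    "is_initiator",
    "is_follower",
    "order_index",
    "event_order_indices",
    "vocal_summary",
    "vocal_rates",
    "observation_table",
]

#: Seconds without a new joiner after which an event closes.
EVENT_CLOSE_GAP = 300.0
#: Minimum participants (initiator included) for a successful movement.
MIN_PARTICIPANTS = 3


class MovementError(ValueError):
    """Invalid movement-log input."""


@dataclass(frozen=True)
class MovementEvent:
    """One segmented departure event.

    ``joins`` is the ordered (individual, join time) list; the initiator
    is by definition the first joiner.  ``calls`` maps each participant to
    the number of calls it gave during the event window.
    """

    event_id: str
    joins: tuple[tuple[str, float], ...]
    calls: Mapping[str, int]
    successful: bool

    def __post_init__(self) -> None:
        times = [t for _, t in self.joins]
        if any(b < a for a, b in zip(times, times[1:])):
            raise MovementError(f"{self.event_id}: join times must be nondecreasing")
        ids = [i for i, _ in self.joins]
        if len(set(ids)) != len(ids):
            raise MovementError(f"{self.event_id}: repeated participant")
        if any(c < 0 for c in self.calls.values()):
            raise MovementError(f"{self.event_id}: negative call count")
        object.__setattr__(self, "joins", tuple(self.joins))
        object.__setattr__(self, "calls", dict(self.calls))

    @property
    def initiator_id(self) -> str:
        return self.joins[0][0]

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.joins)

    @property
    def n_participants(self) -> int:
        return len(self.joins)

    @property
    def vocal(self) -> bool:
        return any(c > 0 for c in self.calls.values())

    @property
    def initiator_vocal(self) -> bool:
        return self.calls.get(self.initiator_id, 0) > 0


@dataclass(frozen=True)
class DisplacementObservation:
    """A measured displacement used for initiator/follower classification."""

    individual_id: str
    displacement: float  # meters
    bearing: float  # degrees, [0, 360)
    elapsed: float  # seconds since movement onset
    reference_bearing: float  # initiator's direction, degrees

    def __post_init__(self) -> None:
        if self.displacement < 0:
            raise MovementError("displacement must be nonnegative")
        for b in (self.bearing, self.reference_bearing):
            if not (0 <= b < 360):
                raise MovementError("bearings must lie in [0, 360)")
        if self.elapsed < 0:
            raise MovementError("elapsed must be nonnegative")


def segment_events(
    join_stream: Sequence[tuple[str, float, int]],
    close_gap: float = EVENT_CLOSE_GAP,
) -> list[MovementEvent]:
    """Cut a time-sorted (individual, time, n_calls) stream into events.

    A new event opens when more than ``close_gap`` seconds (5 min by
    default) separate a join from the previous one.  Within an event each
    individual is counted once; repeat joins are ignored entirely.
    """
    times = [t for _, t, _ in join_stream]
    if any(b < a for a, b in zip(times, times[1:])):
        raise MovementError("join stream must be sorted by time")

    events: list[MovementEvent] = []
    current: list[tuple[str, float]] = []
    calls: dict[str, int] = {}
    last_time: float | None = None

    def flush() -> None:
        if current:
            events.append(
                MovementEvent(
                    event_id=f"m{len(events) + 1:03d}",
                    joins=tuple(current),
                    calls=dict(calls),
                    successful=len(current) >= MIN_PARTICIPANTS,
                )
            )

    for ind, t, n_calls in join_stream:
        if last_time is not None and t - last_time > close_gap:
            flush()
            current, calls = [], {}
        if all(ind != j for j, _ in current):
            current.append((str(ind), float(t)))
            calls[str(ind)] = int(n_calls)
        last_time = t
    flush()
    return events


def is_initiator(d: DisplacementObservation, any_earlier_qualifier: bool = False) -> bool:
    """First individual to walk over 10 m (strict) within 30 s (inclusive)."""
    return d.displacement > 10.0 and d.elapsed <= 30.0 and not any_earlier_qualifier


def is_follower(d: DisplacementObservation) -> bool:
    """Moves over 5 m (strict) within 45 degrees of the initiator's bearing."""
    diff = abs(d.bearing - d.reference_bearing) % 360.0
    diff = min(diff, 360.0 - diff)
    return d.displacement > 5.0 and diff <= 45.0


def order_index(i: int, n: int) -> float:
    """Joining-order index 1 - (I-1)/(N-1); 1 first joiner, 0 last."""
    if n < 2:
        raise MovementError("order index undefined for fewer than 2 participants")
    if not 1 <= i <= n:
        raise MovementError(f"join position {i} outside 1..{n}")
    return 1.0 - (i - 1) / (n - 1)


def event_order_indices(event: MovementEvent) -> dict[str, float]:
    """Order index per participant; join-time ties keep record order."""
    n = event.n_participants
    return {ind: order_index(k + 1, n) for k, (ind, _) in enumerate(event.joins)}


@dataclass(frozen=True)
class VocalSummary:
    """Event-level vocal tallies with reconciled 1-decimal percentages."""

    n_events: int
    n_vocal: int
    n_nonvocal: int
    pct_vocal: float
    pct_nonvocal: float
    n_initiator_vocal: int
    pct_initiator_vocal_of_vocal: float


def _reconciled_percentages(a: int, b: int) -> tuple[float, float]:
    """Round 100*a/(a+b) and its complement so they sum to 100.0.

    Largest-remainder adjustment in units of 0.1 resolves the rare case
    where independently rounded halves do not add back to 100.0.
    """
    total = a + b
    if total == 0:
        return float("nan"), float("nan")
    exact = (100.0 * a / total, 100.0 * b / total)
    in_tenths = [e * 10 for e in exact]
    floors = [int(np.floor(v)) for v in in_tenths]
    shortfall = 1000 - sum(floors)
    remainders = [v - f for v, f in zip(in_tenths, floors)]
    order = sorted(range(2), key=lambda k: -remainders[k])
    for k in order[:shortfall]:
        floors[k] += 1
    return floors[0] / 10.0, floors[1] / 10.0


def vocal_summary(
    events: Sequence[MovementEvent],
    successful_only: bool = True,
) -> VocalSummary:
    """Tally vocal vs non-vocal events and vocalizing initiators.

    Percentages are reported at 1 decimal; the vocal/non-vocal pair is
    reconciled to sum to exactly 100.0.
    """
    pool = [e for e in events if e.successful] if successful_only else list(events)
    n = len(pool)
    n_vocal = sum(e.vocal for e in pool)
    n_nonvocal = n - n_vocal
    n_init = sum(e.initiator_vocal for e in pool)
    pct_vocal, pct_nonvocal = _reconciled_percentages(n_vocal, n_nonvocal)
    pct_init = round(100.0 * n_init / n_vocal, 1) if n_vocal else float("nan")
    return VocalSummary(
        n_events=n,
        n_vocal=n_vocal,
        n_nonvocal=n_nonvocal,
        pct_vocal=pct_vocal,
        pct_nonvocal=pct_nonvocal,
        n_initiator_vocal=n_init,
        pct_initiator_vocal_of_vocal=pct_init,
    )


def vocal_rates(
    events: Sequence[MovementEvent],
    successful_only: bool = True,
) -> pd.DataFrame:
    """Per-individual vocal frequency across movements.

    The rate is total calls divided by the number of events the
    individual participated in; the raw exposure (participation count)
    is reported alongside so alternative normalizations stay possible.
    Also carries each individual's mean joining-order index.
    """
    pool = [e for e in events if e.successful] if successful_only else list(events)
    totals: dict[str, dict[str, float]] = {}
    for event in pool:
        indices = event_order_indices(event) if event.n_participants >= 2 else {}
        for ind in event.participants:
            row = totals.setdefault(
                ind, {"total_calls": 0.0, "n_events": 0.0, "order_sum": 0.0}
            )
            row["total_calls"] += event.calls.get(ind, 0)
            row["n_events"] += 1
            row["order_sum"] += indices.get(ind, np.nan)
    records = []
    for ind in sorted(totals):
        row = totals[ind]
        records.append(
            {
                "id": ind,
                "total_calls": int(row["total_calls"]),
                "n_events": int(row["n_events"]),
                "vocal_rate": row["total_calls"] / row["n_events"],
                "mean_order_index": row["order_sum"] / row["n_events"],
            }
        )
    return pd.DataFrame(
        records, columns=["id", "total_calls", "n_events", "vocal_rate", "mean_order_index"]
    )


def observation_table(
    events: Sequence[MovementEvent],
    roster: Iterable,
    centrality: Mapping[str, float] | pd.Series,
    rank: Mapping[str, int] | pd.Series | None = None,
    relatives: Mapping[str, int] | pd.Series | None = None,
    successful_only: bool = True,
) -> pd.DataFrame:
    """One row per (event, participant) for the vocal-frequency model.

    Columns: calls, female (1/0), centrality, rank, relatives,
    order_index, exposure (=1 event).  Sex codes female = 1 so a positive
    coefficient means females call more.
    """
    by_id = {ind.id: ind for ind in roster}
    pool = [e for e in events if e.successful] if successful_only else list(events)
    rows = []
    for event in pool:
        indices = event_order_indices(event) if event.n_participants >= 2 else {}
        for ind in event.participants:
            entry = by_id.get(ind)
            if entry is None:
                raise MovementError(f"unknown individual id: {ind}")
            rows.append(
                {
                    "event_id": event.event_id,
                    "id": ind,
                    "calls": event.calls.get(ind, 0),
                    "female": 1.0 if entry.sex == "female" else 0.0,
                    "centrality": float(centrality[ind]),
                    "rank": float(rank[ind]) if rank is not None else np.nan,
                    "relatives": float(relatives[ind])
                    if relatives is not None
                    else float(entry.n_relatives),
                    "order_index": indices.get(ind, np.nan),
                    "exposure": 1.0,
                }
            )
    return pd.DataFrame(rows)


# -- CSV I/O -----------------------------------------------------------------

def read_movements_csv(path: str | Path) -> list[MovementEvent]:
    """Read a movements log (event_id, individual_id, join_time_s, n_calls)."""
    df = pd.read_csv(path)
    events = []
    for event_id, grp in df.groupby("event_id", sort=True):
        grp = grp.sort_values("join_time_s", kind="stable")
        joins = tuple(
            (str(r.individual_id), float(r.join_time_s)) for r in grp.itertuples()
        )
        calls = {str(r.individual_id): int(r.n_calls) for r in grp.itertuples()}
        events.append(
            MovementEvent(
                event_id=str(event_id),
                joins=joins,
                calls=calls,
                successful=len(joins) >= MIN_PARTICIPANTS,
            )
        )
    return events


def events_to_frame(events: Sequence[MovementEvent]) -> pd.DataFrame:
    rows = []
    for event in events:
        for ind, t in event.joins:
            rows.append(
                {
                    "event_id": event.event_id,
                    "individual_id": ind,
                    "join_time_s": t,
                    "n_calls": event.calls.get(ind, 0),
                }
            )
    return pd.DataFrame(rows, columns=["event_id", "individual_id", "join_time_s", "n_calls"])


def write_movement_outputs(out_dir: str | Path, events: Sequence[MovementEvent]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = vocal_summary(events)
    pd.DataFrame([summary.__dict__]).to_csv(out / "events_summary.csv", index=False)
    order_rows = []
    for event in events:
        if not event.successful:
            continue
        for ind, idx in event_order_indices(event).items():
            order_rows.append({"event_id": event.event_id, "id": ind, "order_index": idx})
    pd.DataFrame(order_rows, columns=["event_id", "id", "order_index"]).to_csv(
        out / "order_index.csv", index=False
    )
    vocal_rates(events).to_csv(out / "vocal_rates.csv", index=False)
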