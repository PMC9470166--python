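"""Data model and IO for home-cage lickometer recordings.

A lickometer samples the state of an infrared beam in front of the bottle
valve; each beam break is a *lick*.  The device firmware only writes to
memory at minimum every 2 s, so any spout interaction within a 2 s window is
aggregated into a *drinking bout* carrying the lick count and the total
beam-broken time (*lick duration*).  Recorded bouts can be longer than 2 s
but never shorter.  :func:`device_emulate` reproduces that write rule in
software so raw event streams and device-level bout records are
interconvertible.

Times are decimal seconds from session start, 0-based, with half-open
``[onset, offset)`` lick intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "LickEvent",
    "BoutRecord",
    "SessionRecord",
    "ClassLabel",
    "CLASS_ORDER",
    "DEVICE_WRITE_GAP_S",
    "device_emulate",
    "read_events",
    "write_events",
    "read_sessions",
    "write_sessions",
]

#: Minimum spacing of device memory writes (seconds); also the default
#: lick-clustering gap and the floor on recorded bout span.
DEVICE_WRITE_GAP_S = 2.0

FLUIDS = ("water", "alcohol")
VIRUSES = ("ChR2", "eGFP")
STIM_MODES = ("none", "closed_loop", "open_loop")

#: Canonical fluid × virus class order used for one-hot encoding everywhere.
CLASS_ORDER = (
    ("water", "ChR2"),
    ("water", "eGFP"),
    ("alcohol", "ChR2"),
    ("alcohol", "eGFP"),
)


@dataclass(frozen=True)
class LickEvent:
    """A single beam-break interval ``[onset, offset)`` in seconds."""

    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset < self.offset):
            raise ValidationError(
                f"LickEvent requires offset > onset >= 0, got ({self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class BoutRecord:
    """A device-level drinking bout (2 s write rule applied)."""

    start: float
    end: float
    n_licks: int
    lick_duration: float

    def __post_init__(self) -> None:
        span = self.end - self.start
        if span < DEVICE_WRITE_GAP_S - 1e-9:
            raise ValidationError(f"bout span {span:.6g} s < {DEVICE_WRITE_GAP_S} s floor")
        if self.n_licks < 1:
            raise ValidationError(f"bout needs n_licks >= 1, got {self.n_licks}")
        if not (0.0 < self.lick_duration <= span + 1e-9):
            raise ValidationError(
                f"lick_duration {self.lick_duration:.6g} must be in (0, span={span:.6g}]"
            )

    @property
    def span(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ClassLabel:
    """Fluid × virus class with its one-hot encoding over :data:`CLASS_ORDER`."""

    fluid: str
    virus: str

    def __post_init__(self) -> None:
        if (self.fluid, self.virus) not in CLASS_ORDER:
            raise ValidationError(f"unknown class {(self.fluid, self.virus)}")

    @property
    def index(self) -> int:
        return CLASS_ORDER.index((self.fluid, self.virus))

    @property
    def one_hot(self) -> tuple[int, int, int, int]:
        return tuple(int(i == self.index) for i in range(len(CLASS_ORDER)))  # type: ignore[return-value]


@dataclass
class SessionRecord:
    """One animal-session: metadata, bottle weights and the cleaned/raw bout list.

    The schedule is the limited-access paradigm: five sessions per week
    (four 2 h, one 4 h), six weeks, so ``week == ceil(session_index / 5)``.
    """

    animal_id: str
    session_index: int
    session_length_h: float
    fluid: str
    virus: str
    stim_mode: str = "none"
    bottle_weight_pre_g: float = 0.0
    bottle_weight_post_g: float = 0.0
    body_weight_g: float = float("nan")
    bouts: list[BoutRecord] = field(default_factory=list)
    bottle_side: str | None = None  # hardware holds two bottles; one used

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValidationError(f"fluid must be one of {FLUIDS}, got {self.fluid!r}")
        if self.virus not in VIRUSES:
            raise ValidationError(f"virus must be one of {VIRUSES}, got {self.virus!r}")
        if self.stim_mode not in STIM_MODES:
            raise ValidationError(f"stim_mode must be one of {STIM_MODES}")
        if not 1 <= int(self.session_index):
            raise ValidationError(f"session_index must be >= 1, got {self.session_index}")
        if self.session_length_h not in (2, 4, 2.0, 4.0):
            raise ValidationError(
                f"session_length_h must be 2 or 4, got {self.session_length_h}"
            )
        if self.bottle_weight_post_g > self.bottle_weight_pre_g + 1e-9:
            raise ValidationError(
                "bottle_weight_post_g exceeds bottle_weight_pre_g "
                f"({self.bottle_weight_post_g} > {self.bottle_weight_pre_g}) "
                f"for animal {self.animal_id} session {self.session_index}"
            )
        horizon = self.session_length_s + DEVICE_WRITE_GAP_S
        for b in self.bouts:
            if b.end > horizon + 1e-6:
                raise ValidationError(
                    f"bout ending at {b.end:.6g} s exceeds session length "
                    f"{self.session_length_s:.6g} s (animal {self.animal_id})"
                )

    @property
    def week(self) -> int:
        return math.ceil(self.session_index / 5)

    @property
    def session_length_s(self) -> float:
        return self.session_length_h * 3600.0

    @property
    def label(self) -> ClassLabel:
        return ClassLabel(self.fluid, self.virus)

    @property
    def grams_consumed(self) -> float:
        return self.bottle_weight_pre_g - self.bottle_weight_post_g

    def with_bouts(self, bouts: Sequence[BoutRecord]) -> "SessionRecord":
        return replace(self, bouts=list(bouts))


def _validate_event_stream(events: Sequence[LickEvent]) -> None:
    for i in range(1, len(events)):
        if events[i].onset < events[i - 1].onset:
            raise ValidationError(f"events not sorted by onset at position {i}")
        if events[i].onset < events[i - 1].offset - 1e-12:
            raise ValidationError(
                f"overlapping events at position {i}: "
                f"onset {events[i].onset} < previous offset {events[i - 1].offset}"
            )


def device_emulate(
    events: Sequence[LickEvent], gap: float = DEVICE_WRITE_GAP_S
) -> list[BoutRecord]:
    """Aggregate a lick stream into bout records using the device write rule.

    Consecutive licks whose inter-onset interval is at most ``gap`` share a
    bout; a bout ends once more than ``gap`` seconds elapse after the
    previous lick's onset.  The recorded span is floored at ``gap`` (a single
    isolated lick still occupies one full write window), which is why
    recorded bouts are never shorter than 2 s at the default gap.
    """
    if gap <= 0:
        raise ValidationError(f"gap must be positive, got {gap}")
    events = list(events)
    _validate_event_stream(events)
    bouts: list[BoutRecord] = []
    i = 0
    n = len(events)
    while i < n:
        j = i
        while j + 1 < n and events[j + 1].onset - events[j].onset <= gap:
            j += 1
        group = events[i : j + 1]
        start = group[0].onset
        span = max(group[-1].offset - start, gap)
        bouts.append(
            BoutRecord(
                start=start,
                end=start + span,
                n_licks=len(group),
                lick_duration=sum(e.duration for e in group),
            )
        )
        i = j + 1
    return bouts


# ---------------------------------------------------------------------------
# CSV IO.  Events: animal_id,session_index,onset_s,offset_s.  Sessions: one
# bout per row with metadata denormalized; a zero-bout session is one row
# with the bout columns empty so the session itself round-trips.
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["animal_id", "session_index", "onset_s", "offset_s"]
SESSION_COLUMNS = [
    "animal_id",
    "session_index",
    "week",
    "session_length_h",
    "fluid",
    "virus",
    "stim_mode",
    "start_s",
    "end_s",
    "n_licks",
    "lick_duration_s",
    "bottle_pre_g",
    "bottle_post_g",
    "body_weight_g",
    "bottle_side",
]


def write_events(
    events_by_session: dict[tuple[str, int], Sequence[LickEvent]], path: str | Path
) -> None:
    rows = [
        {"animal_id": a, "session_index": s, "onset_s": e.onset, "offset_s": e.offset}
        for (a, s), evs in sorted(events_by_session.items())
        for e in evs
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> dict[tuple[str, int], list[LickEvent]]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read events file {path}: {exc}") from exc
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"events file {path} missing columns {sorted(missing)}")
    out: dict[tuple[str, int], list[LickEvent]] = {}
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            key = (str(row.animal_id), int(row.session_index))
            out.setdefault(key, []).append(
                LickEvent(float(row.onset_s), float(row.offset_s))
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ParseError(f"events file {path}, line {line}: {exc}") from exc
    for key, evs in out.items():
        evs.sort(key=lambda e: e.onset)
        _validate_event_stream(evs)
    return out


def sessions_to_frame(sessions: Iterable[SessionRecord]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        meta = {
            "animal_id": s.animal_id,
            "session_index": s.session_index,
            "week": s.week,
            "session_length_h": s.session_length_h,
            "fluid": s.fluid,
            "virus": s.virus,
            "stim_mode": s.stim_mode,
            "bottle_pre_g": s.bottle_weight_pre_g,
            "bottle_post_g": s.bottle_weight_post_g,
            "body_weight_g": s.body_weight_g,
            "bottle_side": s.bottle_side,
        }
        if s.bouts:
            for b in s.bouts:
                rows.append(
                    meta
                    | {
                        "start_s": b.start,
                        "end_s": b.end,
                        "n_licks": b.n_licks,
                        "lick_duration_s": b.lick_duration,
                    }
                )
        else:
            rows.append(
                meta | {"start_s": None, "end_s": None, "n_licks": None, "lick_duration_s": None}
            )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions(sessions: Iterable[SessionRecord], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def frame_to_sessions(df: pd.DataFrame, source: str = "<frame>") -> list[SessionRecord]:
    missing = set(SESSION_COLUMNS) - {"bottle_side"} - set(df.columns)
    if missing:
        raise ParseError(f"{source} missing columns {sorted(missing)}")
    sessions: list[SessionRecord] = []
    for (animal, idx), grp in df.groupby(["animal_id", "session_index"], sort=True):
        first = grp.iloc[0]
        bouts = []
        for line, row in grp.iterrows():
            if pd.isna(row["start_s"]):
                continue
            try:
                bouts.append(
                    BoutRecord(
                        start=float(row["start_s"]),
                        end=float(row["end_s"]),
                        n_licks=int(row["n_licks"]),
                        lick_duration=float(row["lick_duration_s"]),
                    )
                )
            except (TypeError, ValueError, ValidationError) as exc:
                raise ParseError(f"{source}, row {line}: {exc}") from exc
        bouts.sort(key=lambda b: b.start)
        side = first.get("bottle_side") if "bottle_side" in grp.columns else None
        sessions.append(
            SessionRecord(
                animal_id=str(animal),
                session_index=int(idx),
                session_length_h=float(first["session_length_h"]),
                fluid=str(first["fluid"]),
                virus=str(first["virus"]),
                stim_mode=str(first["stim_mode"]),
                bottle_weight_pre_g=float(first["bottle_pre_g"]),
                bottle_weight_post_g=float(first["bottle_post_g"]),
                body_weight_g=float(first["body_weight_g"]),
                bouts=bouts,
                bottle_side=None if pd.isna(side) else str(side),
            )
        )
    sessions.sort(key=lambda s: (s.animal_id, s.session_index))
    return sessions


def read_sessions(path: str | Path) -> list[SessionRecord]:
    """Read a denormalized bout-per-row session CSV.

    Sessions come back sorted by ``(animal_id, session_index)``; every type
    invariant is re-validated, and violations raise :class:`ValidationError`
    naming the field, parse failures :class:`ParseError` naming the row.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot read sessions file {path}: {exc}") from exc
    missing = set(SESSION_COLUMNS) - {"bottle_side"} - set(df.columns)
    if missing:
        raise ParseError(f"{path} missing columns {sorted(missing)}")
    if df.empty:
        return []
    return frame_to_sessions(df, source=str(path))
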