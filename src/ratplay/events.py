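"""Core data types for group play sessions.

A play session puts one group of ``k`` familiar juvenile rats (default
``k = 6``) in an open enclosure for 20 minutes.  Every playful nape attack is
scored as one :class:`AttackEvent` carrying the initiator, the recipient, the
recipient's defensive response, whether the defender achieved a role reversal
(a successful counterattack), and how many of the initiator's potential
partners were free at attack time.  Attacks aggregate into directed
:class:`CountMatrix` objects (one per group-day) which downstream modules
row-normalise, screen for randomness and score for partner preference.

All readers/writers speak plain UTF-8 CSV with a header row.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Days of the eight-day test window that are scored (alternating days across
#: the peak juvenile play period, postnatal days 30-40).
SCORED_DAYS: tuple[int, ...] = (1, 3, 5, 8)

#: Defensive responses to a nape attack.  ``no_response`` = attack ignored;
#: ``evasion`` = swerve/leap/run away; ``pin`` = facing defence ending supine
#: under the attacker; ``box`` = facing defence in an upright boxing posture.
RESPONSES: tuple[str, ...] = ("no_response", "evasion", "pin", "box")

#: Default session length in seconds (20 min).
SESSION_S: float = 1200.0

#: Default group size.
GROUP_SIZE: int = 6

EVENT_COLUMNS = (
    "group_id",
    "day",
    "time_s",
    "initiator",
    "recipient",
    "response",
    "role_reversal",
    "n_partners_available",
)


class ValidationError(ValueError):
    """Raised when an input file or record violates a domain invariant.

    ``line`` is the 1-based line number within the offending file when the
    error arose while parsing, otherwise ``None``.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Animal:
    """One rat: identity, group, body weight and tube-test dominance data."""

    animal_id: str
    group_id: int
    weight_g: float
    tube_wins: int = 0
    dominance_rank: int | None = None

    def __post_init__(self):
        if self.tube_wins < 0:
            raise ValidationError(f"negative tube_wins for {self.animal_id}")
        if self.weight_g <= 0:
            raise ValidationError(f"non-positive weight for {self.animal_id}")


@dataclass(frozen=True)
class AttackEvent:
    """One playful nape attack.

    ``n_partners_available`` counts the initiator's free potential partners at
    attack time (0..k-1); ``all_available`` is true when every one of the
    ``k - 1`` partners was free.
    """

    group_id: int
    day: int
    time_s: float
    initiator: str
    recipient: str
    response: str
    role_reversal: bool
    n_partners_available: int
    all_available: bool = field(default=False)

    def validated(self, k: int = GROUP_SIZE, session_s: float = SESSION_S,
                  allow_unscored_days: bool = False,
                  line: int | None = None) -> "AttackEvent":
        """Return self (with ``all_available`` derived) or raise ValidationError."""
        if self.initiator == self.recipient:
            raise ValidationError(
                f"initiator == recipient ({self.initiator!r})", line)
        if self.response not in RESPONSES:
            raise ValidationError(
                f"bad response code {self.response!r} "
                f"(expected one of {RESPONSES})", line)
        if self.role_reversal and self.response == "no_response":
            raise ValidationError(
                "role_reversal set on a no_response attack "
                "(an ignored attack cannot be counterattacked)", line)
        if not (0.0 <= self.time_s <= session_s):
            raise ValidationError(
                f"time_s {self.time_s} outside session [0, {session_s}]", line)
        if not (0 <= self.n_partners_available <= k - 1):
            raise ValidationError(
                f"n_partners_available {self.n_partners_available} "
                f"outside 0..{k - 1}", line)
        if self.day not in SCORED_DAYS and not allow_unscored_days:
            raise ValidationError(
                f"day {self.day} is not a scored day {SCORED_DAYS} "
                "(pass allow_unscored_days=True to accept)", line)
        return replace(self, all_available=self.n_partners_available == k - 1)


@dataclass(frozen=True)
class ProximityRecord:
    """Seconds an unordered pair spent within one body length of each other,
    with time spent actually playing together already subtracted."""

    group_id: int
    day: int
    animal_a: str
    animal_b: str
    proximity_s: float

    def __post_init__(self):
        if self.animal_a == self.animal_b:
            raise ValidationError("proximity dyad must be two distinct animals")
        if self.proximity_s < 0:
            raise ValidationError(f"negative proximity_s {self.proximity_s}")

    @property
    def dyad(self) -> tuple[str, str]:
        return tuple(sorted((self.animal_a, self.animal_b)))


@dataclass
class CountMatrix:
    """Directed k x k matrix of nape-attack counts for one group-day.

    Entry ``counts[i, j]`` is the number of attacks initiated by
    ``labels[i]`` on ``labels[j]`` (the B_ij of the preference index); the
    diagonal is structurally zero.
    """

    group_id: int
    day: int
    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0):
            raise ValidationError("negative attack count")
        if np.any(np.diag(self.counts) != 0):
            raise ValidationError("non-zero diagonal in count matrix")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def row_totals(self) -> np.ndarray:
        """Total attacks initiated by each animal (the B_i)."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ProportionMatrix:
    """Row-normalised :class:`CountMatrix`: entry (i, j) is the proportion of
    i's attacks directed at j.  Rows with zero attacks stay all-zero and are
    flagged in ``zero_rows``."""

    group_id: int
    day: int
    labels: tuple[str, ...]
    proportions: np.ndarray
    zero_rows: np.ndarray  # boolean per row

    @property
    def k(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# construction


def build_count_matrix(events: Iterable[AttackEvent], group_id: int, day: int,
                       labels: Sequence[str]) -> CountMatrix:
    """Tally events into a directed count matrix for one group-day.

    All events must belong to ``(group_id, day)`` and reference only animals
    in ``labels``.  ``labels`` order fixes the matrix axes; use sorted labels
    for reproducible output.
    """
    labels = tuple(labels)
    if not labels:
        raise ValidationError("empty label list")
    index = {a: i for i, a in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ev in events:
        if (ev.group_id, ev.day) != (group_id, day):
            raise ValidationError(
                f"event from (group {ev.group_id}, day {ev.day}) passed to "
                f"matrix for (group {group_id}, day {day})")
        try:
            counts[index[ev.initiator], index[ev.recipient]] += 1
        except KeyError as exc:
            raise ValidationError(f"unknown animal_id {exc.args[0]!r}") from None
    return CountMatrix(group_id, day, labels, counts)


def to_proportions(counts: CountMatrix) -> ProportionMatrix:
    """Row-normalise a count matrix; zero rows are flagged, not an error."""
    totals = counts.row_totals.astype(float)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    props = counts.counts / safe[:, None]
    props[zero] = 0.0
    return ProportionMatrix(counts.group_id, counts.day, counts.labels,
                            props, zero)


# ---------------------------------------------------------------------------
# delimited-text IO

def _format_time(t: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    return repr(float(t))


def write_event_log(events: Iterable[AttackEvent], path: str | Path) -> None:
    """Write events as canonical CSV (header, 'true'/'false' booleans)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            writer.writerow([
                ev.group_id, ev.day, _format_time(ev.time_s), ev.initiator,
                ev.recipient, ev.response,
                "true" if ev.role_reversal else "false",
                ev.n_partners_available,
            ])


def read_event_log(path: str | Path, k: int = GROUP_SIZE,
                   session_s: float = SESSION_S,
                   allow_unscored_days: bool = False,
                   known_animals: set[str] | None = None
                   ) -> list[AttackEvent]:
    """Parse and validate an events CSV.

    Raises :class:`ValidationError` naming the offending line on any invariant
    violation (unknown animal, self-attack, bad response code, bad day, ...).
    """
    path = Path(path)
    events: list[AttackEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(EVENT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(
                f"missing required columns: {sorted(missing)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            try:
                ev = AttackEvent(
                    group_id=int(row["group_id"]),
                    day=int(row["day"]),
                    time_s=float(row["time_s"]),
                    initiator=row["initiator"].strip(),
                    recipient=row["recipient"].strip(),
                    response=row["response"].strip(),
                    role_reversal=_parse_bool(row["role_reversal"], lineno),
                    n_partners_available=int(row["n_partners_available"]),
                )
            except ValidationError:
                raise
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"unparseable row: {exc}", lineno) from None
            ev = ev.validated(k=k, session_s=session_s,
                              allow_unscored_days=allow_unscored_days,
                              line=lineno)
            if known_animals is not None:
                for a in (ev.initiator, ev.recipient):
                    if a not in known_animals:
                        raise ValidationError(
                            f"unknown animal_id {a!r}", lineno)
            events.append(ev)
    return events


def _parse_bool(text: str, line: int) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValidationError(f"bad boolean {text!r}", line)


def write_animals(animals: Iterable[Animal], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["group_id", "animal_id", "weight_g", "tube_wins"])
        for a in animals:
            writer.writerow([a.group_id, a.animal_id,
                             repr(float(a.weight_g)), a.tube_wins])


def read_animals(path: str | Path) -> list[Animal]:
    df = pd.read_csv(path)
    animals = []
    seen: set[tuple[int, str]] = set()
    for i, row in df.iterrows():
        key = (int(row["group_id"]), str(row["animal_id"]))
        if key in seen:
            raise ValidationError(
                f"duplicate animal {key[1]!r} in group {key[0]}", int(i) + 2)
        seen.add(key)
        animals.append(Animal(
            animal_id=str(row["animal_id"]),
            group_id=int(row["group_id"]),
            weight_g=float(row["weight_g"]),
            tube_wins=int(row.get("tube_wins", 0)),
        ))
    return animals


def write_proximity(records: Iterable[ProximityRecord],
                    path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["group_id", "day", "animal_a", "animal_b",
                         "proximity_s"])
        for r in records:
            writer.writerow([r.group_id, r.day, r.animal_a, r.animal_b,
                             repr(float(r.proximity_s))])


def read_proximity(path: str | Path,
                   session_s: float = SESSION_S) -> list[ProximityRecord]:
    df = pd.read_csv(path)
    records = []
    for i, row in df.iterrows():
        rec = ProximityRecord(
            group_id=int(row["group_id"]), day=int(row["day"]),
            animal_a=str(row["animal_a"]), animal_b=str(row["animal_b"]),
            proximity_s=float(row["proximity_s"]))
        if rec.proximity_s > session_s:
            raise ValidationError(
                f"proximity_s {rec.proximity_s} exceeds session length "
                f"{session_s}", int(i) + 2)
        records.append(rec)
    return records


def events_to_frame(events: Sequence[AttackEvent]) -> pd.DataFrame:
    """Events as a DataFrame (adds the derived ``all_available`` column)."""
    return pd.DataFrame(
        [{**{c: getattr(ev, c) for c in EVENT_COLUMNS},
          "all_available": ev.all_available} for ev in events],
        columns=list(EVENT_COLUMNS) + ["all_available"])


def matrices_to_frame(counts: Sequence[CountMatrix]) -> pd.DataFrame:
    """Long-format export: one row per directed dyad per group-day."""
    rows = []
    for cm in counts:
        pm = to_proportions(cm)
        for i, a in enumerate(cm.labels):
            for j, b in enumerate(cm.labels):
                if i == j:
                    continue
                rows.append({
                    "group_id": cm.group_id, "day": cm.day,
                    "initiator": a, "recipient": b,
                    "count": int(cm.counts[i, j]),
                    "proportion": float(pm.proportions[i, j]),
                })
    return pd.DataFrame(rows)


def event_log_bytes(events: Sequence[AttackEvent]) -> bytes:
    """Canonical CSV serialisation as bytes (for hashing/determinism checks)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(EVENT_COLUMNS)
    for ev in events:
        writer.writerow([
            ev.group_id, ev.day, _format_time(ev.time_s), ev.initiator,
            ev.recipient, ev.response,
            "true" if ev.role_reversal else "false",
            ev.n_partners_available,
        ])
    return buf.getvalue().encode()
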