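"""Domain types and on-disk formats for a tailored-messaging trial.

The toolkit revolves around four observable tables:

* a **message bank** — persuasive messages written by experts or peers,
  each carrying content tags (reasons to quit, tips and strategies,
  nicotine-replacement therapy, distraction/substitution);
* a **rating stream** — one event per message sent to a user on a study
  day, with an optional 1–5 Likert reply ("this message influenced me to
  quit": 1 = strongly disagree … 5 = strongly agree);
* **user profiles** — group label plus the baseline demographic and
  smoking-behaviour fields collected at registration;
* **trial records** — per-user engagement (website visits), seven
  follow-up impact items, and the 30-day cessation flag.

Formats are deliberately plain: messages as a JSON array, everything else
as headed CSV. Missing Likert values are empty CSV fields, never 0 —
zero is outside the scale and would silently corrupt means.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "Message",
    "UserProfile",
    "RatingEvent",
    "RatingMatrix",
    "TrialRecord",
    "MESSAGE_SOURCES",
    "READINESS_STAGES",
    "AGE_BANDS",
    "load_message_bank",
    "write_message_bank",
    "load_profiles",
    "write_profiles",
    "load_ratings",
    "write_ratings",
    "load_trial",
    "write_trial",
]

MESSAGE_SOURCES = ("expert", "peer")

#: Readiness-to-quit stages, in order, as collected at registration.
READINESS_STAGES = (
    "not_thinking_of_quitting",
    "thinking_of_quitting",
    "set_a_quit_date",
    "quit_today",
    "already_quit",
)

AGE_BANDS = ("19-34", "35-44", "45+")
EDUCATION_LEVELS = ("other", "advanced_degree")
SMOKING_STATUSES = ("not_actively_quitting", "actively_quitting")

#: Number of follow-up intervention-impact items, in collection order:
#: talk to a doctor, get support, list reasons to quit, behavioural
#: strategies, use NRT, set a quit date, quit smoking.
N_IMPACT_ITEMS = 7


class ValidationError(ValueError):
    """A record violated a data-model invariant; the message names it."""


@dataclass(frozen=True)
class Message:
    """One persuasive message with provenance and content tags."""

    message_id: str
    text: str
    source: str
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValidationError(f"message {self.message_id!r}: empty text")
        if self.source not in MESSAGE_SOURCES:
            raise ValidationError(
                f"message {self.message_id!r}: source {self.source!r} "
                f"not in {MESSAGE_SOURCES}"
            )
        object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass(frozen=True)
class UserProfile:
    """Baseline profile: group plus registration fields.

    ``group`` is an open label (any string) so the toolkit generalises
    beyond the two study groups; the trial statistics require exactly two
    groups per contrast and enforce that themselves.
    """

    user_id: str
    group: str
    gender: str
    age_band: str
    education: str
    ethnicity: str
    allow_smoking_home: bool
    visited_cessation_site: bool
    past_year_quit_attempt: bool
    smoking_status: str
    readiness: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValidationError(
                f"user {self.user_id!r}: age_band {self.age_band!r} not in {AGE_BANDS}"
            )
        if self.education not in EDUCATION_LEVELS:
            raise ValidationError(
                f"user {self.user_id!r}: education {self.education!r} "
                f"not in {EDUCATION_LEVELS}"
            )
        if self.smoking_status not in SMOKING_STATUSES:
            raise ValidationError(
                f"user {self.user_id!r}: smoking_status {self.smoking_status!r} "
                f"not in {SMOKING_STATUSES}"
            )
        if self.readiness not in READINESS_STAGES:
            raise ValidationError(
                f"user {self.user_id!r}: readiness {self.readiness!r} "
                f"not one of the five stages {READINESS_STAGES}"
            )


@dataclass(frozen=True)
class RatingEvent:
    """A message sent to a user on a study day, with an optional reply.

    ``value`` is None when the message was sent but never rated; ratings
    are optional in the live system.
    """

    user_id: str
    message_id: str
    day_index: int
    value: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValidationError(
                f"event ({self.user_id},{self.message_id}): day_index "
                f"{self.day_index} must be >= 1 (day 1 = first message)"
            )
        if self.value is not None and self.value not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"event ({self.user_id},{self.message_id}): rating "
                f"{self.value!r} outside the 1-5 Likert scale"
            )


@dataclass(frozen=True)
class TrialRecord:
    """Per-user follow-up record: engagement, impact items, cessation."""

    user_id: str
    group: str
    website_visits: int
    impact_items: tuple[Optional[int], ...]
    quit_30day: Optional[bool]

    def __post_init__(self) -> None:
        if self.website_visits < 0:
            raise ValidationError(
                f"user {self.user_id!r}: website_visits {self.website_visits} < 0"
            )
        if len(self.impact_items) != N_IMPACT_ITEMS:
            raise ValidationError(
                f"user {self.user_id!r}: expected {N_IMPACT_ITEMS} impact items, "
                f"got {len(self.impact_items)}"
            )
        for i, v in enumerate(self.impact_items, 1):
            if v is not None and v not in (1, 2, 3, 4, 5):
                raise ValidationError(
                    f"user {self.user_id!r}: impact item {i} value {v!r} "
                    f"outside the 1-5 scale"
                )


class RatingMatrix:
    """Sparse users x messages Likert matrix.

    Unobserved cells are *absent* — never zero-filled; 0 is outside the
    rating scale. Internally a dict keyed by (user index, item index).
    """

    def __init__(
        self,
        users: Sequence[str],
        items: Sequence[str],
        entries: Mapping[tuple[str, str], float] | None = None,
    ) -> None:
        if len(set(users)) != len(users):
            raise ValidationError("duplicate user ids in matrix roster")
        if len(set(items)) != len(items):
            raise ValidationError("duplicate item ids in matrix roster")
        self.users = list(users)
        self.items = list(items)
        self._uidx = {u: i for i, u in enumerate(self.users)}
        self._iidx = {m: j for j, m in enumerate(self.items)}
        self._data: dict[tuple[int, int], float] = {}
        if entries:
            for (u, m), v in entries.items():
                self.set(u, m, v)

    # -- mutation ---------------------------------------------------------
    def set(self, user: str, item: str, value: float) -> None:
        if user not in self._uidx:
            raise ValidationError(f"unknown user id {user!r}")
        if item not in self._iidx:
            raise ValidationError(f"unknown message id {item!r}")
        if not (1 <= value <= 5):
            raise ValidationError(
                f"rating {value!r} for ({user},{item}) outside 1-5"
            )
        self._data[(self._uidx[user], self._iidx[item])] = float(value)

    # -- access -----------------------------------------------------------
    def get(self, user: str, item: str) -> Optional[float]:
        return self._data.get((self._uidx[user], self._iidx[item]))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        u, m = pair
        return (self._uidx.get(u, -1), self._iidx.get(m, -1)) in self._data

    @property
    def n_observed(self) -> int:
        return len(self._data)

    @property
    def density(self) -> float:
        return len(self._data) / (len(self.users) * len(self.items))

    def user_ratings(self, user: str) -> dict[str, float]:
        """All observed ratings of one user, keyed by message id."""
        ui = self._uidx[user]
        return {
            self.items[j]: v for (i, j), v in self._data.items() if i == ui
        }

    def item_means(self) -> dict[str, float]:
        sums: dict[int, list[float]] = {}
        for (_, j), v in self._data.items():
            sums.setdefault(j, []).append(v)
        return {self.items[j]: float(np.mean(vs)) for j, vs in sums.items()}

    def global_mean(self) -> float:
        if not self._data:
            return 3.0  # scale midpoint for an empty matrix
        return float(np.mean(list(self._data.values())))

    def to_dense(self) -> np.ndarray:
        """Dense float array with NaN in unobserved cells."""
        out = np.full((len(self.users), len(self.items)), np.nan)
        for (i, j), v in self._data.items():
            out[i, j] = v
        return out

    def triplets(self) -> list[tuple[str, str, float]]:
        return [
            (self.users[i], self.items[j], v)
            for (i, j), v in sorted(self._data.items())
        ]

    def subset_users(self, keep: Iterable[str]) -> "RatingMatrix":
        keep = [u for u in self.users if u in set(keep)]
        sub = RatingMatrix(keep, self.items)
        for u in keep:
            for m, v in self.user_ratings(u).items():
                sub.set(u, m, v)
        return sub

    def copy(self) -> "RatingMatrix":
        out = RatingMatrix(self.users, self.items)
        out._data = dict(self._data)
        return out

    @classmethod
    def from_events(
        cls,
        events: Iterable[RatingEvent],
        users: Sequence[str] | None = None,
        items: Sequence[str] | None = None,
    ) -> "RatingMatrix":
        events = list(events)
        if users is None:
            users = sorted({e.user_id for e in events})
        if items is None:
            items = sorted({e.message_id for e in events})
        mat = cls(users, items)
        for e in events:
            if e.value is not None:
                mat.set(e.user_id, e.message_id, e.value)
        return mat


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MESSAGE_COLUMNS = ("message_id", "text", "source", "tags")


def load_message_bank(path: str | Path) -> list[Message]:
    """Read a message bank from a JSON array or a CSV file.

    JSON: ``[{"message_id": ..., "text": ..., "source": ..., "tags": [...]}]``.
    CSV: same columns, tags as a ``;``-separated field. Duplicate ids,
    empty text and unknown sources are rejected with the offending record
    named.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text() or "[]")
        records = [dict(r) for r in raw]
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                records = []
            else:
                missing = set(_MESSAGE_COLUMNS[:3]) - set(reader.fieldnames)
                if missing:
                    raise ValidationError(
                        f"{path.name}: missing column(s) {sorted(missing)}"
                    )
                records = list(reader)
                for r in records:
                    r["tags"] = [t for t in (r.get("tags") or "").split(";") if t]
    bank: list[Message] = []
    seen: set[str] = set()
    for r in records:
        for col in _MESSAGE_COLUMNS[:3]:
            if col not in r:
                raise ValidationError(f"{path.name}: record missing field {col!r}")
        mid = str(r["message_id"])
        if mid in seen:
            raise ValidationError(f"{path.name}: duplicate message_id {mid!r}")
        seen.add(mid)
        bank.append(
            Message(
                message_id=mid,
                text=str(r["text"]),
                source=str(r["source"]),
                tags=frozenset(r.get("tags") or ()),
            )
        )
    return bank


def write_message_bank(bank: Sequence[Message], path: str | Path) -> None:
    payload = [
        {
            "message_id": m.message_id,
            "text": m.text,
            "source": m.source,
            "tags": sorted(m.tags),
        }
        for m in bank
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


_PROFILE_COLUMNS = (
    "user_id",
    "group",
    "gender",
    "age_band",
    "education",
    "ethnicity",
    "allow_smoking_home",
    "visited_cessation_site",
    "past_year_quit_attempt",
    "smoking_status",
    "readiness",
)

_BOOL_PROFILE_FIELDS = (
    "allow_smoking_home",
    "visited_cessation_site",
    "past_year_quit_attempt",
)


def _parse_bool(raw: str, where: str) -> bool:
    if raw in ("1", "true", "True", "yes"):
        return True
    if raw in ("0", "false", "False", "no"):
        return False
    raise ValidationError(f"{where}: boolean field has value {raw!r}")


def load_profiles(path: str | Path) -> list[UserProfile]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(_PROFILE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path.name}: missing column(s) {sorted(missing)}")
        out: list[UserProfile] = []
        seen: set[str] = set()
        for row in reader:
            uid = row["user_id"]
            if uid in seen:
                raise ValidationError(f"{path.name}: duplicate user_id {uid!r}")
            seen.add(uid)
            kwargs = {c: row[c] for c in _PROFILE_COLUMNS}
            for b in _BOOL_PROFILE_FIELDS:
                kwargs[b] = _parse_bool(row[b], f"{path.name} user {uid!r}")
            out.append(UserProfile(**kwargs))
    return out


def write_profiles(profiles: Sequence[UserProfile], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PROFILE_COLUMNS)
        for p in profiles:
            writer.writerow(
                [
                    p.user_id,
                    p.group,
                    p.gender,
                    p.age_band,
                    p.education,
                    p.ethnicity,
                    int(p.allow_smoking_home),
                    int(p.visited_cessation_site),
                    int(p.past_year_quit_attempt),
                    p.smoking_status,
                    p.readiness,
                ]
            )


_RATING_COLUMNS = ("user_id", "message_id", "day_index", "value")


def load_ratings(
    path: str | Path,
    bank: Sequence[Message] | None = None,
    roster: Sequence[str] | None = None,
) -> tuple[RatingMatrix, list[RatingEvent]]:
    """Read a rating-event CSV into a sparse matrix plus the event list.

    When ``bank``/``roster`` are given, every referenced message/user id
    must exist in them; the matrix axes then follow the bank and roster
    order rather than the order of appearance.
    """
    path = Path(path)
    known_items = None if bank is None else {m.message_id for m in bank}
    known_users = None if roster is None else set(roster)
    events: list[RatingEvent] = []
    seen_pairs: set[tuple[str, str]] = set()
    seen_days: set[tuple[str, int]] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is not None:
            missing = set(_RATING_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise ValidationError(
                    f"{path.name}: missing column(s) {sorted(missing)}"
                )
            for lineno, row in enumerate(reader, start=2):
                uid, mid = row["user_id"], row["message_id"]
                if known_users is not None and uid not in known_users:
                    raise ValidationError(
                        f"{path.name} line {lineno}: unknown user id {uid!r}"
                    )
                if known_items is not None and mid not in known_items:
                    raise ValidationError(
                        f"{path.name} line {lineno}: unknown message id {mid!r}"
                    )
                raw = (row["value"] or "").strip()
                if raw == "":
                    value: Optional[int] = None
                else:
                    try:
                        fv = float(raw)
                    except ValueError:
                        raise ValidationError(
                            f"{path.name} line {lineno}: unparseable rating {raw!r}"
                        ) from None
                    if not fv.is_integer() or not (1 <= fv <= 5):
                        raise ValidationError(
                            f"{path.name} line {lineno}: rating {raw} outside 1-5"
                        )
                    value = int(fv)
                if (uid, mid) in seen_pairs:
                    raise ValidationError(
                        f"{path.name} line {lineno}: duplicate event for "
                        f"user {uid!r} and message {mid!r}"
                    )
                day = int(row["day_index"])
                if (uid, day) in seen_days:
                    raise ValidationError(
                        f"{path.name} line {lineno}: user {uid!r} already has "
                        f"an event on day {day}"
                    )
                seen_pairs.add((uid, mid))
                seen_days.add((uid, day))
                events.append(RatingEvent(uid, mid, day, value))
    users = list(roster) if roster is not None else sorted({e.user_id for e in events})
    items = (
        [m.message_id for m in bank]
        if bank is not None
        else sorted({e.message_id for e in events})
    )
    return RatingMatrix.from_events(events, users, items), events


def write_ratings(events: Sequence[RatingEvent], path: str | Path) -> None:
    """Write events as CSV; missing ratings become empty fields."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RATING_COLUMNS)
        for e in events:
            writer.writerow(
                [e.user_id, e.message_id, e.day_index, "" if e.value is None else e.value]
            )


_TRIAL_COLUMNS = ("user_id", "group", "website_visits") + tuple(
    f"impact_{i}" for i in range(1, N_IMPACT_ITEMS + 1)
) + ("quit_30day",)


def load_trial(path: str | Path) -> list[TrialRecord]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(_TRIAL_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path.name}: missing column(s) {sorted(missing)}")
        out: list[TrialRecord] = []
        for row in reader:
            items: list[Optional[int]] = []
            for i in range(1, N_IMPACT_ITEMS + 1):
                raw = (row[f"impact_{i}"] or "").strip()
                items.append(None if raw == "" else int(raw))
            rawq = (row["quit_30day"] or "").strip()
            quit_flag = None if rawq == "" else _parse_bool(
                rawq, f"{path.name} user {row['user_id']!r}"
            )
            out.append(
                TrialRecord(
                    user_id=row["user_id"],
                    group=row["group"],
                    website_visits=int(row["website_visits"]),
                    impact_items=tuple(items),
                    quit_30day=quit_flag,
                )
            )
    return out


def write_trial(records: Sequence[TrialRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRIAL_COLUMNS)
        for r in records:
            writer.writerow(
                [r.user_id, r.group, r.website_visits]
                + ["" if v is None else v for v in r.impact_items]
                + ["" if r.quit_30day is None else int(r.quit_30day)]
            )
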