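"""The daily tailoring loop.

Each active user receives at most one message per study day: the
highest-predicted message they have not yet been sent. A reply rating (1-5,
optional) is ingested immediately and the user's latent factor re-inferred
from their accumulated ratings, so the next day's pick reflects all
feedback so far — the more a user rates, the more personalised the stream
becomes. Item factors stay frozen throughout, mirroring the cold-start
contract under which the models are evaluated.

Hard limits: at most 30 messages per user, within a 65-day window; the
schedule deactivates at whichever limit is hit first. The send-day cadence
is configurable (default: consecutive days), but the limits hold for any
skip pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import Message, RatingEvent
from .recommenders import (
    ColdUserFactor,
    FactorModel,
    infer_user_factors,
    predict_from_factor,
    rank_messages,
)

__all__ = ["ScheduleState", "next_message", "ingest_rating", "advance_day", "simulate_user_run"]

MAX_MESSAGES = 30
MAX_DAYS = 65


@dataclass
class ScheduleState:
    """Per-user scheduling state.

    ``day_index`` is 1-based (day 1 = first message day). The state goes
    inactive once 30 messages have been sent or day 65 has elapsed.
    """

    user_id: str
    day_index: int = 1
    sent: list[str] = field(default_factory=list)
    ratings: dict[str, float] = field(default_factory=dict)
    max_messages: int = MAX_MESSAGES
    max_days: int = MAX_DAYS
    active: bool = True
    factor: Optional[ColdUserFactor] = None
    seed: int = 0

    @property
    def messages_sent(self) -> int:
        return len(self.sent)

    def _check_limits(self) -> None:
        if self.messages_sent >= self.max_messages or self.day_index > self.max_days:
            self.active = False


def next_message(
    state: ScheduleState,
    model: FactorModel,
    bank: Sequence[Message],
) -> Optional[str]:
    """Pick and record today's message: the highest-predicted unsent one.

    Ties break by ascending message id (deterministic across runs).
    Returns None ("done") when the user is inactive or the bank is
    exhausted. A user who has rated nothing is scored from the prior-mean
    factor, i.e. effectively by the global mean — the system always has a
    message to send.
    """
    if not state.active:
        return None
    sent = set(state.sent)
    candidates = [m.message_id for m in bank if m.message_id not in sent]
    if not candidates:
        state.active = False
        return None
    if state.factor is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            state.factor = infer_user_factors(model, state.ratings, seed=state.seed)
    ranked = rank_messages(model, state.factor, candidates)
    choice = ranked[0][0]
    assert choice not in sent, "a message may never be sent twice to a user"
    state.sent.append(choice)
    state._check_limits()
    return choice


def ingest_rating(
    state: ScheduleState, model: FactorModel, event: RatingEvent
) -> None:
    """Record a reply rating and re-infer the user's factor.

    Only sent messages may be rated. A missing value (message sent, no
    reply) changes nothing in the model view. Item factors are never
    touched — personalisation happens entirely in the user factor.
    """
    if event.message_id not in state.sent:
        raise ValueError(
            f"user {state.user_id!r} was never sent message {event.message_id!r}"
        )
    if event.value is None:
        return
    state.ratings[event.message_id] = float(event.value)
    state.factor = infer_user_factors(model, state.ratings, seed=state.seed)


def advance_day(state: ScheduleState) -> ScheduleState:
    """Move to the next study day; deactivate past day 65 or at 30 sends."""
    if not state.active:
        warnings.warn(
            f"advance_day on inactive schedule for user {state.user_id!r}",
            RuntimeWarning,
        )
        return state
    state.day_index += 1
    state._check_limits()
    return state


def simulate_user_run(
    model: FactorModel,
    bank: Sequence[Message],
    user_id: str,
    rating_policy,
    seed: int = 0,
    send_days: Optional[Sequence[int]] = None,
) -> list[RatingEvent]:
    """Run one user through the full window and return their event stream.

    ``rating_policy(message_id, day_index) -> int | None`` decides the
    reply each day (None = no reply). ``send_days`` restricts sending to
    a subset of days (e.g. weekdays); by default every day is a send day.
    """
    state = ScheduleState(user_id=user_id, seed=seed)
    allowed = None if send_days is None else set(send_days)
    events: list[RatingEvent] = []
    while state.active:
        if allowed is None or state.day_index in allowed:
            mid = next_message(state, model, bank)
            if mid is not None:
                value = rating_policy(mid, state.day_index)
                event = RatingEvent(user_id, mid, state.day_index, value)
                events.append(event)
                ingest_rating(state, model, event)
        if state.active:
            advance_day(state)
    return events
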