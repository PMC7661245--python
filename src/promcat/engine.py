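"""The adaptive loop: select the most informative item, update, stop.

After each response the engine re-estimates theta (EAP) over the full
pattern, then selects the unadministered item with maximum Fisher
information at the current estimate (ties broken by bank order, first
wins). Before any response the estimate is the prior mean, so the first
item is the most informative one at theta = 0. The test stops when a
stopping rule fires: minimum SEM reached (checked only once at least one
item has been answered, so a prior SD below threshold cannot produce a
zero-item test), maximum item count, elapsed-time limit, or bank
exhaustion — reported with that precedence.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

from .estimation import AbilityEstimate, ResponsePattern, eap_estimate
from .grm import ThetaGrid, item_information
from .item_bank import ItemBank

__all__ = [
    "StoppingRules",
    "CatState",
    "SessionError",
    "select_next_item",
    "should_stop",
    "advance",
    "run_session",
    "EngineSessionRecord",
]


class SessionError(RuntimeError):
    """The adaptive session was driven into an invalid transition."""


@dataclass(frozen=True)
class StoppingRules:
    """Termination conditions; at least one must be set.

    ``min_sem`` is the SEM threshold the test must reach before stopping
    (0.5, i.e. marginal reliability ~0.75, is the conventional choice for
    PROMs); ``max_items`` caps the number of administered items;
    ``max_seconds`` caps wall-clock duration.
    """

    min_sem: float | None = None
    max_items: int | None = None
    max_seconds: float | None = None

    def __post_init__(self) -> None:
        if self.min_sem is None and self.max_items is None and self.max_seconds is None:
            raise ValueError("at least one stopping rule must be set")
        if self.min_sem is not None and self.min_sem <= 0:
            raise ValueError("min_sem must be positive")
        if self.max_items is not None and self.max_items < 1:
            raise ValueError("max_items must be at least 1")
        if self.max_seconds is not None and self.max_seconds <= 0:
            raise ValueError("max_seconds must be positive")


@dataclass(frozen=True)
class CatState:
    """Immutable snapshot of a session between steps."""

    administered: ResponsePattern
    remaining: tuple[str, ...]
    estimate: AbilityEstimate
    stopped: bool = False
    stop_reason: str = ""

    def __post_init__(self) -> None:
        if self.stopped and not self.stop_reason:
            raise ValueError("a stopped state must carry a stop reason")
        admin_ids = {i for i, _ in self.administered.entries}
        if admin_ids & set(self.remaining):
            raise ValueError("administered and remaining overlap")

    @classmethod
    def initial(cls, bank: ItemBank, grid: ThetaGrid | None = None) -> "CatState":
        pattern = ResponsePattern()
        return cls(
            administered=pattern,
            remaining=bank.item_ids,
            estimate=eap_estimate(pattern, bank, grid),
        )


def select_next_item(state: CatState, bank: ItemBank) -> str:
    """Most informative remaining item at the current theta estimate.

    Ties broken by bank order (first wins). Raises :class:`SessionError`
    if no items remain (the caller should have stopped).
    """
    if state.stopped:
        raise SessionError("cannot select an item in a stopped session")
    if not state.remaining:
        raise SessionError("item bank exhausted: nothing left to select")
    theta = state.estimate.theta
    best_id, best_info = None, -1.0
    for item_id in sorted(state.remaining, key=bank.position):
        info = item_information(bank[item_id], theta)
        if info > best_info:
            best_id, best_info = item_id, info
    return best_id


def should_stop(
    state: CatState, rules: StoppingRules, elapsed: float = 0.0
) -> tuple[bool, str]:
    """Evaluate the stopping rules; the reason reports the first rule met.

    Precedence: min_sem -> max_items -> max_seconds -> bank_exhausted.
    """
    n = len(state.administered)
    if rules.min_sem is not None and n >= 1 and state.estimate.sem <= rules.min_sem:
        return True, "min_sem"
    if rules.max_items is not None and n >= rules.max_items:
        return True, "max_items"
    if rules.max_seconds is not None and elapsed >= rules.max_seconds:
        return True, "max_seconds"
    if not state.remaining:
        return True, "bank_exhausted"
    return False, ""


def advance(
    state: CatState,
    item_id: str,
    category: int,
    bank: ItemBank,
    grid: ThetaGrid | None = None,
) -> CatState:
    """Record a response and re-estimate theta over the full pattern."""
    if state.stopped:
        raise SessionError("cannot advance a stopped session")
    if item_id not in state.remaining:
        raise SessionError(
            f"item {item_id!r} is not awaiting administration in this session"
        )
    item = bank[item_id]
    if not 0 <= category < item.n_categories:
        raise SessionError(
            f"category {category} invalid for item {item_id!r} "
            f"with {item.n_categories} categories"
        )
    pattern = state.administered.with_response(item_id, category)
    return replace(
        state,
        administered=pattern,
        remaining=tuple(i for i in state.remaining if i != item_id),
        estimate=eap_estimate(pattern, bank, grid),
    )


@dataclass(frozen=True)
class EngineSessionRecord:
    """Raw outcome of one adaptive administration.

    ``steps`` holds (item_id, category, theta_after, sem_after) per
    administered item, in order.
    """

    steps: tuple[tuple[str, int, float, float], ...]
    final: AbilityEstimate
    stop_reason: str


def run_session(
    bank: ItemBank,
    rules: StoppingRules,
    responder,
    grid: ThetaGrid | None = None,
    clock=time.monotonic,
) -> EngineSessionRecord:
    """Loop select -> present -> advance -> check-stop until a rule fires.

    ``responder(item)`` must return a category index ``0..K-1`` for the
    presented item; a returned ``None`` aborts the session cleanly
    (stop reason ``"aborted"``). An invalid category raises
    :class:`SessionError` after recording nothing for that item.
    """
    if grid is None:
        grid = ThetaGrid.standard_normal()
    start = clock()
    state = CatState.initial(bank, grid)
    steps: list[tuple[str, int, float, float]] = []
    while True:
        stop, reason = should_stop(state, rules, elapsed=clock() - start)
        if stop:
            break
        item_id = select_next_item(state, bank)
        category = responder(bank[item_id])
        if category is None:
            reason = "aborted"
            break
        state = advance(state, item_id, int(category), bank, grid)
        steps.append(
            (item_id, int(category), state.estimate.theta, state.estimate.sem)
        )
    return EngineSessionRecord(
        steps=tuple(steps), final=state.estimate, stop_reason=reason
    )
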