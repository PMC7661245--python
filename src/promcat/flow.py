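"""Assessment flow: score, render feedback, persist responses.

Mirrors the node sequence of a simple adaptive assessment: the adaptive
engine produces (theta, sem); a scoring node maps theta onto a percentile
of a normal reference population, ``percent = 100 * Phi((theta - mean) / sd)``
(default mean 0, SD 1); a feedback page substitutes ``{{theta}}``,
``{{sem}}`` and ``{{percent}}`` into a template; and the whole session is
appended to a flat CSV response store, one row per administered item plus a
summary row.

Display formatting: theta and sem render to 2 decimals, percent to 1
decimal (configurable). Stored numbers keep full precision; formatting
happens only at render time, so nothing is double-rounded.
"""

from __future__ import annotations

import csv
import re
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from scipy.stats import norm

from .engine import StoppingRules, run_session
from .estimation import AbilityEstimate
from .grm import ThetaGrid
from .item_bank import ItemBank

__all__ = [
    "ScoringSpec",
    "FeedbackTemplate",
    "SessionRecord",
    "CatConfig",
    "FlowError",
    "TemplateError",
    "StoreConflictError",
    "percentile_score",
    "render_feedback",
    "persist_session",
    "load_sessions",
    "run_flow",
    "DEFAULT_TEMPLATE_TEXT",
]

DEFAULT_TEMPLATE_TEXT = (
    "Theta is {{theta}}. SEM is {{sem}}.\n"
    "Your score is higher than {{percent}}% of the general population."
)


class FlowError(RuntimeError):
    """A flow node failed; the message names the node."""


class TemplateError(ValueError):
    """Feedback template contains an unknown placeholder."""


class StoreConflictError(ValueError):
    """The response store already contains this session_id."""


@dataclass(frozen=True)
class ScoringSpec:
    """Percentile scoring against a normal reference population."""

    score_type: str = "percentile_normal"
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.score_type != "percentile_normal":
            raise ValueError(f"unsupported score_type {self.score_type!r}")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


_PLACEHOLDER = re.compile(r"\{\{\s*(\w+)\s*\}\}")
_KNOWN_PLACEHOLDERS = frozenset({"theta", "sem", "percent"})


@dataclass(frozen=True)
class FeedbackTemplate:
    """Feedback text with ``{{theta}}``, ``{{sem}}``, ``{{percent}}`` slots.

    Unknown placeholder names are rejected at construction.
    """

    text: str

    def __post_init__(self) -> None:
        unknown = set(self.placeholders) - _KNOWN_PLACEHOLDERS
        if unknown:
            raise TemplateError(
                f"unknown placeholder(s) {sorted(unknown)}; "
                f"allowed: {sorted(_KNOWN_PLACEHOLDERS)}"
            )

    @property
    def placeholders(self) -> tuple[str, ...]:
        return tuple(m.group(1) for m in _PLACEHOLDER.finditer(self.text))


@dataclass(frozen=True)
class SessionRecord:
    """Complete record of one assessment run.

    ``steps`` holds (item_id, category, theta_after, sem_after) per step.
    ``percent`` is stored at full precision; formatting is render-only.
    """

    session_id: str
    started_at: str
    ended_at: str
    steps: tuple[tuple[str, int, float, float], ...]
    final: AbilityEstimate
    percent: float
    stop_reason: str
    rendered_feedback: str


def percentile_score(theta: float, spec: ScoringSpec) -> float:
    """Percent of the reference population scoring below theta, in [0, 100].

    Strictly increasing in theta; exactly 50 at theta = mean.
    """
    return 100.0 * float(norm.cdf((theta - spec.mean) / spec.sd))


def render_feedback(
    template: FeedbackTemplate,
    estimate: AbilityEstimate,
    percent: float,
    *,
    theta_decimals: int = 2,
    sem_decimals: int = 2,
    percent_decimals: int = 1,
) -> str:
    """Substitute formatted values for every placeholder; no braces remain."""
    values = {
        "theta": f"{estimate.theta:.{theta_decimals}f}",
        "sem": f"{estimate.sem:.{sem_decimals}f}",
        "percent": f"{percent:.{percent_decimals}f}",
    }

    def substitute(match: re.Match) -> str:
        name = match.group(1)
        if name not in values:
            raise TemplateError(f"no value bound for placeholder {name!r}")
        return values[name]

    return _PLACEHOLDER.sub(substitute, template.text)


# Response store schema: one CSV per store, append-mode. Step rows carry the
# per-item response and the post-response estimate; the summary row carries
# the final estimate, percentile, stop reason and rendered feedback. The
# timestamp column holds started_at on step rows and ended_at on the summary.
_STORE_COLUMNS = [
    "session_id",
    "row_type",
    "seq",
    "item_id",
    "response",
    "theta",
    "sem",
    "percent",
    "stop_reason",
    "timestamp",
    "feedback",
]


def persist_session(record: SessionRecord, store) -> None:
    """Append a session to the flat response store (CSV).

    Raises :class:`StoreConflictError` if the store already holds the
    session_id, and OSError on write failure.
    """
    store = Path(store)
    exists = store.exists() and store.stat().st_size > 0
    if exists and any(r.session_id == record.session_id for r in load_sessions(store)):
        raise StoreConflictError(
            f"session {record.session_id!r} already persisted in {store}"
        )
    with open(store, "a", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_STORE_COLUMNS)
        if not exists:
            writer.writeheader()
        for seq, (item_id, category, theta, sem) in enumerate(record.steps, start=1):
            writer.writerow(
                {
                    "session_id": record.session_id,
                    "row_type": "step",
                    "seq": seq,
                    "item_id": item_id,
                    "response": category,
                    "theta": repr(theta),
                    "sem": repr(sem),
                    "percent": "",
                    "stop_reason": "",
                    "timestamp": record.started_at,
                    "feedback": "",
                }
            )
        writer.writerow(
            {
                "session_id": record.session_id,
                "row_type": "summary",
                "seq": len(record.steps),
                "item_id": "",
                "response": "",
                "theta": repr(record.final.theta),
                "sem": repr(record.final.sem),
                "percent": repr(record.percent),
                "stop_reason": record.stop_reason,
                "timestamp": record.ended_at,
                "feedback": record.rendered_feedback,
            }
        )


def load_sessions(store) -> list[SessionRecord]:
    """Re-read a response store into SessionRecords (lossless for numbers)."""
    store = Path(store)
    steps: dict[str, list[tuple[str, int, float, float]]] = {}
    started: dict[str, str] = {}
    records: list[SessionRecord] = []
    with open(store, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            sid = row["session_id"]
            if row["row_type"] == "step":
                steps.setdefault(sid, []).append(
                    (
                        row["item_id"],
                        int(row["response"]),
                        float(row["theta"]),
                        float(row["sem"]),
                    )
                )
                started.setdefault(sid, row["timestamp"])
            elif row["row_type"] == "summary":
                session_steps = tuple(steps.get(sid, []))
                records.append(
                    SessionRecord(
                        session_id=sid,
                        started_at=started.get(sid, row["timestamp"]),
                        ended_at=row["timestamp"],
                        steps=session_steps,
                        final=AbilityEstimate(
                            theta=float(row["theta"]),
                            sem=float(row["sem"]),
                            n_responses=len(session_steps),
                        ),
                        percent=float(row["percent"]),
                        stop_reason=row["stop_reason"],
                        rendered_feedback=row["feedback"],
                    )
                )
    return records


@dataclass(frozen=True)
class CatConfig:
    """Run configuration mirroring the assessment wizard's fields.

    ``model`` must be ``"GRM"``; ``order`` is ``"CAT"`` (adaptive) or
    ``"fixed"`` (administer the bank in file order, non-adaptive).
    """

    stopping: StoppingRules
    scoring: ScoringSpec = ScoringSpec()
    template: FeedbackTemplate = FeedbackTemplate(DEFAULT_TEMPLATE_TEXT)
    model: str = "GRM"
    order: str = "CAT"
    bank_path: str | None = None
    store_path: str | None = None
    seed: int | None = None
    theta_decimals: int = 2
    sem_decimals: int = 2
    percent_decimals: int = 1

    def __post_init__(self) -> None:
        if self.model != "GRM":
            raise ValueError(f"unsupported model {self.model!r}; only GRM")
        if self.order not in ("CAT", "fixed"):
            raise ValueError(f"order must be 'CAT' or 'fixed', got {self.order!r}")


def run_flow(
    bank: ItemBank,
    config: CatConfig,
    responder,
    grid: ThetaGrid | None = None,
    *,
    session_id: str | None = None,
    clock=None,
) -> SessionRecord:
    """Execute assessment -> scoring -> feedback and persist the record.

    The assessment node runs the adaptive session (or fixed-order
    administration), the scoring node converts the final theta to a
    percentile, and the feedback node renders the template with
    (theta, sem, percent). Component failures are re-raised as
    :class:`FlowError` naming the node.
    """
    started_at = _now()
    sid = session_id or uuid.uuid4().hex
    try:
        if config.order == "fixed":
            engine_record = _run_fixed(bank, config.stopping, responder, grid)
        else:
            kwargs = {"clock": clock} if clock is not None else {}
            engine_record = run_session(
                bank, config.stopping, responder, grid, **kwargs
            )
    except Exception as exc:
        raise FlowError(f"assessment node failed: {exc}") from exc
    try:
        percent = percentile_score(engine_record.final.theta, config.scoring)
    except Exception as exc:
        raise FlowError(f"scoring node failed: {exc}") from exc
    try:
        rendered = render_feedback(
            config.template,
            engine_record.final,
            percent,
            theta_decimals=config.theta_decimals,
            sem_decimals=config.sem_decimals,
            percent_decimals=config.percent_decimals,
        )
    except Exception as exc:
        raise FlowError(f"feedback node failed: {exc}") from exc
    record = SessionRecord(
        session_id=sid,
        started_at=started_at,
        ended_at=_now(),
        steps=engine_record.steps,
        final=engine_record.final,
        percent=percent,
        stop_reason=engine_record.stop_reason,
        rendered_feedback=rendered,
    )
    if config.store_path is not None:
        try:
            persist_session(record, config.store_path)
        except StoreConflictError:
            raise
        except Exception as exc:
            raise FlowError(f"persistence node failed: {exc}") from exc
    return record


def _run_fixed(bank, rules, responder, grid):
    """Non-adaptive administration: items in file order, same stopping rules."""
    from .engine import CatState, advance, should_stop

    if grid is None:
        grid = ThetaGrid.standard_normal()
    state = CatState.initial(bank, grid)
    steps = []
    reason = ""
    for item_id in bank.item_ids:
        stop, reason = should_stop(state, rules)
        if stop:
            break
        category = responder(bank[item_id])
        if category is None:
            reason = "aborted"
            break
        state = advance(state, item_id, int(category), bank, grid)
        steps.append(
            (item_id, int(category), state.estimate.theta, state.estimate.sem)
        )
    else:
        _, reason = should_stop(state, rules)
    from .engine import EngineSessionRecord

    return EngineSessionRecord(
        steps=tuple(steps), final=state.estimate, stop_reason=reason
    )


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()
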