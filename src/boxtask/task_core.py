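"""Box Task structure: layouts, target schedules, the search/trial/session
state machine, and the canonical session-log data model.

The Box Task is a self-ordered search test: closed boxes appear at fixed
screen locations and the participant opens them one by one to find a hidden
target.  When a target is found it stays hidden in its box and a new target
is hidden in one of the remaining boxes; a *search* ends when the current
target is found, and a *trial* comprises one search per box.  A session is
two practice trials of 3 boxes followed by two trials each at set sizes
4, 6 and 8.

Targets are pre-assigned one per box as a seeded random permutation: box
``target_order[k-1]`` hides the target of search ``k``.  Coordinates live on
an abstract 100x100 canvas and matter only for log fidelity, never for
scoring.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

SET_SIZES = (4, 6, 8)
PRACTICE_SET_SIZE = 3
#: session layout: two practice trials then two trials per test set size
SESSION_SET_SIZES = (3, 3, 4, 4, 6, 6, 8, 8)

VALID_SET_SIZES = frozenset({3, 4, 6, 8})

EMPTY = "empty"
TARGET_FOUND = "target_found"
TRIAL_COMPLETE = "trial_complete"


class BoxTaskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BoxTaskError):
    """Layout/canvas configuration cannot be satisfied."""


class DomainError(BoxTaskError, ValueError):
    """Operation called outside its domain (bad index, incomplete trial...)."""


class ParseError(BoxTaskError):
    """Session-log file violates the documented schema."""


# ---------------------------------------------------------------------------
# layout configuration and specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayoutConfig:
    """Canvas bounds (abstract units) and minimum pairwise box separation."""

    canvas_width: float = 100.0
    canvas_height: float = 100.0
    min_separation: float = 15.0
    max_placement_attempts: int = 5000


@dataclass(frozen=True)
class BoxLayout:
    set_size: int
    positions: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.set_size not in VALID_SET_SIZES:
            raise DomainError(f"set_size must be one of {sorted(VALID_SET_SIZES)}, got {self.set_size}")
        if len(self.positions) != self.set_size:
            raise DomainError("positions must have one entry per box")


@dataclass(frozen=True)
class TrialSpec:
    layout: BoxLayout
    target_order: tuple[int, ...]
    trial_index: int  # 1-based position within the session
    is_practice: bool = False

    def __post_init__(self) -> None:
        n = self.layout.set_size
        if sorted(self.target_order) != list(range(n)):
            raise DomainError(f"target_order must be a permutation of 0..{n - 1}")

    @property
    def set_size(self) -> int:
        return self.layout.set_size


@dataclass(frozen=True)
class SessionSpec:
    participant_id: str
    trials: tuple[TrialSpec, ...]
    seed: int


@dataclass(frozen=True)
class OpenEvent:
    box_index: int
    timestamp: float
    outcome: str  # EMPTY or TARGET_FOUND


@dataclass(frozen=True)
class SearchRecord:
    search_index: int  # 1-based k-th target sought
    opens: tuple[OpenEvent, ...]

    @property
    def path(self) -> list[int]:
        return [o.box_index for o in self.opens]


@dataclass(frozen=True)
class TrialRecord:
    spec: TrialSpec
    searches: tuple[SearchRecord, ...]

    @property
    def is_complete(self) -> bool:
        return len(self.searches) == self.spec.set_size and all(
            s.opens and s.opens[-1].outcome == TARGET_FOUND for s in self.searches
        )

    def all_opens(self) -> list[OpenEvent]:
        return [o for s in self.searches for o in s.opens]


@dataclass
class SessionRecord:
    spec: SessionSpec
    trials: tuple[TrialRecord, ...]
    metadata: dict = field(default_factory=dict)

    def test_trials(self) -> list[TrialRecord]:
        """The six scored (non-practice) trials, in session order."""
        return [t for t in self.trials if not t.spec.is_practice]


# ---------------------------------------------------------------------------
# spec construction
# ---------------------------------------------------------------------------


def _place_boxes(n: int, cfg: LayoutConfig, rng: np.random.Generator) -> tuple[tuple[float, float], ...]:
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < n:
        if attempts >= cfg.max_placement_attempts:
            raise ConfigurationError(
                f"could not place {n} boxes with separation {cfg.min_separation} "
                f"on a {cfg.canvas_width}x{cfg.canvas_height} canvas"
            )
        attempts += 1
        x = float(rng.uniform(0.0, cfg.canvas_width))
        y = float(rng.uniform(0.0, cfg.canvas_height))
        if all(math.hypot(x - px, y - py) >= cfg.min_separation for px, py in positions):
            positions.append((round(x, 3), round(y, 3)))
    return tuple(positions)


def build_session_spec(
    seed: int,
    layout_config: LayoutConfig | None = None,
    participant_id: str = "sim",
) -> SessionSpec:
    """Build the canonical session: 2 practice 3-box trials, then 2x4, 2x6, 2x8.

    A pure function of ``(seed, layout_config)``: positions and target orders
    are drawn from a generator seeded with ``seed``.
    """
    if seed < 0:
        raise DomainError("seed must be non-negative")
    cfg = layout_config or LayoutConfig()
    rng = np.random.default_rng(seed)
    trials = []
    for idx, n in enumerate(SESSION_SET_SIZES, start=1):
        layout = BoxLayout(set_size=n, positions=_place_boxes(n, cfg, rng))
        order = tuple(int(i) for i in rng.permutation(n))
        trials.append(TrialSpec(layout=layout, target_order=order, trial_index=idx, is_practice=(n == PRACTICE_SET_SIZE)))
    return SessionSpec(participant_id=participant_id, trials=tuple(trials), seed=int(seed))


# ---------------------------------------------------------------------------
# trial state machine
# ---------------------------------------------------------------------------


class TrialState:
    """In-progress trial; append opens via :func:`open_box` until complete."""

    def __init__(self, spec: TrialSpec):
        self.spec = spec
        self.current_search = 1  # 1-based
        self.searches: list[SearchRecord] = []
        self._current_opens: list[OpenEvent] = []
        self.last_timestamp = -math.inf
        self.complete = False

    @property
    def current_target(self) -> int:
        return self.spec.target_order[self.current_search - 1]

    def found_targets(self) -> list[int]:
        """Boxes whose targets were found in completed searches."""
        return list(self.spec.target_order[: self.current_search - 1])

    def current_opens(self) -> list[OpenEvent]:
        return list(self._current_opens)

    def to_record(self) -> TrialRecord:
        if not self.complete:
            raise DomainError("trial not complete")
        return TrialRecord(spec=self.spec, searches=tuple(self.searches))


def open_box(state: TrialState, box_index: int, timestamp: float) -> str:
    """Open a box; returns EMPTY, TARGET_FOUND or TRIAL_COMPLETE.

    TARGET_FOUND is returned iff ``box_index`` is the current search's target;
    finding the final target returns TRIAL_COMPLETE instead.
    """
    if state.complete:
        raise DomainError("trial already complete")
    n = state.spec.set_size
    if not (0 <= box_index < n):
        raise DomainError(f"box_index {box_index} out of range for set size {n}")
    if timestamp <= state.last_timestamp:
        raise DomainError(f"timestamp {timestamp} not after previous {state.last_timestamp}")
    state.last_timestamp = timestamp

    hit = box_index == state.current_target
    event = OpenEvent(box_index=int(box_index), timestamp=float(timestamp), outcome=TARGET_FOUND if hit else EMPTY)
    state._current_opens.append(event)
    if not hit:
        return EMPTY
    state.searches.append(SearchRecord(search_index=state.current_search, opens=tuple(state._current_opens)))
    state._current_opens = []
    if state.current_search == n:
        state.complete = True
        return TRIAL_COMPLETE
    state.current_search += 1
    return TARGET_FOUND


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    rule: str
    trial_index: int | None
    search_index: int | None
    message: str


def validate_session(record: SessionRecord) -> list[Violation]:
    """Check every structural invariant; returns violations, raises nothing."""
    out: list[Violation] = []

    def bad(rule: str, trial: int | None, search: int | None, msg: str) -> None:
        out.append(Violation(rule, trial, search, msg))

    if len(record.trials) != len(record.spec.trials):
        bad("SessionRecord.alignment", None, None, "trials do not align one-to-one with spec.trials")

    sizes = tuple(t.set_size for t in record.spec.trials)
    if sizes != SESSION_SET_SIZES:
        bad("SessionSpec.trial_order", None, None, f"set sizes {sizes} != {SESSION_SET_SIZES}")

    for trial in record.trials:
        ti = trial.spec.trial_index
        n = trial.spec.set_size
        pos = trial.spec.layout.positions
        if len(set(pos)) != len(pos):
            bad("BoxLayout.distinct_positions", ti, None, "positions not pairwise distinct")
        if sorted(trial.spec.target_order) != list(range(n)):
            bad("TrialSpec.target_permutation", ti, None, "target_order is not a permutation")
        if len(trial.searches) != n:
            bad("TrialRecord.search_count", ti, None, f"{len(trial.searches)} searches for set size {n}")
        prev_t = -math.inf
        for search in trial.searches:
            si = search.search_index
            if not search.opens:
                bad("SearchRecord.nonempty", ti, si, "search has no opens")
                continue
            if search.opens[-1].outcome != TARGET_FOUND:
                bad("SearchRecord.terminal_target_found", ti, si, "last open is not target_found")
            for o in search.opens[:-1]:
                if o.outcome == TARGET_FOUND:
                    bad("SearchRecord.single_target", ti, si, "non-terminal open marked target_found")
            for o in search.opens:
                if not (0 <= o.box_index < n):
                    bad("OpenEvent.box_range", ti, si, f"box {o.box_index} out of range")
                if o.timestamp <= prev_t:
                    bad("OpenEvent.monotone_timestamps", ti, si, f"timestamp {o.timestamp} not increasing")
                prev_t = o.timestamp
            if si - 1 < n and search.opens and search.opens[-1].outcome == TARGET_FOUND:
                expected = trial.spec.target_order[si - 1]
                if search.opens[-1].box_index != expected:
                    bad("TrialRecord.target_order_consistency", ti, si, f"found box {search.opens[-1].box_index}, expected {expected}")
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise ParseError(f"missing required field '{key}' in {where}")
    return obj[key]


def session_to_dict(record: SessionRecord) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "participant_id": record.spec.participant_id,
        "seed": record.spec.seed,
        "metadata": record.metadata,
        "trials": [
            {
                "set_size": t.spec.set_size,
                "trial_index": t.spec.trial_index,
                "is_practice": t.spec.is_practice,
                "positions": [list(p) for p in t.spec.layout.positions],
                "target_order": list(t.spec.target_order),
                "searches": [
                    {
                        "search_index": s.search_index,
                        "opens": [{"box": o.box_index, "t": o.timestamp, "outcome": o.outcome} for o in s.opens],
                    }
                    for s in t.searches
                ],
            }
            for t in record.trials
        ],
    }


def session_from_dict(doc: dict) -> SessionRecord:
    version = _require(doc, "schema_version", "session document")
    if version != SCHEMA_VERSION:
        raise ParseError(f"schema_version {version} unsupported (expected {SCHEMA_VERSION})")
    pid = _require(doc, "participant_id", "session document")
    seed = _require(doc, "seed", "session document")
    trials: list[TrialRecord] = []
    specs: list[TrialSpec] = []
    for i, tdoc in enumerate(_require(doc, "trials", "session document")):
        where = f"trial {i + 1}"
        layout = BoxLayout(
            set_size=int(_require(tdoc, "set_size", where)),
            positions=tuple(tuple(p) for p in _require(tdoc, "positions", where)),
        )
        spec = TrialSpec(
            layout=layout,
            target_order=tuple(int(x) for x in _require(tdoc, "target_order", where)),
            trial_index=int(_require(tdoc, "trial_index", where)),
            is_practice=bool(_require(tdoc, "is_practice", where)),
        )
        searches = tuple(
            SearchRecord(
                search_index=int(_require(sdoc, "search_index", f"{where} search {j + 1}")),
                opens=tuple(
                    OpenEvent(
                        box_index=int(_require(odoc, "box", f"{where} open")),
                        timestamp=float(_require(odoc, "t", f"{where} open")),
                        outcome=str(_require(odoc, "outcome", f"{where} open")),
                    )
                    for odoc in _require(sdoc, "opens", f"{where} search {j + 1}")
                ),
            )
            for j, sdoc in enumerate(_require(tdoc, "searches", where))
        )
        specs.append(spec)
        trials.append(TrialRecord(spec=spec, searches=searches))
    session_spec = SessionSpec(participant_id=str(pid), trials=tuple(specs), seed=int(seed))
    return SessionRecord(spec=session_spec, trials=tuple(trials), metadata=doc.get("metadata", {}))


def write_session(record: SessionRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(session_to_dict(record), indent=1) + "\n")
    return path


def read_session(path: str | Path) -> SessionRecord:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top-level document must be an object")
    return session_from_dict(doc)


def events_table(records: SessionRecord | Iterable[SessionRecord]) -> pd.DataFrame:
    """Flat event table: one row per OpenEvent across the given sessions."""
    if isinstance(records, SessionRecord):
        records = [records]
    rows = []
    for rec in records:
        for trial in rec.trials:
            for search in trial.searches:
                for oi, o in enumerate(search.opens, start=1):
                    rows.append(
                        {
                            "participant_id": rec.spec.participant_id,
                            "trial_index": trial.spec.trial_index,
                            "set_size": trial.spec.set_size,
                            "is_practice": trial.spec.is_practice,
                            "search_index": search.search_index,
                            "open_index": oi,
                            "box": o.box_index,
                            "t_seconds": o.timestamp,
                            "outcome": o.outcome,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_index",
            "set_size",
            "is_practice",
            "search_index",
            "open_index",
            "box",
            "t_seconds",
            "outcome",
        ],
    )


def replay_trial(record: TrialRecord) -> TrialRecord:
    """Re-drive the state machine with the logged opens; the engine is its own
    validator — the replay must reproduce the identical record."""
    state = TrialState(record.spec)
    for o in record.all_opens():
        open_box(state, o.box_index, o.timestamp)
    return state.to_record()
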