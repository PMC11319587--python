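"""Shared fixtures: hand-built trial records and small simulated cohorts.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from boxtask.task_core import (
    BoxLayout,
    OpenEvent,
    SearchRecord,
    SessionRecord,
    SessionSpec,
    TrialRecord,
    TrialSpec,
    TrialState,
    build_session_spec,
    open_box,
    EMPTY,
    TARGET_FOUND,
)


def _grid_positions(n: int) -> tuple[tuple[float, float], ...]:
    return tuple((20.0 * (i % 4) + 10.0, 25.0 * (i // 4) + 10.0) for i in range(n))


def make_trial(target_order, search_paths, trial_index=3) -> TrialRecord:
    """Build a TrialRecord from explicit search paths.

    ``search_paths[k]`` is the full open sequence of search k+1 and must end
    on ``target_order[k]``.  Timestamps are 1, 2, 3, ... seconds.
    """
    n = len(target_order)
    layout = BoxLayout(set_size=n, positions=_grid_positions(n))
    spec = TrialSpec(layout=layout, target_order=tuple(target_order), trial_index=trial_index)
    t = 0.0
    searches = []
    for k, path in enumerate(search_paths, start=1):
        assert path[-1] == target_order[k - 1], "path must end on the search's target"
        opens = []
        for box in path:
            t += 1.0
            opens.append(OpenEvent(box_index=box, timestamp=t, outcome=EMPTY))
        opens[-1] = OpenEvent(box_index=path[-1], timestamp=opens[-1].timestamp, outcome=TARGET_FOUND)
        searches.append(SearchRecord(search_index=k, opens=tuple(opens)))
    return TrialRecord(spec=spec, searches=tuple(searches))


def drive_trial(target_order, open_sequence, trial_index=3) -> TrialRecord:
    """Run the open sequence through the live state machine."""
    n = len(target_order)
    layout = BoxLayout(set_size=n, positions=_grid_positions(n))
    spec = TrialSpec(layout=layout, target_order=tuple(target_order), trial_index=trial_index)
    state = TrialState(spec)
    for t, box in enumerate(open_sequence, start=1):
        open_box(state, box, float(t))
    return state.to_record()


@pytest.fixture(scope="session")
def session_spec():
    return build_session_spec(seed=0, participant_id="p0")


@pytest.fixture(scope="session")
def perfect_session(session_spec):
    """A session in which every search goes straight to its target."""
    trials = []
    for tspec in session_spec.trials:
        state = TrialState(tspec)
        t = 0.0
        for target in tspec.target_order:
            t += 1.0
            open_box(state, target, t)
        trials.append(state.to_record())
    return SessionRecord(spec=session_spec, trials=tuple(trials), metadata={})


@pytest.fixture(scope="session")
def small_cohort():
    """8 participants per group, seed 7 — enough for structural checks."""
    from boxtask import simulate

    cohort = simulate.CohortSpec(
        n_per_group={g: 8 for g in simulate.GROUPS}, seed=7, presets=simulate.default_presets()
    )
    return simulate.simulate_cohort(cohort)
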