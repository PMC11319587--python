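"""Synthetic cohorts: parametric cognitive agents producing Box Task session
logs, plus a coupled neuropsychological-covariate generator.

No patient-level Box Task data are publicly deposited, so the package ships
a generative stand-in.  Each simulated participant is an agent with two
memory stores that decay geometrically per intervening open:

* ``rho_between`` — per-open retention of "this box already held a found
  target": a past-target box found ``d`` opens ago is remembered (and
  avoided) with probability ``rho_between ** d``;
* ``rho_within`` — per-open retention of "I opened this box earlier in the
  current search", retained with probability ``rho_within ** d``.

At each choice the agent excludes every remembered box, then follows a fixed
canonical scan order (lowest box index first) with probability
``sigma_scan``, else picks uniformly among the believed-eligible boxes.  If
everything is believed excluded, the belief resets to all boxes except the
one just opened.  Per-open latencies are log-normal.

A single latent severity scalar per participant (mean 0, SD
``severity_sd``) degrades both memory parameters (logistic shift) and the
neuropsychological covariates (linear loadings), inducing the group-specific
covariate--error couplings: in the shipped presets visuospatial episodic
memory (RCF 3-min recall) carries the dominant loading in AD but a ~zero
loading in bvFTD, while attention (Trails A) loads in both patient groups.

Shipped presets (``presets.yaml``) are calibrated so simulated cohorts at
the study sample sizes (28 AD / 28 bvFTD / 32 controls) reproduce the
published group means of between-search errors, completion times and
ACE-III totals; the calibration grid search lives in
``scripts/calibrate_presets.py``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .task_core import (
    DomainError,
    OpenEvent,
    SearchRecord,
    SessionRecord,
    SessionSpec,
    TrialRecord,
    TrialSpec,
    build_session_spec,
    EMPTY,
    TARGET_FOUND,
)

GROUPS = ("control", "bvFTD", "AD")

#: covariate name -> (instrument minimum, instrument maximum)
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "ace_total": (0.0, 100.0),
    "ace_visuospatial": (0.0, 16.0),
    "rcf_copy": (0.0, 36.0),
    "rcf_copy_time": (10.0, 1200.0),
    "rcf_recall": (0.0, 36.0),
    "spatial_span_forward": (0.0, 16.0),
    "spatial_span_backward": (0.0, 16.0),
    "trails_a_time": (5.0, 600.0),
    "trails_b_time": (10.0, 1200.0),
}

COVARIATE_NAMES = tuple(COVARIATE_RANGES)

#: covariates reported as integer scores by their instruments
_INTEGER_COVARIATES = frozenset(
    {"ace_total", "ace_visuospatial", "rcf_recall", "spatial_span_forward", "spatial_span_backward"}
)


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one simulated participant."""

    rho_between: float  # per-open retention of past-target locations, (0, 1]
    rho_within: float  # per-open retention of same-search opens, (0, 1]
    sigma_scan: float  # probability of following the canonical scan order, [0, 1]
    latency_mu: float  # log-scale mean of per-open latency (log seconds)
    latency_sd: float  # log-scale SD of per-open latency

    def __post_init__(self) -> None:
        if not (0.0 < self.rho_between <= 1.0 and 0.0 < self.rho_within <= 1.0):
            raise DomainError("retention probabilities must be in (0, 1]")
        if not (0.0 <= self.sigma_scan <= 1.0):
            raise DomainError("sigma_scan must be in [0, 1]")
        if self.latency_sd < 0:
            raise DomainError("latency_sd must be >= 0")


@dataclass(frozen=True)
class CovariateModel:
    """Per-test marginal mean/SD plus loading on the latent severity scalar.

    A covariate is drawn as ``mean + loading * z + noise`` with
    ``z ~ N(0, 1)`` the standardized severity and noise variance
    ``sd**2 - loading**2`` (so the marginal SD matches the target), then
    truncated to the instrument range.
    """

    means: dict[str, float]
    sds: dict[str, float]
    loadings: dict[str, float]

    def __post_init__(self) -> None:
        for name in COVARIATE_NAMES:
            if name not in self.means or name not in self.sds:
                raise DomainError(f"covariate model missing entry for '{name}'")
            if self.sds[name] < 0:
                raise DomainError(f"SD for '{name}' must be >= 0")
            if abs(self.loadings.get(name, 0.0)) > self.sds[name]:
                raise DomainError(f"|loading| for '{name}' exceeds its SD")


@dataclass(frozen=True)
class GroupPreset:
    group: str
    agent: AgentParams
    severity_sd: float  # logit-scale shift of the retention parameters per unit z
    covariate_model: CovariateModel

    def __post_init__(self) -> None:
        if self.severity_sd < 0:
            raise DomainError("severity_sd must be >= 0")


@dataclass(frozen=True)
class NeuropsychProfile:
    participant_id: str
    group: str
    values: dict[str, float]

    @property
    def trails_b_minus_a(self) -> float:
        return self.values["trails_b_time"] - self.values["trails_a_time"]


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: Mapping[str, int]
    seed: int
    presets: Mapping[str, GroupPreset]

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise DomainError(f"n for group '{g}' must be >= 1")
            if g not in self.presets:
                raise DomainError(f"no preset for group '{g}'")


# ---------------------------------------------------------------------------
# agent behaviour
# ---------------------------------------------------------------------------


def agent_for_severity(base: AgentParams, severity: float) -> AgentParams:
    """Degrade the memory parameters by ``severity`` on the logit scale.

    Positive severity = worse memory.  Scan tendency and latency are left at
    the group level (no speed--accuracy coupling)."""
    if severity == 0.0:
        return base

    def shift(rho: float) -> float:
        if rho >= 1.0:
            return 1.0
        return float(np.clip(expit(logit(rho) - severity), 1e-4, 1.0))

    return AgentParams(
        rho_between=shift(base.rho_between),
        rho_within=shift(base.rho_within),
        sigma_scan=base.sigma_scan,
        latency_mu=base.latency_mu,
        latency_sd=base.latency_sd,
    )


def simulate_trial(agent: AgentParams, spec: TrialSpec, rng: np.random.Generator) -> TrialRecord:
    """Play one trial.  See the module docstring for the choice mechanism."""
    n = spec.set_size
    boxes = np.arange(n)
    open_counter = 0  # ordinal of opens within the trial
    t = 0.0
    searches: list[SearchRecord] = []
    found: list[tuple[int, int]] = []  # (box, open ordinal when found)
    last_opened = -1

    for k in range(1, n + 1):
        target = spec.target_order[k - 1]
        opens: list[OpenEvent] = []
        cur_opens: list[tuple[int, int]] = []  # (box, ordinal) this search
        while True:
            open_counter += 1
            excluded = set()
            for box, m in found:
                d = open_counter - m
                if rng.random() < agent.rho_between**d:
                    excluded.add(box)
            for box, m in cur_opens:
                d = open_counter - m
                if rng.random() < agent.rho_within**d:
                    excluded.add(box)
            eligible = [b for b in range(n) if b not in excluded]
            if not eligible:
                eligible = [b for b in range(n) if b != last_opened] or list(range(n))
            if rng.random() < agent.sigma_scan:
                choice = eligible[0]  # canonical scan order: lowest index first
            else:
                choice = int(eligible[int(rng.integers(len(eligible)))])
            t += float(rng.lognormal(agent.latency_mu, agent.latency_sd))
            hit = choice == target
            opens.append(OpenEvent(box_index=choice, timestamp=t, outcome=TARGET_FOUND if hit else EMPTY))
            last_opened = choice
            if hit:
                found.append((choice, open_counter))
                break
            cur_opens.append((choice, open_counter))
        searches.append(SearchRecord(search_index=k, opens=tuple(opens)))
    return TrialRecord(spec=spec, searches=tuple(searches))


def simulate_session(agent: AgentParams, spec: SessionSpec, rng: np.random.Generator) -> SessionRecord:
    trials = tuple(simulate_trial(agent, tspec, rng) for tspec in spec.trials)
    metadata = {"agent": asdict(agent), "seed": spec.seed}
    return SessionRecord(spec=spec, trials=trials, metadata=metadata)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def draw_covariates(
    preset: GroupPreset,
    severity: float,
    rng: np.random.Generator,
    participant_id: str = "sim",
) -> NeuropsychProfile:
    """Draw one neuropsychological profile given the standardized severity
    ``z`` (the same scalar that degrades the agent's memory)."""
    model = preset.covariate_model
    values: dict[str, float] = {}
    for name in COVARIATE_NAMES:
        mean, sd = model.means[name], model.sds[name]
        loading = model.loadings.get(name, 0.0)
        resid_sd = float(np.sqrt(max(sd**2 - loading**2, 1e-6)))
        raw = mean + loading * severity + rng.normal(0.0, resid_sd)
        lo, hi = COVARIATE_RANGES[name]
        val = float(np.clip(raw, lo, hi))
        if name in _INTEGER_COVARIATES:
            val = float(np.round(val))
        values[name] = val
    return NeuropsychProfile(participant_id=participant_id, group=preset.group, values=values)


def profiles_table(profiles: Iterable[NeuropsychProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"participant_id": p.participant_id, "group": p.group}
        row.update(p.values)
        row["trails_b_minus_a"] = p.trails_b_minus_a
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def simulate_participant(
    preset: GroupPreset, participant_id: str, rng: np.random.Generator
) -> tuple[SessionRecord, NeuropsychProfile]:
    """One participant: latent severity -> degraded agent + coupled covariates."""
    z = float(rng.normal(0.0, 1.0))
    agent = agent_for_severity(preset.agent, preset.severity_sd * z)
    profile = draw_covariates(preset, z, rng, participant_id=participant_id)
    session_seed = int(rng.integers(2**31 - 1))
    spec = build_session_spec(seed=session_seed, participant_id=participant_id)
    session = simulate_session(agent, spec, rng)
    session.metadata.update(
        {
            "group": preset.group,
            "severity_z": z,
            "base_agent": asdict(preset.agent),
            "session_seed": session_seed,
        }
    )
    return session, profile


def simulate_cohort(cohort: CohortSpec) -> tuple[list[SessionRecord], pd.DataFrame]:
    """Simulate every participant of the cohort; deterministic under
    ``cohort.seed`` (each participant draws from an independently spawned
    stream, so group order and sizes do not perturb one another)."""
    root = np.random.SeedSequence(cohort.seed)
    sessions: list[SessionRecord] = []
    profiles: list[NeuropsychProfile] = []
    groups = [g for g in GROUPS if g in cohort.n_per_group]
    groups += [g for g in cohort.n_per_group if g not in GROUPS]
    streams = {g: root.spawn(1)[0] for g in groups}
    for g in groups:
        preset = cohort.presets[g]
        substreams = streams[g].spawn(cohort.n_per_group[g])
        for i, ss in enumerate(substreams, start=1):
            pid = f"{g}_{i:03d}"
            session, profile = simulate_participant(preset, pid, np.random.default_rng(ss))
            sessions.append(session)
            profiles.append(profile)
    return sessions, profiles_table(profiles)


# ---------------------------------------------------------------------------
# presets: shipped calibrated values + YAML round-trip
# ---------------------------------------------------------------------------


def _preset_to_dict(p: GroupPreset) -> dict:
    return {
        "group": p.group,
        "agent": asdict(p.agent),
        "severity_sd": p.severity_sd,
        "covariate_model": {
            "means": dict(p.covariate_model.means),
            "sds": dict(p.covariate_model.sds),
            "loadings": dict(p.covariate_model.loadings),
        },
    }


def _preset_from_dict(doc: dict) -> GroupPreset:
    return GroupPreset(
        group=doc["group"],
        agent=AgentParams(**doc["agent"]),
        severity_sd=float(doc["severity_sd"]),
        covariate_model=CovariateModel(
            means={k: float(v) for k, v in doc["covariate_model"]["means"].items()},
            sds={k: float(v) for k, v in doc["covariate_model"]["sds"].items()},
            loadings={k: float(v) for k, v in doc["covariate_model"]["loadings"].items()},
        ),
    )


def save_presets(presets: Mapping[str, GroupPreset], path: str | Path) -> Path:
    path = Path(path)
    doc = {g: _preset_to_dict(p) for g, p in presets.items()}
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_presets(path: str | Path) -> dict[str, GroupPreset]:
    doc = yaml.safe_load(Path(path).read_text())
    return {g: _preset_from_dict(d) for g, d in doc.items()}


def default_presets() -> dict[str, GroupPreset]:
    """The shipped calibrated presets (see ``presets.yaml`` in the package)."""
    with resources.files("boxtask").joinpath("presets.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return {g: _preset_from_dict(d) for g, d in doc.items()}


def default_cohort_spec(seed: int = 42, n_per_group: Mapping[str, int] | None = None) -> CohortSpec:
    """Study-sized cohort: 28 AD, 28 bvFTD, 32 controls, seed 42."""
    return CohortSpec(
        n_per_group=dict(n_per_group) if n_per_group else {"control": 32, "bvFTD": 28, "AD": 28},
        seed=seed,
        presets=default_presets(),
    )
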