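"""End-to-end orchestration: simulate -> score -> classify -> analyze -> report.

Every run is fully determined by its :class:`RunConfig` (cohort sizes, seed,
preset file, analysis toggles); outputs are plain CSV/JSON files plus a
``run_metadata.json`` sidecar recording the tool version, seed and a hash of
the resolved configuration, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, scoring, simulate, stats, task_core
from .classify import ChaidParams, classify_table, evaluate_classifier, fit_chaid, predict_tree, roc_auc
from .simulate import CohortSpec, default_presets, load_presets
from .task_core import DomainError

log = logging.getLogger("boxtask")

#: Box Task aggregate measures entered into the AUC comparison and whether a
#: larger value indicates AD (errors and times: yes; cognitive scores: no)
AUC_MEASURES = {
    "between_mean_4": True,
    "between_mean_6": True,
    "between_mean_8": True,
    "within_mean_4": True,
    "within_mean_6": True,
    "within_mean_8": True,
    "time_mean_4": True,
    "time_mean_6": True,
    "time_mean_8": True,
    "strategy_mean_4": True,
    "strategy_mean_6": True,
    "strategy_mean_8": True,
    "ace_total": False,
    "ace_visuospatial": False,
    "rcf_copy": False,
    "rcf_copy_time": True,
    "rcf_recall": False,
    "spatial_span_forward": False,
    "spatial_span_backward": False,
    "trails_a_time": True,
    "trails_b_minus_a": True,
}


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 42
    n_per_group: dict = field(default_factory=lambda: {"control": 32, "bvFTD": 28, "AD": 28})
    presets_path: Path | None = None  # None -> shipped calibrated presets
    emulate_missing_4box_t1_time: bool = True
    run_chaid: bool = True
    run_regression: bool = True
    run_contrasts: bool = True
    n_permutations: int = 9999

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["presets_path"] = str(self.presets_path) if self.presets_path else None
        return d

    def config_hash(self) -> str:
        semantic = {k: v for k, v in self.resolved().items() if k != "out_dir"}
        return hashlib.sha256(yaml.safe_dump(semantic, sort_keys=True).encode()).hexdigest()[:16]


def _wide_features(agg: pd.DataFrame, cov: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: per-set-size aggregates as columns plus the
    covariates."""
    wide = agg.pivot_table(
        index=["participant_id", "group"],
        columns="set_size",
        values=["between_mean", "within_mean", "time_mean", "strategy_mean", "between_sum", "within_sum"],
    )
    wide.columns = [f"{m}_{ss}" for m, ss in wide.columns]
    return wide.reset_index().merge(cov.drop(columns="group"), on="participant_id")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns {artefact name: path}.  A stage failure
    aborts with a stage-named error; artefacts already written remain."""
    t_start = time.time()
    out = Path(config.out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    presets = load_presets(config.presets_path) if config.presets_path else default_presets()
    unknown = [g for g in config.n_per_group if g not in presets]
    if unknown:
        raise DomainError(f"stage simulate: unknown preset name(s) {unknown}")

    def stage(name):
        log.info("stage %-10s +%.1fs", name, time.time() - t_start)

    # --- simulate -----------------------------------------------------------
    stage("simulate")
    cohort = CohortSpec(n_per_group=config.n_per_group, seed=config.seed, presets=presets)
    sessions, covariates = simulate.simulate_cohort(cohort)
    for rec in sessions:
        task_core.write_session(rec, out / "sessions" / f"{rec.spec.participant_id}.json")
    covariates = covariates.sort_values("participant_id").reset_index(drop=True)
    paths["covariates"] = out / "covariates.csv"
    covariates.to_csv(paths["covariates"], index=False)

    # --- score --------------------------------------------------------------
    stage("score")
    per_trial = scoring.score_table(sessions)
    agg = scoring.aggregate_table(sessions, emulate_missing_4box_t1_time=config.emulate_missing_4box_t1_time)
    paths["scores_per_trial"] = out / "scores_per_trial.csv"
    paths["scores_aggregate"] = out / "scores_aggregate.csv"
    per_trial.to_csv(paths["scores_per_trial"], index=False)
    agg.to_csv(paths["scores_aggregate"], index=False)

    # --- classify -----------------------------------------------------------
    stage("classify")
    wide = _wide_features(agg, covariates)
    patients = wide[wide["group"].isin(["AD", "bvFTD"])].reset_index(drop=True)
    tree_inputs = patients.rename(
        columns={"within_sum_6": "ws6_sum", "between_sum_4": "bs4_sum"}
    )[["participant_id", "group", "ace_total", "ws6_sum", "bs4_sum"]]
    tree_inputs["predicted"] = classify_table(tree_inputs)
    paths["classification_fixed"] = out / "classification_fixed.csv"
    tree_inputs.to_csv(paths["classification_fixed"], index=False)
    evaluation = evaluate_classifier(tree_inputs["predicted"], tree_inputs["group"])

    chaid_render = None
    if config.run_chaid:
        chaid_features = patients[
            ["ace_total", "between_sum_4", "between_sum_6", "between_sum_8",
             "within_sum_4", "within_sum_6", "within_sum_8"]
        ]
        # node-size floor scaled down for miniature cohorts
        min_node = max(2, min(10, len(patients) // 4))
        tree = fit_chaid(
            chaid_features, patients["group"], ChaidParams(forced_first="ace_total", min_node_size=min_node)
        )
        paths["chaid_tree"] = out / "chaid_tree.json"
        paths["chaid_tree"].write_text(json.dumps(tree.to_dict(), indent=1))
        chaid_render = tree.render()
        (out / "chaid_tree.txt").write_text(chaid_render + "\n")
        chaid_eval = evaluate_classifier(predict_tree(tree, chaid_features), patients["group"])
    else:
        chaid_eval = None

    # --- AUC ----------------------------------------------------------------
    stage("auc")
    rows = []
    for measure, larger_is_ad in AUC_MEASURES.items():
        if measure not in patients.columns:
            continue
        res = roc_auc(patients[measure], patients["group"], larger_indicates_positive=larger_is_ad)
        rows.append({"measure": measure, "auc": res.auc, "larger_indicates_AD": larger_is_ad})
    auc_table = pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    paths["auc_table"] = out / "auc_table.csv"
    auc_table.to_csv(paths["auc_table"], index=False)

    # --- analyze ------------------------------------------------------------
    if config.run_regression:
        stage("regression")
        reg_results, verdict = stats.regression_dissociation_check(agg, covariates)
        for group, res in reg_results.items():
            paths[f"regression_{group}"] = out / f"regression_{group}.csv"
            stats.regression_table(res).to_csv(paths[f"regression_{group}"], index=False)
    else:
        reg_results, verdict = {}, None

    if config.run_contrasts:
        stage("contrasts")
        contrasts = stats.group_setsize_contrasts(
            agg, n_permutations=config.n_permutations, seed=config.seed
        )
        paths["contrasts"] = out / "contrasts.csv"
        stats.contrasts_table(contrasts).to_csv(paths["contrasts"], index=False)
    else:
        contrasts = []

    # --- report -------------------------------------------------------------
    stage("report")
    lines = [
        f"boxtask {__version__} pipeline report",
        f"seed {config.seed}, cohort {dict(config.n_per_group)}",
        "",
        "Group means (mean of two trials) by set size:",
        agg.groupby(["group", "set_size"])[["between_mean", "within_mean", "time_mean", "strategy_mean"]]
        .mean()
        .round(2)
        .to_string(),
        "",
        f"Fixed-tree classification of patients: overall {evaluation.overall_percent_correct:.1f}% correct, "
        f"risk {evaluation.risk_estimate:.3f} (SE {evaluation.risk_se:.3f})",
    ]
    if chaid_eval is not None:
        lines += [
            f"CHAID (refit) classification: overall {chaid_eval.overall_percent_correct:.1f}% correct",
            chaid_render or "",
        ]
    if reg_results:
        lines += ["", f"Regression dissociation verdict (RCF recall significant in AD only): {verdict}"]
    lines += ["", "Top AUC measures (AD vs bvFTD):", auc_table.head(5).to_string(index=False)]
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")

    meta = {
        "tool_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.resolved(),
        "artefacts": {k: str(v) for k, v in paths.items()},
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    paths["run_metadata"] = out / "run_metadata.json"
    stage("done")
    return paths


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int, out_dir: Path) -> dict[str, list[Path]]:
    """Miniature cohort (3 per group) plus deliberately defective session
    logs for exercising the validator; regenerated on demand, never
    committed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = CohortSpec(
        n_per_group={g: 3 for g in simulate.GROUPS}, seed=seed, presets=default_presets()
    )
    sessions, covariates = simulate.simulate_cohort(cohort)
    session_paths = []
    for rec in sessions:
        session_paths.append(task_core.write_session(rec, out / f"{rec.spec.participant_id}.json"))
    covariates.to_csv(out / "covariates.csv", index=False)

    # defect 1: search lacking its terminal target_found open
    doc = task_core.session_to_dict(sessions[0])
    doc["trials"][2]["searches"][1]["opens"][-1]["outcome"] = "empty"
    p1 = out / "defect_missing_target.json"
    p1.write_text(json.dumps(doc))

    # defect 2: non-monotone timestamps
    doc = task_core.session_to_dict(sessions[1])
    opens = doc["trials"][3]["searches"][0]["opens"]
    opens.insert(1, {"box": opens[0]["box"], "t": opens[0]["t"] - 0.5, "outcome": "empty"})
    p2 = out / "defect_bad_timestamps.json"
    p2.write_text(json.dumps(doc))

    return {"sessions": session_paths, "defects": [p1, p2]}
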