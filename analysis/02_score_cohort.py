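"""Score the simulated cohort: between-/within-search errors, completion
time and the normalized-Levenshtein strategy score, per trial and per set
size.

Reads results/cohort/sessions (run 01 first), writes the tidy per-trial and
per-participant aggregate tables under results/, and prints the group means
next to the published group-mean anchors.
"""

from pathlib import Path

from boxtask import scoring, task_core

IN = Path("results/cohort/sessions")
OUT = Path("results")

PUBLISHED_BETWEEN = {("AD", 4): 2.02, ("AD", 6): 6.29, ("AD", 8): 11.71,
                     ("bvFTD", 4): 0.97, ("bvFTD", 6): 3.89, ("bvFTD", 8): 9.81,
                     ("control", 4): 0.29, ("control", 6): 1.18, ("control", 8): 3.55}


def main() -> None:
    sessions = [task_core.read_session(p) for p in sorted(IN.glob("*.json"))]
    if not sessions:
        raise SystemExit("no sessions found; run analysis/01_simulate_cohort.py first")
    per_trial = scoring.score_table(sessions)
    agg = scoring.aggregate_table(sessions, emulate_missing_4box_t1_time=True)
    per_trial.to_csv(OUT / "scores_per_trial.csv", index=False)
    agg.to_csv(OUT / "scores_aggregate.csv", index=False)

    means = agg.groupby(["group", "set_size"])[["between_mean", "within_mean", "time_mean", "strategy_mean"]].mean()
    means["between_published"] = [PUBLISHED_BETWEEN[(g, s)] for g, s in means.index]
    print(means.round(2))
    print(f"\nwrote scores_per_trial.csv and scores_aggregate.csv to {OUT}/")


if __name__ == "__main__":
    main()
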