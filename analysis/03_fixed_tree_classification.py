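"""Apply the published fixed decision tree (ACE-III root at 70; 6-box
within-search errors >= 1 on the high branch; 4-box between-search errors
>= 2 on the low branch) to the simulated patients, and verify the printed
arithmetic of the published confusion counts (21/28 AD, 23/28 bvFTD correct
-> 78.6% overall, risk 0.214, SE 0.055).

Run 01 and 02 first.  Writes results/classification_fixed.csv.
"""

from pathlib import Path

import pandas as pd

from boxtask.classify import classify_table, evaluate_classifier

OUT = Path("results")


def main() -> None:
    agg = pd.read_csv(OUT / "scores_aggregate.csv")
    cov = pd.read_csv(OUT / "cohort" / "covariates.csv")
    ws6 = agg[agg.set_size == 6][["participant_id", "within_sum"]].rename(columns={"within_sum": "ws6_sum"})
    bs4 = agg[agg.set_size == 4][["participant_id", "between_sum"]].rename(columns={"between_sum": "bs4_sum"})
    df = cov[cov.group.isin(["AD", "bvFTD"])][["participant_id", "group", "ace_total"]].merge(ws6, on="participant_id").merge(bs4, on="participant_id")
    df["predicted"] = classify_table(df)
    df.to_csv(OUT / "classification_fixed.csv", index=False)

    res = evaluate_classifier(df["predicted"], df["group"])
    print("Fixed tree on the simulated cohort:")
    print(f"  overall {res.overall_percent_correct:.1f}% correct, risk {res.risk_estimate:.3f} (SE {res.risk_se:.3f})")
    print(f"  per class: {({k: round(v, 1) for k, v in res.per_class_percent_correct.items()})}")

    # the published confusion counts, re-evaluated from scratch
    labels = ["AD"] * 28 + ["bvFTD"] * 28
    preds = ["AD"] * 21 + ["bvFTD"] * 7 + ["bvFTD"] * 23 + ["AD"] * 5
    printed = evaluate_classifier(preds, labels)
    print("\nPublished confusion counts (21/28 AD and 23/28 bvFTD correct) imply:")
    print(f"  overall {printed.overall_percent_correct:.1f}% correct, risk {printed.risk_estimate:.3f}, SE {printed.risk_se:.3f}")


if __name__ == "__main__":
    main()
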