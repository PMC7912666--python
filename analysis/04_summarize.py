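"""Summarize the study: how well do reduced calibration sets hold up?

Reads the report from 03_calibrate.py and answers the study's questions:
(i) for each reduced set, how many of the four reference parameters have an
external-validation SEP not significantly different from the full
calibration; (ii) SEP as a percentage of each model's applicability range,
so parameters on different scales are comparable; (iii) whether the NH or
the HC route gives the better count-matched selections.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = pd.read_csv(RESULTS / "report" / "report.csv")
    reduced = report[report["set"] != "FC"]

    summary = (
        reduced.groupby("set")
        .agg(
            n_params_ok=("significant_vs_FC", lambda s: int((~s).sum())),
            mean_sep_percent=("SEP_percent", "mean"),
            N=("N", "first"),
        )
        .reset_index()
        .sort_values("N")
    )
    fc_sep = report[report["set"] == "FC"].set_index("parameter")["SEP_percent"]
    summary["fc_mean_sep_percent"] = fc_sep.mean()

    print("Per reduced set: parameters with SEP not significantly different from FC (of 4)")
    print(summary.to_string(index=False))

    count_sets = reduced[reduced["set"].str.fullmatch(r"(NH|HC)-\d+")]
    if not count_sets.empty:
        head = (
            count_sets.assign(method=count_sets["set"].str.split("-").str[0])
            .groupby("method")[["SEP_percent"]]
            .mean()
            .round(2)
        )
        print("\nCount-matched comparison (mean SEP% by method):")
        print(head.to_string())
        wins = 0
        for (t, p), grp in count_sets.assign(
            target=count_sets["set"].str.split("-").str[1]
        ).groupby(["target", "parameter"]):
            by_m = grp.set_index("set")["SEP"]
            if len(by_m) == 2 and by_m.filter(like="HC").iloc[0] < by_m.filter(like="NH").iloc[0]:
                wins += 1
        print(f"HC beats NH on {wins} of {count_sets['set'].nunique() * 2} count-matched comparisons")

    ok = (summary["n_params_ok"] >= 3).mean()
    print(
        f"\n{100 * ok:.0f}% of reduced sets keep at least 3 of 4 parameters "
        "statistically indistinguishable from the full calibration"
    )
    out = RESULTS / "report" / "summary.csv"
    summary.to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
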