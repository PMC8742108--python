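"""Group-difference and covariate-association statistics on the cohort.

Kruskal-Wallis across the four groups with median (range) summaries for
every marker, and Welch-t / ANOVA associations of the methylation markers
with stage, grade, nodal status and metastasis in the case groups.
"""

import argparse
from pathlib import Path

import pandas as pd

from panelforge.cohort import MU_MARKER_NAMES
from panelforge.io import COVARIATE_COLUMNS, REQUIRED_COLUMNS, read_cohort
from panelforge.stats import covariate_association, marker_group_stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_cohort(args.cohort)
    markers = [
        c for c in table.columns
        if c not in REQUIRED_COLUMNS and c not in COVARIATE_COLUMNS
    ]
    stats = marker_group_stats(table, markers)
    stats.to_csv(args.out / "group_stats.csv")
    print("Kruskal-Wallis across the four groups (top rows):")
    print(stats[["H", "p"]].head(8).round(4).to_string())

    cases = table[table["group"].isin(["DCIS", "invasive"])]
    # stage collapsed to early vs advanced, as in a two-level comparison
    cases = cases.assign(
        stage_group=cases["stage"].map(
            lambda s: "0-II" if s in ("0", "I", "II") else "III-IV"
        )
    )
    rows = []
    for marker in MU_MARKER_NAMES:
        for covariate in ("stage_group", "grade", "nodal", "metastasis"):
            res = covariate_association(cases, marker, covariate)
            rows.append(
                {
                    "marker": marker,
                    "covariate": covariate,
                    "test": res.statistic_name,
                    "statistic": res.statistic,
                    "p": res.p_value,
                }
            )
    assoc = pd.DataFrame(rows)
    assoc.to_csv(args.out / "covariate_associations.csv", index=False)
    print("\nmethylation vs clinicopathological covariates:")
    print(assoc.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
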