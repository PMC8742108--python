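"""Protein-marker diagnostics: fixed-specificity singles and the MAD panel.

For each of the six candidate plasma proteins, fixes specificity at 70%
on the training controls and reports the achieved sensitivity and AUC
(the single-marker regime, where AUCs sit near 0.5-0.65).  The OR-rule
Median + 1 MAD panel is built over the up-regulated candidates - an
any-positive fusion only makes sense when every rule is specific on its
own, and a median + MAD threshold with a positive-below direction calls
the majority of controls positive.  The six-marker combination is then
assessed on the multivariate path: a logistic model on all six proteins
with its combined ROC, frozen on the training set.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from panelforge.cohort import (
    PROTEIN_PANEL_CANDIDATES,
    default_study_markers,
    is_case,
    split_train_test,
)
from panelforge.diagnostics import empirical_roc, evaluate_split, logistic_combined_roc
from panelforge.io import read_cohort
from panelforge.panel import PanelBuildSpec, cutoff_at_fixed_specificity


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_cohort(args.cohort)
    train, test = split_train_test(table, 0.7, seed=args.seed)
    directions = {
        m.name: ("positive_above" if m.direction == "up_in_cases" else "positive_below")
        for m in default_study_markers()
    }

    case_mask = is_case(train["group"].to_numpy())
    rows = []
    for m in PROTEIN_PANEL_CANDIDATES:
        v = train[m].to_numpy()
        res = cutoff_at_fixed_specificity(
            v[case_mask], v[~case_mask], 0.7, directions[m], m
        )
        roc = empirical_roc(v, case_mask, directions[m])
        rows.append(
            {
                "marker": m,
                "cutoff": res.rule.threshold,
                "specificity": res.specificity,
                "sensitivity": res.sensitivity,
                "auc": roc.auc,
            }
        )
    singles = pd.DataFrame(rows)
    singles.to_csv(args.out / "protein_singles.csv", index=False)
    print("single proteins at 70% training specificity:")
    print(singles.round(3).to_string(index=False))

    up_candidates = tuple(
        m for m in PROTEIN_PANEL_CANDIDATES if directions[m] == "positive_above"
    )
    spec = PanelBuildSpec(
        markers=up_candidates,
        rule="median_plus_k_mad",
        k=1.0,
        directions=directions,
        select=True,
    )
    result = evaluate_split(train, test, spec, combined_roc=False)
    print(f"\nMAD OR-panel over up-regulated candidates kept: "
          f"{', '.join(result.panel.markers)}")
    print("train:", result.train_summary.display_row())
    print("test :", result.test_summary.display_row())

    combined = logistic_combined_roc(train, PROTEIN_PANEL_CANDIDATES)
    beta = combined.coefficients.to_numpy()
    X_test = test[list(PROTEIN_PANEL_CANDIDATES)].to_numpy()
    probs = 1.0 / (1.0 + np.exp(-(beta[0] + X_test @ beta[1:])))
    test_auc = empirical_roc(probs, is_case(test["group"].to_numpy())).auc
    report = {
        "mad_panel": result.panel.to_dict(),
        "mad_train": result.train_summary.to_dict(),
        "mad_test": result.test_summary.to_dict(),
        "logistic_markers": list(PROTEIN_PANEL_CANDIDATES),
        "logistic_train_auc": combined.roc.auc,
        "logistic_test_auc": test_auc,
    }
    (args.out / "protein_panel.json").write_text(json.dumps(report, indent=2))
    print(f"six-protein logistic ROC  train AUC {combined.roc.auc:.3f}  "
          f"test AUC {test_auc:.3f}")


if __name__ == "__main__":
    main()
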