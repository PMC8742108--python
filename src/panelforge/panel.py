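"""Cut-off rules, marker calls, methylation scoring and panel selection.

A marker enters a panel through a cut-off rule: a threshold plus a
direction (positive above for markers elevated in disease, positive below
for markers suppressed).  Thresholds come from one of three sources:

* ``median_plus_k_mad`` - median + k * MAD of the values pooled across
  cases and controls (the MAD is unscaled: no 1.4826 consistency factor);
* ``fixed_value`` - an externally chosen constant, e.g. the M/U ratio
  cut-off of 1 for methylation calls;
* ``fixed_specificity`` - the least extreme threshold achieving a target
  specificity on controls.

Calls are strict: a tie at the threshold is negative.  Panels combine
marker calls with an any-positive (OR) rule, so the panel's sensitivity
can only rise above, and its specificity only fall below, the single
markers'.  Panel selection is backward marker elimination maximising
sensitivity (specificity, then panel size, then marker name break ties) -
a marker-removal search, not leave-one-out cross-validation.

The methylation score encodes each call against case/control status:
+1 a true positive (case, M/U above cut-off), 0 a negative call, and -1 a
false positive (control above cut-off).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .cohort import is_case

Direction = Literal["positive_above", "positive_below"]
_SOURCES = ("median_plus_k_mad", "fixed_value", "fixed_specificity")


@dataclass(frozen=True)
class CutoffRule:
    marker: str
    threshold: float
    direction: Direction = "positive_above"
    source: str = "fixed_value"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError(f"{self.marker}: threshold must be finite")
        if self.direction not in ("positive_above", "positive_below"):
            raise ValueError(f"{self.marker}: bad direction {self.direction!r}")
        if self.source not in _SOURCES:
            raise ValueError(f"{self.marker}: bad source {self.source!r}")

    def call(self, values) -> np.ndarray:
        """Binary calls; strict inequality, ties at the threshold are 0."""
        v = np.asarray(values, dtype=float)
        if self.direction == "positive_above":
            return (v > self.threshold).astype(int)
        return (v < self.threshold).astype(int)


@dataclass(frozen=True)
class PanelDefinition:
    rules: tuple[CutoffRule, ...]
    combination: str = "any_positive"
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.rules) == 0:
            raise ValueError("a panel needs >= 1 rule")
        names = [r.marker for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("panel marker names must be unique")
        if self.combination != "any_positive":
            raise ValueError(f"unknown combination rule {self.combination!r}")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(r.marker for r in self.rules)

    def without(self, marker: str) -> "PanelDefinition":
        rules = tuple(r for r in self.rules if r.marker != marker)
        return replace(self, rules=rules)

    def to_dict(self) -> dict:
        return {
            "combination": self.combination,
            "note": self.note,
            "rules": [
                {
                    "marker": r.marker,
                    "threshold": float(r.threshold),
                    "direction": r.direction,
                    "source": r.source,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelDefinition":
        rules = tuple(
            CutoffRule(
                marker=r["marker"],
                threshold=float(r["threshold"]),
                direction=r.get("direction", "positive_above"),
                source=r.get("source", "fixed_value"),
            )
            for r in d["rules"]
        )
        return cls(rules, d.get("combination", "any_positive"), d.get("note", ""))


def mad(values) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("mad requires >= 1 finite value")
    return float(np.median(np.abs(v - np.median(v))))


def direction_for(marker_direction: str) -> Direction:
    """A marker elevated in disease is called positive above its threshold."""
    if marker_direction == "up_in_cases":
        return "positive_above"
    if marker_direction == "down_in_cases":
        return "positive_below"
    raise ValueError(f"unknown marker direction {marker_direction!r}")


def derive_cutoff(
    values_pooled,
    marker: str = "marker",
    k: float = 1.0,
    direction: Direction = "positive_above",
) -> CutoffRule:
    """Median + k * MAD threshold from values pooled across cases and controls."""
    if k < 0:
        raise ValueError("k must be >= 0")
    v = np.asarray(values_pooled, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to derive a cut-off from")
    threshold = float(np.median(v) + k * mad(v))
    return CutoffRule(marker, threshold, direction, "median_plus_k_mad")


@dataclass(frozen=True)
class FixedSpecificityCutoff:
    rule: CutoffRule
    specificity: float
    sensitivity: float


def cutoff_at_fixed_specificity(
    cases,
    controls,
    spec_target: float,
    direction: Direction = "positive_above",
    marker: str = "marker",
) -> FixedSpecificityCutoff:
    """Least extreme threshold achieving specificity >= target on controls.

    For ``positive_above`` the smallest such threshold is returned, for
    ``positive_below`` the largest, together with the achieved
    sensitivity on cases.  If the controls are all identical the
    degenerate extreme is returned with a warning.
    """
    if not 0 < spec_target < 1:
        raise ValueError("spec_target must be in (0, 1)")
    ca = np.asarray(cases, dtype=float)
    co = np.asarray(controls, dtype=float)
    if ca.size == 0 or co.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(co) == 0:
        warnings.warn(
            f"{marker}: all control values identical; degenerate cut-off",
            stacklevel=2,
        )
    candidates = np.unique(co)
    if direction == "positive_above":
        # spec(t) = fraction of controls <= t, increasing in t
        for t in candidates:
            if np.mean(co <= t) >= spec_target:
                threshold = float(t)
                break
    else:
        for t in candidates[::-1]:
            if np.mean(co >= t) >= spec_target:
                threshold = float(t)
                break
    rule = CutoffRule(marker, threshold, direction, "fixed_specificity")
    spec = float(1.0 - rule.call(co).mean())
    sens = float(rule.call(ca).mean())
    return FixedSpecificityCutoff(rule, spec, sens)


def score_methylation(mu_value: float, group: str, cutoff: float = 1.0) -> int:
    """Score an M/U ratio: case above cut-off +1, control above cut-off -1.

    A score of +1 is a true positive, -1 a false positive, 0 in a case a
    false negative and 0 in a control a true negative.  The comparison is
    strictly greater-than, so a value exactly at the cut-off scores 0.
    """
    if not mu_value >= 0:
        raise ValueError("M/U ratio must be >= 0")
    positive = mu_value > cutoff
    if is_case(group):
        return 1 if positive else 0
    return -1 if positive else 0


def call_markers(table: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    """Apply every panel rule to a cohort table.

    Returns a score table with per-marker binary calls (``call_<m>``),
    signed methylation-style scores (``score_<m>``: the call for cases,
    minus the call for controls) and the combined ``panel_call``.
    """
    missing = [r.marker for r in panel.rules if r.marker not in table.columns]
    if missing:
        raise KeyError(f"panel markers absent from table: {missing}")
    out = table[["sample_id", "group"]].copy()
    case_mask = is_case(table["group"].to_numpy())
    sign = np.where(case_mask, 1, -1)
    for rule in panel.rules:
        calls = rule.call(table[rule.marker].to_numpy())
        out[f"call_{rule.marker}"] = calls
        out[f"score_{rule.marker}"] = calls * sign
    out["panel_call"] = combine_panel(out, panel).to_numpy()
    return out


def combine_panel(score_table: pd.DataFrame, panel: PanelDefinition) -> pd.Series:
    """Any-positive fusion: the panel call is the max over marker calls."""
    cols = [f"call_{m}" for m in panel.markers]
    missing = [c for c in cols if c not in score_table.columns]
    if missing:
        raise KeyError(f"score table lacks call columns: {missing}")
    return score_table[cols].max(axis=1).rename("panel_call")


def panel_sensitivity_specificity(
    table: pd.DataFrame, panel: PanelDefinition
) -> tuple[float, float]:
    """(sensitivity, specificity) of the combined panel call on a cohort."""
    scores = call_markers(table, panel)
    case_mask = is_case(scores["group"].to_numpy())
    calls = scores["panel_call"].to_numpy()
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValueError("need both cases and controls")
    sens = float(calls[case_mask].mean())
    spec = float(1.0 - calls[~case_mask].mean())
    return sens, spec


def leave_one_out_selection(
    table: pd.DataFrame, candidate_panel: PanelDefinition
) -> PanelDefinition:
    """Backward marker elimination maximising panel sensitivity.

    At each round the panel is re-evaluated with each single marker
    removed; if some removal keeps sensitivity at least at its current
    value, the best removal is accepted (higher specificity first, then
    the alphabetically first marker name) and the search recurses.  The
    procedure never returns a panel less sensitive than the full
    candidate set, and is deterministic given the table.  This is a
    marker-subset search, not leave-one-out cross-validation.
    """
    panel = candidate_panel
    removed: list[str] = []
    sens, spec = panel_sensitivity_specificity(table, panel)
    while len(panel.rules) > 1:
        best: tuple[float, float, str] | None = None
        for marker in sorted(panel.markers):
            cand_sens, cand_spec = panel_sensitivity_specificity(
                table, panel.without(marker)
            )
            if cand_sens >= sens:
                key = (cand_sens, cand_spec, marker)
                # maximise (sens, spec); on full ties prefer the earliest name
                if best is None or key[:2] > best[:2]:
                    best = key
        if best is None:
            break
        sens, spec, marker = best
        panel = panel.without(marker)
        removed.append(marker)
    note = "backward elimination removed: " + (", ".join(removed) or "none")
    return replace(panel, note=note)


@dataclass(frozen=True)
class PanelBuildSpec:
    """How to turn candidate markers into a frozen panel on a training set."""

    markers: tuple[str, ...]
    rule: str = "median_plus_k_mad"
    k: float = 1.0
    fixed_cutoff: float = 1.0
    spec_target: float = 0.7
    directions: Mapping[str, Direction] | None = None
    select: bool = True  # run backward elimination after building cut-offs

    def direction_of(self, marker: str) -> Direction:
        if self.directions and marker in self.directions:
            return self.directions[marker]
        return "positive_above"


def build_panel(table: pd.DataFrame, spec: PanelBuildSpec) -> PanelDefinition:
    """Derive per-marker cut-offs on a table and optionally prune the panel.

    ``median_plus_k_mad`` pools the values of the whole table (cases and
    controls together); ``fixed_value`` applies one constant threshold to
    every marker; ``fixed_specificity`` anchors each threshold on the
    control samples.
    """
    rules = []
    for m in spec.markers:
        if m not in table.columns:
            raise KeyError(f"marker {m!r} absent from table")
        direction = spec.direction_of(m)
        values = table[m].to_numpy(dtype=float)
        if spec.rule == "median_plus_k_mad":
            rules.append(derive_cutoff(values, m, spec.k, direction))
        elif spec.rule == "fixed_value":
            rules.append(CutoffRule(m, spec.fixed_cutoff, direction, "fixed_value"))
        elif spec.rule == "fixed_specificity":
            case_mask = is_case(table["group"].to_numpy())
            res = cutoff_at_fixed_specificity(
                values[case_mask], values[~case_mask], spec.spec_target, direction, m
            )
            rules.append(res.rule)
        else:
            raise ValueError(f"unknown cut-off rule {spec.rule!r}")
    panel = PanelDefinition(tuple(rules), note=f"built with rule={spec.rule}")
    if spec.select and len(rules) > 1:
        panel = leave_one_out_selection(table, panel)
    return panel
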