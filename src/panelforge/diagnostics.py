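"""Diagnostic evaluation: confusion counts, exact binomial CIs, ROC/AUC.

Sensitivity, specificity and accuracy carry exact Clopper-Pearson 95%
confidence intervals in their beta-quantile form; at x = n the lower
bound reduces to (alpha/2)^(1/n).  ROC curves come from a full threshold
sweep, so the AUC equals the Mann-Whitney concordance probability with
ties counted one half.  The combined ("multivariate") ROC of several
markers uses the predicted probabilities of a binomial logistic
regression fitted by maximum likelihood; complete separation is detected
and flagged, with the AUC still available from the ranking.

Undefined metrics (zero denominators) raise rather than silently report 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import is_case
from .panel import PanelBuildSpec, PanelDefinition, build_panel, call_markers


class Confusion(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


def confusion(score_table: pd.DataFrame, call_col: str = "panel_call") -> Confusion:
    """Exact confusion counts of a binary call column against case status.

    DCIS and invasive samples count as cases, benign and healthy as
    controls.  Raises if either class is empty.
    """
    case_mask = is_case(score_table["group"].to_numpy())
    calls = score_table[call_col].to_numpy().astype(int)
    if case_mask.sum() == 0:
        raise ValueError("no cases in score table")
    if (~case_mask).sum() == 0:
        raise ValueError("no controls in score table")
    tp = int((calls[case_mask] == 1).sum())
    fn = int((calls[case_mask] == 0).sum())
    fp = int((calls[~case_mask] == 1).sum())
    tn = int((calls[~case_mask] == 0).sum())
    return Confusion(tp, fp, tn, fn)


def clopper_pearson_ci(x, n, level: float = 0.95):
    """Exact binomial confidence interval (beta-quantile form).

    lower = Beta(alpha/2; x, n-x+1), upper = Beta(1-alpha/2; x+1, n-x),
    with lower = 0 at x = 0 and upper = 1 at x = n.  Accepts arrays.
    """
    x_arr = np.asarray(x)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    if np.any((x_arr < 0) | (x_arr > n_arr)):
        raise ValueError("x must satisfy 0 <= x <= n")
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        lower = np.where(
            x_arr > 0, sps.beta.ppf(alpha / 2, x_arr, n_arr - x_arr + 1), 0.0
        )
        upper = np.where(
            x_arr < n_arr, sps.beta.ppf(1 - alpha / 2, x_arr + 1, n_arr - x_arr), 1.0
        )
    if np.ndim(x) == 0 and np.ndim(n) == 0:
        return float(lower), float(upper)
    return lower, upper


@dataclass(frozen=True)
class DiagnosticSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    level: float = 0.95

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    def display_row(self) -> dict[str, str]:
        """Point estimates to whole percent, CI bounds to 2 decimals."""

        def fmt(point, ci):
            return f"{round(point * 100):.0f}% ({ci[0] * 100:.2f}-{ci[1] * 100:.2f}%)"

        return {
            "sensitivity": fmt(self.sensitivity, self.sensitivity_ci),
            "specificity": fmt(self.specificity, self.specificity_ci),
            "accuracy": fmt(self.accuracy, self.accuracy_ci),
        }

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "accuracy_ci": list(self.accuracy_ci),
            "level": self.level,
        }


def summarize_diagnostics(counts: Confusion, level: float = 0.95) -> DiagnosticSummary:
    """Sensitivity/specificity/accuracy with exact CIs from confusion counts."""
    tp, fp, tn, fn = counts
    n_cases = tp + fn
    n_controls = tn + fp
    n = n_cases + n_controls
    if n_cases == 0:
        raise ValueError("sensitivity undefined: no cases")
    if n_controls == 0:
        raise ValueError("specificity undefined: no controls")
    return DiagnosticSummary(
        tp,
        fp,
        tn,
        fn,
        sensitivity=tp / n_cases,
        specificity=tn / n_controls,
        accuracy=(tp + tn) / n,
        sensitivity_ci=clopper_pearson_ci(tp, n_cases, level),
        specificity_ci=clopper_pearson_ci(tn, n_controls, level),
        accuracy_ci=clopper_pearson_ci(tp + tn, n, level),
        level=level,
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def empirical_roc(values, labels, direction: str = "positive_above") -> ROCResult:
    """Threshold-sweep ROC of one marker; AUC = tie-adjusted concordance.

    ``labels`` may be booleans (True = case) or group labels, which are
    mapped through the case/control clubbing.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    y = labels if labels.dtype == bool else is_case(labels)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    scores = v if direction == "positive_above" else -v
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    return ROCResult(thr, fpr, tpr, float(roc_auc_score(y, scores)))


@dataclass
class LogisticROC:
    roc: ROCResult
    coefficients: pd.Series
    probabilities: np.ndarray
    separation: bool
    converged: bool


def logistic_combined_roc(
    table: pd.DataFrame, markers: Sequence[str], labels=None
) -> LogisticROC:
    """Combined ROC from logistic-regression predicted probabilities.

    Fits case status on the marker columns by maximum likelihood (Newton /
    IRLS, relative log-likelihood tolerance 1e-8, up to 100 iterations).
    Under complete separation the MLE diverges; the fit falls back to a
    weakly ridged solver for the ranking and the result is flagged, the
    AUC remaining valid because it depends only on the ordering.
    """
    import statsmodels.api as sm

    if len(markers) == 0:
        raise ValueError(">= 1 marker required")
    X = table[list(markers)].to_numpy(dtype=float)
    if labels is None:
        labels = table["group"].to_numpy()
    labels = np.asarray(labels)
    y = labels if labels.dtype == bool else is_case(labels)
    y = y.astype(int)

    converged = False
    params = None
    probs = None
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
        converged = bool(fit.mle_retvals.get("converged", False))
        params = np.asarray(fit.params, dtype=float)
        probs = np.asarray(fit.predict(design), dtype=float)
    except Exception:
        pass

    separation = False
    if probs is not None and np.isfinite(probs).all():
        separation = bool(probs[y == 1].min() > probs[y == 0].max())
    if probs is None or not np.isfinite(probs).all() or (not converged):
        # ridge-stabilised fallback keeps the ranking under separation
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e6, max_iter=2000)
        lr.fit(X, y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        probs = lr.predict_proba(X)[:, 1]
        separation = bool(probs[y == 1].min() > probs[y == 0].max())
        if not separation:
            raise RuntimeError(
                "logistic fit did not converge and the data are not separable; "
                f"markers={list(markers)}"
            )
        converged = False

    fpr, tpr, thr = roc_curve(y.astype(bool), probs, drop_intermediate=False)
    roc = ROCResult(thr, fpr, tpr, float(roc_auc_score(y, probs)))
    coef = pd.Series(params, index=["intercept", *markers], name="coefficient")
    return LogisticROC(roc, coef, probs, separation, converged)


@dataclass
class SplitEvaluation:
    panel: PanelDefinition
    train_summary: DiagnosticSummary
    test_summary: DiagnosticSummary
    train_roc: ROCResult | None
    test_roc: ROCResult | None
    train_separation: bool = False


def evaluate_split(
    train: pd.DataFrame,
    test: pd.DataFrame,
    panel_spec: PanelBuildSpec | PanelDefinition,
    combined_roc: bool = True,
) -> SplitEvaluation:
    """Build a panel on the training set only, then evaluate both sets.

    Cut-offs and marker selection are frozen from the training data and
    applied unchanged to the test set, so no test-set value can influence
    any threshold.  The combined ROC fits the logistic model on the
    training set and scores the test set with the trained coefficients.
    """
    if isinstance(panel_spec, PanelDefinition):
        panel = panel_spec
    else:
        panel = build_panel(train, panel_spec)
    train_summary = summarize_diagnostics(confusion(call_markers(train, panel)))
    test_summary = summarize_diagnostics(confusion(call_markers(test, panel)))

    train_roc = test_roc = None
    separation = False
    if combined_roc:
        fit = logistic_combined_roc(train, panel.markers)
        train_roc = fit.roc
        separation = fit.separation
        beta = fit.coefficients.to_numpy()
        X_test = test[list(panel.markers)].to_numpy(dtype=float)
        lin = beta[0] + X_test @ beta[1:]
        probs = 1.0 / (1.0 + np.exp(-lin))
        y_test = is_case(test["group"].to_numpy())
        if 0 < y_test.sum() < len(y_test):
            fpr, tpr, thr = roc_curve(y_test, probs, drop_intermediate=False)
            test_roc = ROCResult(thr, fpr, tpr, float(roc_auc_score(y_test, probs)))
    return SplitEvaluation(
        panel, train_summary, test_summary, train_roc, test_roc, separation
    )
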