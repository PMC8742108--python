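"""Three-class differential-expression screening and qPCR relative quantification.

The screen takes a log2-scale genes x samples matrix over tumour (T),
paired-normal (PN) and apparently-normal (AN) tissue classes, runs a
univariate one-way F-test per gene and applies a fold-change filter on the
class means (geometric means on the natural scale).  A gene is selected
when its p-value falls strictly below the significance threshold and at
least one pairwise class difference reaches the fold threshold
(inclusive).

Relative quantification follows the 2^-ddCt scheme: each gene Ct is
normalised against the arithmetic mean of the reference-gene Cts (the
log-scale equivalent of geometric-mean normalisation), then expressed
relative to the mean normalised value of the calibrator class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("T", "PN", "AN")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values (genes in rows) with a class per sample."""

    values: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.classes.index):
            self.classes = self.classes.reindex(self.values.columns)
        if self.classes.isna().any():
            raise ValueError("every sample needs a class label")
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown expression classes: {sorted(unknown)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def class_columns(self, cls: str) -> pd.DataFrame:
        return self.values.loc[:, (self.classes == cls).to_numpy()]


@dataclass
class ScreenResult:
    """Per-gene F statistics, p-values, pairwise log2 fold changes and calls."""

    table: pd.DataFrame
    p_threshold: float
    fold_threshold: float

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def class_comparison(
    matrix: ExpressionMatrix,
    p_threshold: float = 0.001,
    fold_threshold: float = 2.0,
) -> ScreenResult:
    """One-way F-test across the three classes plus a fold-change filter.

    Selection requires p strictly below ``p_threshold`` and the largest
    pairwise class-mean difference at least log2(``fold_threshold``)
    (inclusive at the boundary).  A class with fewer than 2 samples is
    excluded with a warning; an all-constant gene gets p = 1 and is never
    selected.  The preset (0.001, 2.0) is the screen's default; a stricter
    (0.0001, 2.5) preset mirrors a more conservative shortlist.
    """
    if not fold_threshold >= 1:
        raise ValueError("fold_threshold must be >= 1")
    used = []
    for c in CLASSES:
        n_c = int((matrix.classes == c).sum())
        if n_c >= 2:
            used.append(c)
        elif n_c > 0:
            warnings.warn(
                f"class {c} has {n_c} sample(s) and is excluded from the screen",
                stacklevel=2,
            )
    if len(used) < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")

    arrays = [matrix.class_columns(c).to_numpy() for c in used]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*arrays, axis=1)
    f_stat = np.asarray(f_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    # all-constant genes: no variance anywhere -> uninformative, never selected
    constant = np.all(np.concatenate(arrays, axis=1)
                      == arrays[0][:, :1], axis=1)
    f_stat[constant] = 0.0
    p[constant] = 1.0
    p = np.where(np.isnan(p), 1.0, p)

    means = {c: matrix.class_columns(c).to_numpy().mean(axis=1) for c in used}
    out = pd.DataFrame({"F": f_stat, "p": p}, index=matrix.values.index)
    pair_cols = []
    for i, a in enumerate(used):
        for b in used[i + 1:]:
            col = f"log2fc_{a}_vs_{b}"
            out[col] = means[a] - means[b]
            pair_cols.append(col)
    out["max_abs_log2_fold"] = np.abs(out[pair_cols].to_numpy()).max(axis=1)
    # tiny tolerance keeps an exactly-2-fold shift inclusive through float means
    fold_ok = out["max_abs_log2_fold"].to_numpy() >= np.log2(fold_threshold) - 1e-9
    out["selected"] = (p < p_threshold) & fold_ok
    top = np.argmax(np.column_stack([means[c] for c in used]), axis=1)
    out["direction"] = [f"up_in_{used[i]}" for i in top]
    return ScreenResult(out, p_threshold, fold_threshold)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: gene Ct plus reference-gene Cts for the sample."""

    sample_id: str
    gene: str
    ct: float
    reference_cts: Mapping[str, float] = field(default_factory=dict)
    sample_class: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"{self.sample_id}/{self.gene}: Ct must be finite and > 0")
        if len(self.reference_cts) == 0:
            raise ValueError(f"{self.sample_id}/{self.gene}: >= 1 reference gene required")


def relative_quantification(
    records: Sequence[CtRecord], calibrator_class: str
) -> pd.DataFrame:
    """2^-ddCt relative quantification against a calibrator class.

    dCt = Ct_gene - mean(reference Cts); ddCt subtracts the mean dCt of
    the calibrator-class samples per gene; RQ = 2^-ddCt.  Returns a
    samples x genes table of RQ values.
    """
    rows = []
    for r in records:
        refs = np.array(list(r.reference_cts.values()), dtype=float)
        if not np.isfinite(refs).all():
            raise ValueError(
                f"missing/non-finite reference Ct for sample {r.sample_id!r}, "
                f"gene {r.gene!r}"
            )
        rows.append(
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "dct": r.ct - refs.mean(),
                "is_calibrator": r.sample_class == calibrator_class,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame["is_calibrator"].any():
        raise ValueError(f"no samples in calibrator class {calibrator_class!r}")
    cal_mean = (
        frame[frame["is_calibrator"]].groupby("gene")["dct"].mean().rename("cal_dct")
    )
    frame = frame.join(cal_mean, on="gene")
    if frame["cal_dct"].isna().any():
        missing = sorted(frame.loc[frame["cal_dct"].isna(), "gene"].unique())
        raise ValueError(f"genes without calibrator measurements: {missing}")
    frame["rq"] = 2.0 ** -(frame["dct"] - frame["cal_dct"])
    return frame.pivot(index="sample_id", columns="gene", values="rq")


def gene_geometric_summary(rq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene geometric mean of RQ across samples, excluding zeros.

    Returns columns ``geometric_mean``, ``n_used`` and ``n_zero_excluded``.
    """
    values = rq_table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("RQ values must be nonnegative")
    out = []
    for j, gene in enumerate(rq_table.columns):
        col = values[:, j]
        col = col[~np.isnan(col)]
        nz = col[col > 0]
        geo = float(np.exp(np.mean(np.log(nz)))) if len(nz) else np.nan
        out.append(
            {
                "gene": gene,
                "geometric_mean": geo,
                "n_used": int(len(nz)),
                "n_zero_excluded": int((col == 0).sum()),
            }
        )
    return pd.DataFrame(out).set_index("gene")
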