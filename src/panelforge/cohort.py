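"""Seeded synthetic case-control cohorts for plasma biomarker studies.

The generator emulates a four-group breast-cancer case-control design
(healthy controls, benign breast disease, DCIS, invasive carcinoma) with
one numeric column per marker: plasma protein concentrations in pg/ml or
per-gene methylated/unmethylated (M/U) band-intensity ratios from
methylation-specific PCR of cell-free DNA.

Marker values follow a log-normal law parameterised by the per-group
median and a log-scale standard deviation, so distributions are
right-skewed and nonnegative, as plasma concentrations are.  Values under
a per-marker detection floor are recorded as 0, mimicking analytes that
fall below the assay's limit of detection.  Each marker draws from its own
seeded substream, so adding a marker never perturbs another marker's
values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "benign", "DCIS", "invasive")
CONTROL_GROUPS = frozenset({"control", "benign"})
CASE_GROUPS = frozenset({"DCIS", "invasive"})
STAGES = ("0", "I", "II", "III", "IV")

MarkerKind = Literal["protein_pg_ml", "mu_ratio"]
MarkerDirection = Literal["up_in_cases", "down_in_cases"]


def is_case(group):
    """Map group labels to case status (DCIS + invasive vs benign + healthy)."""
    if isinstance(group, str):
        if group == "case":
            return True
        if group not in GROUPS:
            raise ValueError(f"unknown group label: {group!r}")
        return group in CASE_GROUPS
    arr = np.asarray(group)
    bad = ~np.isin(arr, list(GROUPS) + ["case"])
    if bad.any():
        raise ValueError(f"unknown group labels: {sorted(set(arr[bad]))}")
    return np.isin(arr, list(CASE_GROUPS) + ["case"])


@dataclass(frozen=True)
class MarkerSpec:
    """Distributional description of one marker.

    group_location holds the per-group median on the natural scale;
    group_scale the log-scale standard deviation (scalar, or per-group).
    """

    name: str
    kind: MarkerKind = "protein_pg_ml"
    direction: MarkerDirection = "up_in_cases"
    group_location: Mapping[str, float] = field(default_factory=dict)
    group_scale: float | Mapping[str, float] = 0.8
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("protein_pg_ml", "mu_ratio"):
            raise ValueError(f"bad marker kind {self.kind!r}")
        if self.direction not in ("up_in_cases", "down_in_cases"):
            raise ValueError(f"bad marker direction {self.direction!r}")
        for g, loc in self.group_location.items():
            if g not in GROUPS:
                raise ValueError(f"{self.name}: unknown group {g!r}")
            if not np.isfinite(loc) or loc <= 0:
                raise ValueError(f"{self.name}: location for {g} must be finite and > 0")
        for s in self._scales().values():
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"{self.name}: scale must be finite and > 0")
        if not np.isfinite(self.detection_floor) or self.detection_floor < 0:
            raise ValueError(f"{self.name}: detection_floor must be >= 0")

    def _scales(self) -> dict[str, float]:
        if isinstance(self.group_scale, Mapping):
            return dict(self.group_scale)
        return {g: float(self.group_scale) for g in GROUPS}

    def scale_for(self, group: str) -> float:
        return self._scales()[group]


@dataclass(frozen=True)
class CovariateModel:
    """Frequencies for clinicopathological covariates of the case groups.

    The defaults follow the distribution of the study population the
    cohort emulates: node-positive, stage II-III, grade III disease
    dominates the invasive group.  ``mu_stage_factor`` is the
    multiplicative shift applied to M/U marker locations per stage step in
    invasive cases, producing the monotone stage-methylation link.
    """

    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.08, "II": 0.42, "III": 0.36, "IV": 0.14}
    )
    grade3_prob: float = 0.65
    node_positive_prob: float = 0.88
    metastasis_prob: float = 0.17
    er_positive_prob: float = 0.65
    pr_positive_prob: float = 0.44
    her2_probs: Mapping[str, float] = field(
        default_factory=lambda: {"negative": 0.26, "positive": 0.21, "2+": 0.53}
    )
    age_mean: float = 49.0
    age_sd: float = 11.0
    mu_stage_factor: float = 1.25
    cfdna_median: Mapping[str, float] = field(
        default_factory=lambda: {"control": 174.0, "benign": 181.0, "DCIS": 221.0}
    )
    cfdna_stage_median: Mapping[str, float] = field(
        default_factory=lambda: {"I": 297.0, "II": 437.0, "III": 763.0, "IV": 1687.0}
    )
    cfdna_log_sd: float = 0.35


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: Mapping[str, int]
    markers: Sequence[MarkerSpec]
    covariates: CovariateModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if int(n) < 0:
                raise ValueError(f"group size for {g} must be >= 0")
        if len(self.markers) == 0:
            raise ValueError("at least one marker is required")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    def size(self, group: str) -> int:
        return int(self.group_sizes.get(group, 0))


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent substream keyed by (seed, label); stable across runs."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


def _sample_covariates(
    groups: np.ndarray, cov: CovariateModel, seed: int
) -> pd.DataFrame:
    rng = _stream(seed, "__covariates__")
    n = len(groups)
    case_mask = np.isin(groups, list(CASE_GROUPS))
    invasive = groups == "invasive"

    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n).round(0), 25, 85)
    menstrual = np.where(age < 48, "premenopausal", "postmenopausal")

    stage = np.full(n, None, dtype=object)
    stage[groups == "DCIS"] = "0"
    labels = list(cov.stage_probs)
    probs = np.array([cov.stage_probs[s] for s in labels], dtype=float)
    probs = probs / probs.sum()
    stage[invasive] = rng.choice(labels, size=int(invasive.sum()), p=probs)

    def bernoulli_labels(p, yes, no):
        out = np.full(n, None, dtype=object)
        out[case_mask] = np.where(rng.random(int(case_mask.sum())) < p, yes, no)
        return out

    grade = bernoulli_labels(cov.grade3_prob, "III", "I-II")
    nodal = bernoulli_labels(cov.node_positive_prob, "positive", "negative")
    metastasis = bernoulli_labels(cov.metastasis_prob, "positive", "negative")
    er = bernoulli_labels(cov.er_positive_prob, "positive", "negative")
    pr = bernoulli_labels(cov.pr_positive_prob, "positive", "negative")
    her2 = np.full(n, None, dtype=object)
    h_labels = list(cov.her2_probs)
    h_probs = np.array([cov.her2_probs[k] for k in h_labels], dtype=float)
    her2[case_mask] = rng.choice(
        h_labels, size=int(case_mask.sum()), p=h_probs / h_probs.sum()
    )

    cf_median = np.empty(n)
    for g, med in cov.cfdna_median.items():
        cf_median[groups == g] = med
    for s, med in cov.cfdna_stage_median.items():
        cf_median[invasive & (stage == s)] = med
    cfdna = cf_median * np.exp(cov.cfdna_log_sd * rng.standard_normal(n))

    return pd.DataFrame(
        {
            "age": age,
            "menstrual": menstrual,
            "stage": stage,
            "grade": grade,
            "nodal": nodal,
            "metastasis": metastasis,
            "er": er,
            "pr": pr,
            "her2": her2,
            "cfdna_ng_ml": cfdna.round(1),
        }
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table: one row per sample, one column per marker.

    Marker values are log-normal around the configured per-group median;
    draws below the marker's detection floor are recorded as 0.  With a
    covariate model enabled, M/U markers of invasive cases are shifted
    multiplicatively per stage step (centred on stage II), giving the
    monotone stage-methylation association the cohort is meant to carry.
    """
    groups = np.concatenate(
        [np.repeat(g, config.size(g)) for g in GROUPS]
    ).astype(object)
    n = len(groups)
    sample_id = [f"{g}_{i:04d}" for g in GROUPS for i in range(config.size(g))]
    table = pd.DataFrame({"sample_id": sample_id, "group": groups})

    cov = config.covariates
    covariates = None
    stage_offset = np.zeros(n)
    if cov is not None:
        covariates = _sample_covariates(groups, cov, config.seed)
        invasive = groups == "invasive"
        idx = covariates["stage"].map(lambda s: _STAGE_INDEX.get(s, 2)).to_numpy()
        stage_offset[invasive] = idx[invasive] - _STAGE_INDEX["II"]

    for m in config.markers:
        rng = _stream(config.seed, "marker:" + m.name)
        z = rng.standard_normal(n)
        loc = np.array([m.group_location[g] for g in groups], dtype=float)
        scale = np.array([m.scale_for(g) for g in groups], dtype=float)
        vals = loc * np.exp(scale * z)
        if m.kind == "mu_ratio" and cov is not None:
            vals = vals * cov.mu_stage_factor ** stage_offset
        vals[vals < m.detection_floor] = 0.0
        table[m.name] = vals

    if covariates is not None:
        table = pd.concat([table, covariates], axis=1)
    return table


def split_train_test(
    table: pd.DataFrame, fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-group random split; `fraction` is the training share.

    The union of the parts is the input, the intersection empty, and the
    per-group training count is round(fraction * n_group), so group
    proportions are preserved to within one sample.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = _stream(seed, "__split__")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for g in GROUPS:
        idx = np.flatnonzero((table["group"] == g).to_numpy())
        if len(idx) == 0:
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(fraction * len(idx)))
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    train = table.iloc[np.sort(np.concatenate(train_idx))].reset_index(drop=True)
    test = table.iloc[np.sort(np.concatenate(test_idx))].reset_index(drop=True)
    return train, test


def generate_expression_matrix(
    n_genes: int,
    class_sizes: Mapping[str, int],
    planted: Sequence[tuple[int, str, float]] = (),
    noise_sd: float = 0.25,
    seed: int = 0,
    baseline: float = 8.0,
):
    """Log2-scale genes x samples matrix with i.i.d. Gaussian noise.

    ``planted`` lists (gene index, class, fold) effects: the class mean of
    that gene is shifted by log2(fold).  Every class needs >= 2 samples so
    the downstream F-test has a within-class variance estimate.
    """
    from .screen import CLASSES, ExpressionMatrix

    for c, size in class_sizes.items():
        if c not in CLASSES:
            raise ValueError(f"unknown expression class {c!r}")
        if int(size) < 2:
            raise ValueError(f"class {c} needs >= 2 samples, got {size}")
    rng = _stream(seed, "__expression__")
    classes = np.concatenate(
        [np.repeat(c, int(class_sizes.get(c, 0))) for c in CLASSES]
    ).astype(object)
    n_samples = len(classes)
    values = baseline + noise_sd * rng.standard_normal((int(n_genes), n_samples))
    for gene, cls, fold in planted:
        if not fold > 0:
            raise ValueError("planted fold must be > 0")
        values[int(gene), classes == cls] += np.log2(fold)
    sample_ids = [f"{c}{i:03d}" for c in CLASSES for i in range(int(class_sizes.get(c, 0)))]
    genes = [f"gene{i:05d}" for i in range(int(n_genes))]
    frame = pd.DataFrame(values, index=genes, columns=sample_ids)
    return ExpressionMatrix(frame, pd.Series(classes, index=sample_ids, name="class"))


# ---------------------------------------------------------------------------
# Reference synthetic study configuration
# ---------------------------------------------------------------------------

# Per-group medians (control, benign, DCIS, invasive) for the 15 plasma
# proteins, in pg/ml, with the regulation direction seen in cases relative
# to controls.  Detection floors give the zero-inflation of low-abundance
# analytes; WIF1's floor leaves roughly a third of samples below detection.
_PROTEIN_TABLE: dict[str, tuple[tuple[float, float, float, float], str, float]] = {
    "CFD": ((15587.84, 13279.12, 13398.16, 14956.99), "down_in_cases", 0.0),
    "FGF1": ((453.73, 992.47, 935.68, 704.56), "up_in_cases", 0.5),
    "FGF2": ((4.38, 3.94, 5.85, 6.44), "up_in_cases", 0.5),
    "DKK3": ((52628.68, 48443.83, 44521.15, 48047.86), "down_in_cases", 0.0),
    "sFRP3": ((218.72, 227.95, 232.78, 273.27), "up_in_cases", 0.0),
    "IGF1": ((1053.63, 6675.06, 6702.13, 5143.85), "up_in_cases", 0.5),
    "IL17B": ((246.50, 281.29, 644.06, 692.22), "up_in_cases", 0.5),
    "IP10": ((793.43, 531.31, 611.60, 872.59), "up_in_cases", 0.5),
    "LEP": ((16591.02, 15987.71, 15743.27, 15043.79), "down_in_cases", 0.0),
    "LOX1": ((31.32, 46.19, 38.50, 34.82), "up_in_cases", 0.0),
    "MIG": ((8.07, 14.59, 9.16, 11.67), "up_in_cases", 0.5),
    "MIP1d": ((3016.82, 2105.31, 2959.81, 3054.95), "up_in_cases", 0.0),
    "OPN": ((25970.97, 27841.24, 43285.42, 28631.63), "up_in_cases", 0.0),
    "SDC1": ((3433.04, 3230.24, 3016.82, 4819.05), "up_in_cases", 0.0),
    "WIF1": ((27.79, 30.87, 13.41, 43.08), "up_in_cases", 20.0),
}

# M/U ratio markers: controls sit well below 1, cases well above, with the
# separation strength of the densitometric MSP read-out in cfDNA.
_MU_TABLE: dict[str, tuple[float, float, float, float]] = {
    "SOSTDC1_meth": (0.30, 0.40, 2.2, 3.3),
    "DACT2_meth": (0.32, 0.42, 2.2, 3.2),
    "WIF1_meth": (0.28, 0.38, 2.6, 3.4),
}

PROTEIN_MARKER_NAMES = tuple(_PROTEIN_TABLE)
MU_MARKER_NAMES = tuple(_MU_TABLE)
PROTEIN_PANEL_CANDIDATES = ("CFD", "LEP", "DKK3", "IL17B", "SDC1", "FGF2")

DEFAULT_PROTEIN_LOG_SD = 0.8
DEFAULT_MU_LOG_SD = 0.6

STUDY_GROUP_SIZES = {"control": 203, "benign": 37, "DCIS": 16, "invasive": 202}


def default_study_markers(
    protein_log_sd: float = DEFAULT_PROTEIN_LOG_SD,
    mu_log_sd: float = DEFAULT_MU_LOG_SD,
) -> list[MarkerSpec]:
    markers = []
    for name, (medians, direction, floor) in _PROTEIN_TABLE.items():
        markers.append(
            MarkerSpec(
                name=name,
                kind="protein_pg_ml",
                direction=direction,  # type: ignore[arg-type]
                group_location=dict(zip(GROUPS, medians)),
                group_scale=protein_log_sd,
                detection_floor=floor,
            )
        )
    for name, medians in _MU_TABLE.items():
        markers.append(
            MarkerSpec(
                name=name,
                kind="mu_ratio",
                direction="up_in_cases",
                group_location=dict(zip(GROUPS, medians)),
                group_scale=mu_log_sd,
            )
        )
    return markers


def default_study_config(
    seed: int = 0,
    group_sizes: Mapping[str, int] | None = None,
    with_covariates: bool = True,
) -> CohortConfig:
    """The reference synthetic configuration: study-sized four-group cohort."""
    return CohortConfig(
        group_sizes=dict(group_sizes or STUDY_GROUP_SIZES),
        markers=default_study_markers(),
        covariates=CovariateModel() if with_covariates else None,
        seed=seed,
    )
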