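"""Readers, writers, run configuration and the end-to-end pipeline driver.

Cohort tables travel as tidy CSV/TSV (one row per sample, header row,
UTF-8, '.' decimal; TSV is auto-detected from the extension).  Expression
matrices are TSV with genes in rows and a two-line header (class labels,
then sample ids).  Lines starting with '#' are metadata and are skipped
on read; every file the pipeline writes embeds the run seed and config
hash in such a line, so reruns are auditable and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import cohort as coh
from . import stats as grpstats
from .panel import PanelBuildSpec, PanelDefinition
from .screen import ExpressionMatrix

log = logging.getLogger("panelforge")

REQUIRED_COLUMNS = ("sample_id", "group")
COVARIATE_COLUMNS = (
    "age",
    "menstrual",
    "stage",
    "grade",
    "nodal",
    "metastasis",
    "er",
    "pr",
    "her2",
    "cfdna_ng_ml",
)
_TEXT_COVARIATES = set(COVARIATE_COLUMNS) - {"age", "cfdna_ng_ml"}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Requires ``sample_id`` and ``group`` columns; group labels must come
    from the four-level enum, marker columns must be numeric and
    nonnegative.  Schema violations raise with the offending column or
    row named.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path.name}: duplicate sample ids {dupes[:5]}")
    bad_groups = set(table["group"]) - set(coh.GROUPS)
    if bad_groups:
        raise ValueError(
            f"{path.name}: group labels outside {coh.GROUPS}: {sorted(bad_groups)}"
        )
    marker_cols = [
        c
        for c in table.columns
        if c not in REQUIRED_COLUMNS and c not in COVARIATE_COLUMNS
    ]
    for col in marker_cols:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"{path.name}: non-numeric value in marker column {col!r} "
                f"around line {row}"
            )
        if (coerced.dropna() < 0).any():
            raise ValueError(f"{path.name}: negative values in marker column {col!r}")
        table[col] = coerced
    return table


def write_cohort(table: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        meta = []
        if seed is not None:
            meta.append(f"seed={seed}")
        if config_hash is not None:
            meta.append(f"config={config_hash}")
        if meta:
            fh.write("# panelforge cohort " + " ".join(meta) + "\n")
        table.to_csv(fh, sep=_sep_for(path), index=False)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """TSV, genes in rows; line 1 holds class labels, line 2 sample ids."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("class\t" + "\t".join(matrix.classes.astype(str)) + "\n")
        fh.write("gene_id\t" + "\t".join(matrix.values.columns) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False)


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        classes = fh.readline().rstrip("\n").split("\t")[1:]
        samples = fh.readline().rstrip("\n").split("\t")[1:]
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    values.columns = samples
    values.index.name = "gene_id"
    return ExpressionMatrix(values, pd.Series(classes, index=samples, name="class"))


def write_panel(panel: PanelDefinition, path, seed=None, config_hash=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = panel.to_dict()
    if seed is not None:
        doc["seed"] = int(seed)
    if config_hash is not None:
        doc["config"] = config_hash
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_panel(path) -> PanelDefinition:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return PanelDefinition.from_dict(doc)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    seed: int = 0
    cohort_path: str | None = None  # None -> simulate the reference cohort
    group_sizes: Mapping[str, int] | None = None
    panel_markers: tuple[str, ...] = coh.MU_MARKER_NAMES
    rule: str = "fixed_value"  # fixed_value | median_plus_k_mad | fixed_specificity
    k: float = 1.0
    fixed_cutoff: float = 1.0
    spec_target: float = 0.7
    select_loo: bool = True
    train_fraction: float = 0.7
    run_stats: bool = True
    run_evaluate: bool = True
    out_dir: str = "results/run"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(self.cohort_path)
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel_markers"] = list(self.panel_markers)
        if self.group_sizes is not None:
            d["group_sizes"] = dict(self.group_sizes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "panel_markers" in doc:
            doc["panel_markers"] = tuple(doc["panel_markers"])
        return cls(**doc)

    def config_hash(self) -> str:
        # output location and verbosity do not affect the computation
        d = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "log_level")}
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _table_hash(table: pd.DataFrame) -> str:
    return hashlib.sha256(
        table.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> split -> stats -> panel -> frozen evaluation.

    Returns the report bundle (also written as report.json) containing the
    seed, config hash, cohort snapshot hash, the frozen panel, train and
    test diagnostic summaries and combined-ROC AUCs.  Deterministic given
    (config, seed); any stage failure aborts with the stage named.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"seed": config.seed, "config_hash": chash}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("cohort")
        if config.cohort_path is None:
            cfg = coh.default_study_config(config.seed, config.group_sizes)
            table = coh.generate_cohort(cfg)
        else:
            table = read_cohort(config.cohort_path)
        report["cohort_hash"] = _table_hash(table)
        report["n_by_group"] = (
            table["group"].value_counts().reindex(coh.GROUPS, fill_value=0).to_dict()
        )
        write_cohort(table, out / "cohort.csv", config.seed, chash)
    except Exception as e:
        raise RuntimeError(f"stage 'cohort' failed: {e}") from e

    if config.run_stats:
        try:
            stage("stats")
            marker_cols = [
                c
                for c in table.columns
                if c not in REQUIRED_COLUMNS and c not in COVARIATE_COLUMNS
            ]
            stats_table = grpstats.marker_group_stats(table, marker_cols)
            with open(out / "stats.csv", "w", encoding="utf-8") as fh:
                fh.write(f"# panelforge stats seed={config.seed} config={chash}\n")
                stats_table.to_csv(fh)
            report["stats"] = {
                m: {"H": float(r["H"]), "p": float(r["p"])}
                for m, r in stats_table.iterrows()
            }
        except Exception as e:
            raise RuntimeError(f"stage 'stats' failed: {e}") from e

    try:
        stage("split")
        train, test = coh.split_train_test(
            table, config.train_fraction, config.seed
        )
        log.info("split: %d train / %d test", len(train), len(test))
        write_cohort(train, out / "train.csv", config.seed, chash)
        write_cohort(test, out / "test.csv", config.seed, chash)
    except Exception as e:
        raise RuntimeError(f"stage 'split' failed: {e}") from e

    try:
        stage("panel")
        directions = {}
        if config.cohort_path is None:
            for m in coh.default_study_markers():
                directions[m.name] = (
                    "positive_above"
                    if m.direction == "up_in_cases"
                    else "positive_below"
                )
        spec = PanelBuildSpec(
            markers=tuple(config.panel_markers),
            rule=config.rule,
            k=config.k,
            fixed_cutoff=config.fixed_cutoff,
            spec_target=config.spec_target,
            directions=directions or None,
            select=config.select_loo,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'panel' failed: {e}") from e

    if config.run_evaluate:
        try:
            stage("evaluate")
            from .diagnostics import evaluate_split

            result = evaluate_split(train, test, spec)
            write_panel(result.panel, out / "panel.yaml", config.seed, chash)
            report["panel"] = result.panel.to_dict()
            report["train"] = result.train_summary.to_dict()
            report["test"] = result.test_summary.to_dict()
            report["train_auc"] = (
                None if result.train_roc is None else result.train_roc.auc
            )
            report["test_auc"] = (
                None if result.test_roc is None else result.test_roc.auc
            )
            report["separation"] = bool(result.train_separation)
            if result.train_roc is not None:
                result.train_roc.as_frame().to_csv(out / "roc_train.csv", index=False)
            if result.test_roc is not None:
                result.test_roc.as_frame().to_csv(out / "roc_test.csv", index=False)
        except Exception as e:
            raise RuntimeError(f"stage 'evaluate' failed: {e}") from e

    report_json = json.dumps(report, indent=2, sort_keys=True)
    (out / "report.json").write_text(report_json, encoding="utf-8")
    report["report_hash"] = hashlib.sha256(report_json.encode()).hexdigest()[:16]
    return report
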