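"""End-to-end pipeline orchestration and human-readable reports.

Runs simulate -> extract -> train -> validate -> report from one serializable
configuration, and provides the descriptive-statistics helpers for the
reference cohort's printed tables (grade distribution summary, confusion
matrix layout with row percentages).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    BootstrapSummary,
    ConfusionMatrix,
    SVMConfig,
    TrainedModel,
    bootstrap_validate,
    confusion_and_accuracy,
    confusion_from_counts,
    train_svm,
    variable_importance,
)
from .features import DIALECTS, FEATURE_NAMES, cohort_feature_table, write_feature_table
from .reference import CLASS_ORDER, GRADE_RANGE
from .simulate import DEFAULT_CLASS_COUNTS, SimParams, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    ``seed`` is the master seed; the simulation and classifier streams are
    derived from it deterministically (overriding the seeds inside ``sim``
    and ``svm``).
    """

    sim: SimParams = field(default_factory=SimParams)
    svm: SVMConfig = field(default_factory=SVMConfig)
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    dialect: str = "caption"
    outdir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        object.__setattr__(self, "class_counts", {k: int(v) for k, v in self.class_counts.items()})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["compensation_matrix"] = {
            k: list(v) for k, v in d["sim"]["compensation_matrix"].items()
        }
        d["svm"]["cost_grid"] = list(d["svm"]["cost_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimParams(**d.pop("sim", {}))
        svm_d = dict(d.pop("svm", {}))
        if "cost_grid" in svm_d:
            svm_d["cost_grid"] = tuple(svm_d["cost_grid"])
        svm = SVMConfig(**svm_d)
        return cls(sim=sim, svm=svm, **d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


def _derived_seed(master: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(master), int(stream)]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    config: PipelineConfig
    feature_table: pd.DataFrame
    model: TrainedModel
    validation: BootstrapSummary
    resubstitution: ConfusionMatrix
    bootstrap_confusion: ConfusionMatrix
    importance: pd.DataFrame
    paths: dict[str, Path]


def _meta(config: PipelineConfig) -> dict:
    return {"version": __version__, "seed": config.seed, "dialect": config.dialect}


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Simulate a cohort, extract features, train, validate and write reports.

    Idempotent given the seed: rerunning with the same configuration rewrites
    byte-identical feature tables and confusion counts.  Every artifact embeds
    the package version, master seed and asymmetry-index dialect.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_params = dataclasses.replace(config.sim, seed=_derived_seed(config.seed, 0))
    svm_config = dataclasses.replace(config.svm, seed=_derived_seed(config.seed, 1))

    logger.info("simulating %d trials", sum(config.class_counts.values()))
    trials = simulate_cohort(config.class_counts, params=sim_params)
    table = cohort_feature_table(trials, dialect=config.dialect)
    paths = {"features": write_feature_table(table, outdir / "features.csv")}

    X, y = table[list(FEATURE_NAMES)], table["label"]
    logger.info("training (grid search over %d costs)", len(svm_config.cost_grid))
    model = train_svm(X, y, svm_config)
    logger.info("selected cost %.2f; validating with %d bootstrap repetitions",
                model.cost, svm_config.bootstrap_reps)
    validation = bootstrap_validate(X, y, svm_config, cost=model.cost)

    resub = confusion_and_accuracy(y, model.predict(X))
    order = list(validation.confusion_counts.index)
    boot_cm = confusion_from_counts(validation.confusion_counts.to_numpy(), order)
    importance = variable_importance(X, y)

    meta = _meta(config)
    confusion_payload = {
        "meta": meta,
        # provenance of each matrix is deliberately explicit: resubstitution
        # re-scores the training data, bootstrap_oob aggregates out-of-bag
        # predictions over all repetitions
        "resubstitution": _confusion_dict(resub),
        "bootstrap_oob": _confusion_dict(boot_cm),
    }
    paths["confusion"] = outdir / "confusion.json"
    paths["confusion"].write_text(json.dumps(confusion_payload, indent=2))

    validation_payload = {
        "meta": meta,
        "cost": model.cost,
        "grid_results": {str(k): v for k, v in model.grid_results.items()},
        "bootstrap_reps": svm_config.bootstrap_reps,
        "mean_accuracy": validation.mean,
        "sd_accuracy": validation.sd,
        "macro_accuracy": validation.macro_accuracy,
        "per_class_accuracy": validation.per_class_mean,
        "redraws": validation.redraws,
    }
    paths["validation"] = outdir / "validation.json"
    paths["validation"].write_text(json.dumps(validation_payload, indent=2))

    paths["importance"] = outdir / "importance.csv"
    importance.to_csv(paths["importance"], index_label="feature")
    paths["model"] = outdir / "model.joblib"
    model.save(paths["model"])
    paths["config"] = outdir / "config.yaml"
    config.to_yaml(paths["config"])

    return PipelineResult(
        config=config,
        feature_table=table,
        model=model,
        validation=validation,
        resubstitution=resub,
        bootstrap_confusion=boot_cm,
        importance=importance,
        paths=paths,
    )


def _confusion_dict(cm: ConfusionMatrix) -> dict:
    return {
        "class_order": list(cm.counts.index),
        "counts": cm.counts.to_numpy().tolist(),
        "row_percent": np.round(cm.row_percent.to_numpy(), 10).tolist(),
        "per_class_accuracy": cm.per_class_accuracy,
        "overall_accuracy": cm.overall_accuracy,
    }


# ---------------------------------------------------------------------------
# descriptive statistics of the printed tables
# ---------------------------------------------------------------------------

@dataclass
class GradeTable:
    """Count-weighted grade summary per lame class (grades 2-7)."""

    counts: dict[str, tuple[int, ...]]
    total: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]

    def formatted(self) -> pd.DataFrame:
        rows = []
        for label, cnts in self.counts.items():
            rows.append({
                "class": label,
                **{f"grade_{g}": c for g, c in zip(GRADE_RANGE, cnts)},
                "total": self.total[label],
                "mean_sd": f"{self.mean[label]:.1f} ± {self.sd[label]:.1f}",
            })
        return pd.DataFrame(rows)


def grade_summary(counts: dict[str, tuple[int, ...] | list[int]]) -> GradeTable:
    """Count-weighted mean and sample SD of lameness grade per class.

    ``counts[label]`` holds the number of horses at each grade 2..7.  Full
    precision is retained; :meth:`GradeTable.formatted` rounds for display.
    """
    grades = np.asarray(GRADE_RANGE, dtype=float)
    out_counts, totals, means, sds = {}, {}, {}, {}
    for label, row in counts.items():
        row = tuple(int(c) for c in row)
        if len(row) != len(GRADE_RANGE):
            raise ValueError(f"{label}: expected {len(GRADE_RANGE)} grade counts")
        if any(c < 0 for c in row):
            raise ValueError(f"{label}: negative counts")
        n = sum(row)
        if n == 0:
            raise ValueError(f"{label}: all-zero grade row")
        w = np.asarray(row, dtype=float)
        mean = float(w @ grades / n)
        if n > 1:
            sd = float(np.sqrt(w @ (grades - mean) ** 2 / (n - 1)))
        else:
            sd = 0.0
        out_counts[label], totals[label], means[label], sds[label] = row, n, mean, sd
    return GradeTable(counts=out_counts, total=totals, mean=means, sd=sds)


def matrix_report(counts, class_order=CLASS_ORDER) -> tuple[str, ConfusionMatrix]:
    """Render a confusion-count matrix with row percentages to one decimal,
    plus per-class and overall accuracy.  Returns (text, metrics)."""
    cm = confusion_from_counts(counts, class_order)
    width = 14
    header = "actual \\ predicted".ljust(20) + "".join(c.rjust(width) for c in class_order)
    lines = [header]
    for actual in class_order:
        cells = []
        for predicted in class_order:
            n = int(cm.counts.loc[actual, predicted])
            pct = cm.row_percent.loc[actual, predicted]
            cells.append(f"{n} ({pct:.1f}%)".rjust(width))
        lines.append(actual.ljust(20) + "".join(cells))
    lines.append("")
    for c in class_order:
        lines.append(f"accuracy {c}: {cm.per_class_accuracy[c]:.1f}%")
    lines.append(f"overall accuracy: {cm.overall_accuracy:.1f}%")
    return "\n".join(lines), cm
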