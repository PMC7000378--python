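"""End-to-end pipeline orchestration, cohort summaries, and region reports.

A run executes extract -> screen -> split -> RFE -> fit -> evaluate ->
subgroup CV -> shuffle test in order, logging each stage, and writes every
artifact (feature table, correlation matrix, selection, model, evaluation,
shuffle distribution, region report) plus a config snapshot under one run
directory.  The package also bundles the published two-session region
coefficient table so overlap analyses can be exercised without subject data.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthcohort
from .atlasfeat import DEFAULT_THRESHOLD, FeatureTable, extract_features
from .model import fit_logistic, stratified_split
from .screen import pearson_matrix, rfe_select, triple_screen
from .synthcohort import SyntheticConfig, build_atlas, generate_cohort
from .validate import evaluate, shuffle_test, subgroup_cv

__all__ = [
    "RunConfig",
    "PipelineResult",
    "load_region_reference",
    "selected_regions_by_day",
    "region_overlap",
    "cohort_summary",
    "run_pipeline",
]

_REFERENCE_TSV = "region_coefficients_2session.tsv"


def load_region_reference() -> pd.DataFrame:
    """Bundled two-session region/coefficient report (one row per region record).

    Columns: region_id, abbreviation, name, day1_coef, day2_coef; a missing
    coefficient means the region was not selected in that session.
    """
    with resources.files("roiclassify.data").joinpath(_REFERENCE_TSV).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if df["region_id"].duplicated().any():
        raise ValueError("region ids in the reference table must be unique")
    return df


def selected_regions_by_day(reference: pd.DataFrame | None = None
                            ) -> tuple[list[int], list[int]]:
    """Region ids selected in session 1 and session 2 of the reference report."""
    ref = load_region_reference() if reference is None else reference
    day1 = ref.loc[ref["day1_coef"].notna(), "region_id"].astype(int).tolist()
    day2 = ref.loc[ref["day2_coef"].notna(), "region_id"].astype(int).tolist()
    return day1, day2


def region_overlap(selected_day1, selected_day2
                   ) -> tuple[list[int], list[int], list[int]]:
    """(shared, only_day1, only_day2) as disjoint sorted id lists."""
    s1, s2 = set(selected_day1), set(selected_day2)
    return sorted(s1 & s2), sorted(s1 - s2), sorted(s2 - s1)


def cohort_summary(labels: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, male count and percentage (one decimal), age mean and SD.

    Sample SD (ddof=1); a single-subject group reports SD as NaN (undefined).
    """
    labels = pd.Series(labels)
    rows = []
    for grp, name in ((0, "control"), (1, "case")):
        idx = labels.index[labels == grp]
        if len(idx) == 0:
            continue
        cov = covariates.loc[idx]
        n = len(idx)
        n_male = int(cov["sex"].sum())
        age = cov["age"].to_numpy(dtype=float)
        rows.append({
            "group": name, "n": n,
            "male_n": n_male,
            "male_pct": round(100.0 * n_male / n, 1),
            "age_mean": float(np.mean(age)),
            "age_sd": float(np.std(age, ddof=1)) if n > 1 else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Settings of one pipeline run; the defaults are the study settings.

    Either ``features_csv`` points at a precomputed feature table, or
    ``synthetic`` describes a cohort to simulate.
    """

    threshold: float = DEFAULT_THRESHOLD
    ratio: float = 0.7
    k: int = 10
    rfe_target: int | None = None  # None -> half the regions
    penalty: float | None = None   # None -> 1/n_train
    n_shuffles: int = 1000
    escalation: int = 10_000
    seed: int = 0
    collinearity_cutoff: float = 0.9
    features_csv: str | None = None
    synthetic: SyntheticConfig = field(default_factory=synthcohort.default_effect_config)
    out_dir: str = "run"

    def validate(self) -> None:
        if not 0.5 <= self.ratio <= 0.9:
            raise ValueError("ratio must be in [0.5, 0.9]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0.0 < self.collinearity_cutoff <= 1.0:
            raise ValueError("collinearity_cutoff must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "ratio": self.ratio, "k": self.k,
            "rfe_target": self.rfe_target, "penalty": self.penalty,
            "n_shuffles": self.n_shuffles, "escalation": self.escalation,
            "seed": self.seed, "collinearity_cutoff": self.collinearity_cutoff,
            "features_csv": self.features_csv,
            "synthetic": self.synthetic.to_dict(),
            "out_dir": self.out_dir,
        }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Everything one run produced, with the paths it was written to."""

    config: RunConfig
    features: FeatureTable
    screening: dict
    selection: object
    model: object
    evaluation: object
    cv_mean: float
    cv_accuracies: list[float]
    shuffle: object
    region_report: pd.DataFrame
    log: list[dict]
    out_dir: Path


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full classification pipeline and write all artifacts.

    Stages run in a fixed order under seeds derived from ``config.seed``;
    rerunning with an identical config reproduces every output byte for byte.
    A stage failure aborts the run naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        log.append({"stage": name, "seed": config.seed,
                    "wall_time_s": round(time.perf_counter() - t0, 3)})
        return result

    if config.features_csv:
        features = stage("load_features",
                         lambda: FeatureTable.from_csv(config.features_csv))
    else:
        def simulate():
            sc = config.synthetic
            atlas = build_atlas(sc.grid_dims, sc.n_regions, seed=sc.seed,
                                spacing=sc.spacing)
            cohort = generate_cohort(sc, atlas)
            return extract_features(cohort, atlas, threshold=config.threshold)
        features = stage("simulate+extract", simulate)
    labels = features.labels
    log[-1]["input_hash"] = _hash_frame(features.counts)

    split = stage("split", lambda: stratified_split(
        labels, ratio=config.ratio, seed=config.seed))
    screening = stage("screen", lambda: triple_screen(
        features, split.train_ids, split.test_ids,
        cutoff=config.collinearity_cutoff))
    train = features.subset(split.train_ids)
    test = features.subset(split.test_ids)
    target = config.rfe_target or max(1, len(features.region_ids) // 2)
    selection = stage("rfe", lambda: rfe_select(
        train, labels.loc[split.train_ids], target, seed=config.seed,
        penalty=config.penalty))
    model = stage("fit", lambda: fit_logistic(
        train, labels.loc[split.train_ids],
        selected_region_ids=selection.selected_region_ids,
        penalty=config.penalty, seed=config.seed))
    evaluation = stage("evaluate", lambda: evaluate(
        model, test, labels.loc[split.test_ids]))
    k = min(config.k, len(split.test_ids))
    cv_mean, cv_accs = stage("subgroup_cv", lambda: subgroup_cv(
        model, test, labels.loc[split.test_ids], k=k, seed=config.seed))
    shuffle = stage("shuffle_test", lambda: shuffle_test(
        features, labels, selection.selected_region_ids,
        observed_accuracy=float(evaluation.accuracy),
        n_runs=config.n_shuffles, escalation_runs=config.escalation,
        ratio=config.ratio, seed=config.seed, penalty=config.penalty))

    region_report = pd.DataFrame({
        "region_id": selection.selected_region_ids,
        "coefficient": [model.coefficients[r]
                        for r in selection.selected_region_ids],
    })

    # artifacts
    features.to_csv(out / "features.csv")
    pearson_matrix(features).to_csv(out / "corr.csv")
    _json_dump(selection.to_dict(), out / "selection.json")
    _json_dump(model.to_dict(), out / "model.json")
    _json_dump({**evaluation.to_dict(),
                "subgroup_cv_mean": cv_mean,
                "subgroup_cv_accuracies": cv_accuracies_to_list(cv_accs),
                "split": split.to_dict()}, out / "evaluation.json")
    _json_dump(shuffle.to_dict(), out / "shuffle.json")
    pd.DataFrame({"accuracy": shuffle.shuffled_accuracies}).to_csv(
        out / "shuffle.csv", index_label="run")
    region_report.to_csv(out / "regions.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "log.jsonl").write_text(
        "\n".join(json.dumps(rec, sort_keys=True) for rec in log) + "\n")

    return PipelineResult(config=config, features=features, screening=screening,
                          selection=selection, model=model,
                          evaluation=evaluation, cv_mean=cv_mean,
                          cv_accuracies=cv_accs, shuffle=shuffle,
                          region_report=region_report, log=log, out_dir=out)


def cv_accuracies_to_list(accs) -> list[float]:
    return [float(a) for a in accs]
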