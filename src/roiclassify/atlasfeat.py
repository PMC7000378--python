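"""Threshold t-statistic maps and count significant voxels per atlas region.

The per-subject, per-region count of voxels whose t value reaches the
significance cutoff (default t >= 3.17, one-sided p ~ 0.001) is the model's
input feature.  The cutoff comparison is inclusive by default and only the
positive tail is counted, matching a one-sided "more activated" contrast;
absolute-value and exclusive variants are available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthcohort import AtlasVolume, SubjectVolume

__all__ = [
    "DEFAULT_THRESHOLD",
    "FeatureTable",
    "ThresholdCurve",
    "count_significant_voxels",
    "extract_features",
    "threshold_curve",
    "t_tail_probability",
]

DEFAULT_THRESHOLD = 3.17

_COVARIATE_COLS = ("age", "sex")


@dataclass
class FeatureTable:
    """Subjects x regions matrix of supra-threshold voxel counts.

    ``counts`` is indexed by subject id with one integer column per region id;
    ``labels`` is the binary group per subject (case = 1); ``covariates``
    carries age and sex aligned to the same index.
    """

    counts: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("voxel counts must be nonnegative")
        if not self.counts.index.equals(self.labels.index):
            raise ValueError("counts and labels must share the subject index")
        if not self.counts.index.equals(self.covariates.index):
            raise ValueError("counts and covariates must share the subject index")

    @property
    def region_ids(self) -> list[int]:
        return list(self.counts.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.counts)

    def subset(self, subject_ids) -> "FeatureTable":
        return FeatureTable(counts=self.counts.loc[subject_ids],
                            labels=self.labels.loc[subject_ids],
                            covariates=self.covariates.loc[subject_ids],
                            threshold=self.threshold)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.concat([self.labels.rename("group"), self.covariates,
                        self.counts], axis=1)
        df.insert(0, "threshold", self.threshold)
        df.to_csv(path, index_label="subject_id")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        threshold = float(df.pop("threshold").iloc[0])
        labels = df.pop("group").astype(int)
        cov = df[list(_COVARIATE_COLS)]
        counts = df.drop(columns=list(_COVARIATE_COLS))
        counts.columns = [int(c) for c in counts.columns]
        return cls(counts=counts, labels=labels, covariates=cov,
                   threshold=threshold)


@dataclass
class ThresholdCurve:
    """Per-subject total significant-voxel counts along an ascending t grid."""

    thresholds: np.ndarray
    counts: pd.DataFrame  # subjects x thresholds

    def __post_init__(self) -> None:
        diffs = np.diff(self.counts.to_numpy(), axis=1)
        if (diffs > 0).any():
            raise ValueError("counts must be non-increasing in threshold")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.counts.to_csv(path, index_label="subject_id")
        return path


def _check_dims(volume: SubjectVolume, atlas: AtlasVolume) -> None:
    if volume.tmap.shape != atlas.labels.shape:
        raise ValueError(
            f"volume grid {volume.tmap.shape} does not match atlas grid "
            f"{atlas.labels.shape}"
        )


def _significant(tmap: np.ndarray, threshold: float, mode: str,
                 inclusive: bool) -> np.ndarray:
    if mode == "positive":
        vals = tmap
    elif mode == "absolute":
        vals = np.abs(tmap)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'positive' or 'absolute'")
    return vals >= threshold if inclusive else vals > threshold


def count_significant_voxels(volume: SubjectVolume, atlas: AtlasVolume,
                             threshold: float = DEFAULT_THRESHOLD,
                             mode: str = "positive",
                             inclusive: bool = True) -> pd.Series:
    """Number of voxels with t >= threshold per atlas region.

    Background (label 0) voxels are ignored; regions with no voxel in the
    subject's field of view report 0, never missing.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    _check_dims(volume, atlas)
    sig = _significant(volume.tmap, threshold, mode, inclusive)
    counts = np.bincount(atlas.labels[sig].ravel(),
                         minlength=atlas.n_regions + 1)[1:]
    return pd.Series(counts, index=pd.Index(atlas.region_ids, name="region_id"),
                     name=volume.subject_id)


def extract_features(cohort: list[SubjectVolume], atlas: AtlasVolume,
                     threshold: float = DEFAULT_THRESHOLD,
                     mode: str = "positive",
                     inclusive: bool = True) -> FeatureTable:
    """Build the subjects x regions feature table, one row per subject in order."""
    if not cohort:
        raise ValueError("cohort is empty")
    bad = [s.subject_id for s in cohort if s.tmap.shape != atlas.labels.shape]
    if bad:
        raise ValueError(f"subjects with grids mismatching the atlas: {bad}")
    rows = [count_significant_voxels(s, atlas, threshold, mode, inclusive)
            for s in cohort]
    counts = pd.DataFrame(rows)
    counts.index.name = "subject_id"
    labels = pd.Series([s.group for s in cohort], index=counts.index,
                       name="group")
    cov = pd.DataFrame({"age": [s.age for s in cohort],
                        "sex": [s.sex for s in cohort]}, index=counts.index)
    return FeatureTable(counts=counts, labels=labels, covariates=cov,
                        threshold=threshold)


def threshold_curve(cohort: list[SubjectVolume], thresholds,
                    atlas: AtlasVolume | None = None,
                    mode: str = "positive",
                    inclusive: bool = True) -> ThresholdCurve:
    """Total significant voxels per subject at each threshold (the t-sweep plot).

    With an atlas, only foreground voxels are counted; otherwise the whole
    grid.  Thresholds must be strictly ascending; the per-subject series is
    then non-increasing by construction.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or len(thresholds) < 1:
        raise ValueError("thresholds must be a 1-D sequence")
    if (np.diff(thresholds) <= 0).any():
        raise ValueError("thresholds must be strictly ascending")
    if not cohort:
        raise ValueError("cohort is empty")
    rows = {}
    for s in cohort:
        if atlas is not None:
            _check_dims(s, atlas)
            vals = s.tmap[atlas.labels > 0]
        else:
            vals = s.tmap.ravel()
        rows[s.subject_id] = [
            int(_significant(vals, t, mode, inclusive).sum()) for t in thresholds
        ]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=thresholds)
    counts.index.name = "subject_id"
    return ThresholdCurve(thresholds=thresholds, counts=counts)


def t_tail_probability(t: float, df: float) -> float:
    """One-sided upper-tail p of Student's t; df=inf gives the normal limit."""
    if not df > 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    if np.isinf(df):
        return float(stats.norm.sf(t))
    return float(stats.t.sf(t, df))
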