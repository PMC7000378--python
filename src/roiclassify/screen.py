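"""Feature screening: correlation structure and recursive feature elimination.

Two screens run before the model fit.  A Pearson-correlation screen across
regions flags multicollinear pairs (|R| >= 0.9 by default) that would distort
logistic coefficients; per study practice it is run three times — on the
training rows, the test rows, and both combined.  Recursive feature
elimination (RFE) then repeatedly fits the logistic learner on
training-standardized features and drops the feature with the smallest
absolute coefficient, one per round, until the target count remains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlasfeat import FeatureTable
from .model import newton_logistic, standardize_columns

__all__ = [
    "CorrelationMatrix",
    "SelectionResult",
    "pearson_matrix",
    "flag_collinear",
    "high_correlation_counts",
    "rfe_select",
    "triple_screen",
]


@dataclass
class CorrelationMatrix:
    """Regions x regions Pearson R over subjects; zero-variance regions flagged."""

    values: pd.DataFrame
    zero_variance_ids: list[int]

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlation values must lie in [-1, 1]")

    @property
    def region_ids(self) -> list[int]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.to_csv(path, index_label="region_id")
        return path

    def plot_heatmap(self, path: str | Path, title: str = "Pearson R") -> Path:
        """Render the matrix as a heatmap image (diagonal = 1 appears white-hot)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.values.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(title)
        ax.set_xlabel("region")
        ax.set_ylabel("region")
        fig.colorbar(im, ax=ax, label="R")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


@dataclass
class SelectionResult:
    """Surviving features and the order in which the rest were eliminated."""

    selected_region_ids: list[int]
    elimination_order: list[int]
    n_target: int

    def __post_init__(self) -> None:
        sel, elim = set(self.selected_region_ids), set(self.elimination_order)
        if sel & elim:
            raise ValueError("selected and eliminated sets overlap")
        if len(self.selected_region_ids) != self.n_target:
            raise ValueError("selected set size must equal n_target")

    def to_dict(self) -> dict:
        return {"selected_region_ids": list(self.selected_region_ids),
                "elimination_order": list(self.elimination_order),
                "n_target": self.n_target}


def pearson_matrix(features: FeatureTable | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson R over subjects for every region pair.

    Zero-variance regions (constant counts) are reported and given R = 0
    off-diagonal rather than propagating undefined values.
    """
    counts = features.counts if isinstance(features, FeatureTable) else features
    if len(counts) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(counts)}")
    X = counts.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    zero_var = [int(c) for c, s in zip(counts.columns, sd) if s == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    values = pd.DataFrame(R, index=counts.columns, columns=counts.columns)
    return CorrelationMatrix(values=values, zero_variance_ids=zero_var)


def flag_collinear(corr: CorrelationMatrix,
                   cutoff: float = 0.9) -> list[tuple[int, int, float]]:
    """Unordered off-diagonal pairs with |R| >= cutoff (multicollinearity rule).

    An empty list means every feature is retained.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    ids = corr.region_ids
    R = corr.values.to_numpy()
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(R[i, j]) >= cutoff:
                out.append((ids[i], ids[j], float(R[i, j])))
    return out


def high_correlation_counts(corr: CorrelationMatrix,
                            levels=(0.7, 0.8, 0.9)) -> dict[float, int]:
    """Number of unordered off-diagonal pairs with R strictly above each level."""
    R = corr.values.to_numpy()
    iu = np.triu_indices_from(R, k=1)
    upper = R[iu]
    return {float(lv): int((upper > lv).sum()) for lv in levels}


def rfe_select(train_features: FeatureTable, train_labels: pd.Series,
               n_target: int, seed: int = 0, penalty: float | None = None,
               include_covariates: bool = True) -> SelectionResult:
    """Recursive feature elimination with the logistic learner, one per round.

    Must be run on training rows only.  Each round fits the penalized logistic
    model on the surviving training-standardized region features (plus pinned
    age/sex covariates, which are never eliminated) and removes the region
    with the smallest absolute coefficient; ties break toward the higher
    column position.  Deterministic given the seed.
    """
    region_ids = list(train_features.counts.columns)
    if not 1 <= n_target <= len(region_ids):
        raise ValueError(
            f"n_target {n_target} outside [1, {len(region_ids)}] features")
    y = pd.Series(train_labels).loc[train_features.counts.index].to_numpy(dtype=float)
    if penalty is None:
        penalty = 1.0 / len(y)
    Xall = train_features.counts.to_numpy(dtype=float)
    if include_covariates:
        pin = train_features.covariates.to_numpy(dtype=float)
    else:
        pin = np.empty((len(y), 0))

    surviving = list(range(len(region_ids)))
    elimination: list[int] = []
    while len(surviving) > n_target:
        X = np.column_stack([Xall[:, surviving], pin])
        Xs, _, _ = standardize_columns(X)
        beta, _, _ = newton_logistic(Xs, y, penalty, gtol=1e-7, maxiter=60)
        imp = np.abs(beta[1:1 + len(surviving)])
        # smallest importance goes; np.argmin on the reversed array makes ties
        # break toward the later (higher-position) column
        weakest = len(imp) - 1 - int(np.argmin(imp[::-1]))
        elimination.append(region_ids[surviving[weakest]])
        del surviving[weakest]
    return SelectionResult(
        selected_region_ids=[region_ids[i] for i in surviving],
        elimination_order=elimination,
        n_target=n_target,
    )


def triple_screen(features: FeatureTable, train_ids, test_ids,
                  cutoff: float = 0.9) -> dict[str, dict]:
    """Collinearity screen on train, test, and combined tables (three reports)."""
    reports = {}
    for name, ids in (("train", list(train_ids)), ("test", list(test_ids)),
                      ("combined", list(train_ids) + list(test_ids))):
        corr = pearson_matrix(features.subset(ids))
        reports[name] = {
            "flagged_pairs": flag_collinear(corr, cutoff=cutoff),
            "zero_variance_ids": corr.zero_variance_ids,
            "high_correlation_counts": high_correlation_counts(corr),
        }
    return reports
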