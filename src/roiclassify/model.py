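"""Stratified splitting and penalized logistic regression on region counts.

The classifier is the logit model

    p(x) = 1 / (1 + exp(-(b0 + b1 x1 + ... + bi xi)))

fitted by maximizing the binomial log-likelihood with a small ridge penalty
(strength 1/n_train by default) on training-standardized features.  The
default optimizer is a damped Newton (IRLS) iteration — deterministic and
stable at small n — with a seeded stochastic-gradient option behind a flag.
Age and sex enter as covariates alongside the selected region counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .atlasfeat import FeatureTable

__all__ = [
    "SplitSpec",
    "FittedModel",
    "ConvergenceError",
    "stratified_split",
    "fit_logistic",
    "predict_probability",
    "ratio_sweep",
]

COVARIATE_NAMES = ("age", "sex")


class ConvergenceError(RuntimeError):
    """Raised when the likelihood maximizer stalls within its iteration budget."""


@dataclass
class SplitSpec:
    """Disjoint train/test subject-id sets from a per-class stratified draw."""

    train_ids: list
    test_ids: list
    ratio: float
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")

    def to_dict(self) -> dict:
        return {"train_ids": list(self.train_ids), "test_ids": list(self.test_ids),
                "ratio": self.ratio, "seed": self.seed,
                "stratified": self.stratified}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels: pd.Series, ratio: float = 0.7,
                     seed: int = 0) -> SplitSpec:
    """Per-class sampling without replacement into train/test.

    The per-class training count is round-half-up(ratio * class size); the
    remainder goes to test.  The same seed reproduces the split exactly.
    """
    if not 0.5 <= ratio <= 0.9:
        raise ValueError(f"ratio must be in [0.5, 0.9], got {ratio}")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects")
        n_train = _round_half_up(ratio * len(ids))
        n_train = min(max(n_train, 1), len(ids) - 1)  # keep both sides nonempty
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    # keep the original subject order for reproducible downstream frames
    order = {sid: i for i, sid in enumerate(labels.index)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return SplitSpec(train_ids=train_ids, test_ids=test_ids, ratio=ratio,
                     seed=seed)


@dataclass
class FittedModel:
    """Intercept and per-region log-odds coefficients over standardized inputs."""

    intercept: float
    coefficients: dict[int, float]
    covariate_coefficients: dict[str, float]
    feature_scaling: dict[str, tuple[float, float]]  # name -> (center, scale)
    selected_region_ids: list[int]
    penalty: float = 0.0
    converged: bool = True

    @property
    def feature_names(self) -> list[str]:
        return [str(r) for r in self.selected_region_ids] + list(
            self.covariate_coefficients)

    def _beta(self) -> np.ndarray:
        return np.array([self.coefficients[r] for r in self.selected_region_ids]
                        + list(self.covariate_coefficients.values()))

    def design(self, features: FeatureTable) -> np.ndarray:
        """Standardized design matrix (regions then covariates) for prediction."""
        cols = []
        for name in self.feature_names:
            if name in COVARIATE_NAMES:
                raw = features.covariates[name].to_numpy(dtype=float)
            else:
                rid = int(name)
                if rid not in features.counts.columns:
                    raise KeyError(f"feature table lacks selected region {rid}")
                raw = features.counts[rid].to_numpy(dtype=float)
            center, scale = self.feature_scaling[name]
            cols.append((raw - center) / scale)
        return np.column_stack(cols)

    def predict_proba(self, features: FeatureTable) -> pd.Series:
        z = self.intercept + self.design(features) @ self._beta()
        return pd.Series(expit(z), index=features.counts.index, name="p")

    def predict(self, features: FeatureTable) -> pd.Series:
        """Hard labels at the fixed p >= 0.5 decision threshold (ties -> case)."""
        return (self.predict_proba(features) >= 0.5).astype(int)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": {str(k): v for k, v in self.coefficients.items()},
            "covariate_coefficients": dict(self.covariate_coefficients),
            "feature_scaling": {k: list(v) for k, v in self.feature_scaling.items()},
            "selected_region_ids": list(self.selected_region_ids),
            "penalty": self.penalty,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            intercept=d["intercept"],
            coefficients={int(k): v for k, v in d["coefficients"].items()},
            covariate_coefficients=dict(d["covariate_coefficients"]),
            feature_scaling={k: (v[0], v[1]) for k, v in d["feature_scaling"].items()},
            selected_region_ids=[int(r) for r in d["selected_region_ids"]],
            penalty=d.get("penalty", 0.0),
            converged=d.get("converged", True),
        )


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns by their mean and SD; zero-variance columns get scale 1."""
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


def _nll(beta: np.ndarray, X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    z = beta[0] + X @ beta[1:]
    # log(1 + exp(-s z)) with s = +-1, numerically safe
    s = 2.0 * y - 1.0
    val = np.logaddexp(0.0, -s * z).mean()
    return val + 0.5 * alpha * float(beta[1:] @ beta[1:])


def newton_logistic(X: np.ndarray, y: np.ndarray, alpha: float,
                    gtol: float = 1e-8, maxiter: int = 100) -> tuple[np.ndarray, bool, float]:
    """Damped Newton maximizer of the ridge-penalized mean log-likelihood.

    Returns (beta with intercept first, converged flag, final gradient norm).
    The intercept is never penalized.
    """
    n, d = X.shape
    beta = np.zeros(d + 1)
    Xi = np.column_stack([np.ones(n), X])
    gnorm = np.inf
    for _ in range(maxiter):
        z = Xi @ beta
        p = expit(z)
        g = Xi.T @ (p - y) / n
        g[1:] += alpha * beta[1:]
        gnorm = float(np.max(np.abs(g)))
        if gnorm < gtol:
            return beta, True, gnorm
        w = p * (1.0 - p)
        H = (Xi * w[:, None]).T @ Xi / n
        H[1:, 1:] += alpha * np.eye(d)
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g
        # backtracking line search on the penalized objective
        f0 = _nll(beta, X, y, alpha)
        t, slope = 1.0, float(g @ step)
        while t > 1e-8:
            cand = beta - t * step
            if _nll(cand, X, y, alpha) <= f0 - 1e-4 * t * slope:
                beta = cand
                break
            t *= 0.5
        else:
            return beta, gnorm < 1e-4, gnorm
    return beta, gnorm < gtol, gnorm


def sgd_logistic(X: np.ndarray, y: np.ndarray, alpha: float, seed: int = 0,
                 epochs: int = 400, lr0: float = 0.5) -> np.ndarray:
    """Seeded per-sample stochastic gradient descent on the same objective."""
    rng = np.random.default_rng(seed)
    n, d = X.shape
    beta = np.zeros(d + 1)
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            step += 1
            lr = lr0 / (1.0 + step / (10.0 * n))
            z = beta[0] + X[i] @ beta[1:]
            r = expit(z) - y[i]
            beta[0] -= lr * r
            beta[1:] -= lr * (r * X[i] + alpha * beta[1:])
    return beta


def fit_logistic(train_features: FeatureTable, train_labels: pd.Series,
                 selected_region_ids: list[int] | None = None,
                 covariates: bool = True,
                 penalty: float | None = None, seed: int = 0,
                 method: str = "newton", gtol: float = 1e-8,
                 maxiter: int = 100) -> FittedModel:
    """Fit the logit model on training rows over the selected regions.

    ``penalty`` is the ridge strength alpha in the objective
    mean(-loglik) + (alpha/2)||b||^2 (intercept unpenalized); the default is
    1/n_train.  Standardization centers/scales are computed from the training
    rows only and stored with the model.  ``method='sgd'`` swaps in the seeded
    stochastic-gradient optimizer.
    """
    if selected_region_ids is None:
        selected_region_ids = list(train_features.counts.columns)
    y = pd.Series(train_labels).loc[train_features.counts.index].to_numpy(dtype=float)
    n = len(y)
    if penalty is None:
        penalty = 1.0 / n
    if penalty < 0:
        raise ValueError("penalty must be >= 0")

    names = [str(r) for r in selected_region_ids]
    Xr = train_features.counts[list(selected_region_ids)].to_numpy(dtype=float)
    if covariates:
        Xc = train_features.covariates[list(COVARIATE_NAMES)].to_numpy(dtype=float)
        Xr = np.column_stack([Xr, Xc])
        names += list(COVARIATE_NAMES)
    Xs, center, scale = standardize_columns(Xr)

    if method == "newton":
        beta, converged, gnorm = newton_logistic(Xs, y, penalty, gtol=gtol,
                                                 maxiter=maxiter)
        if not converged:
            if penalty == 0.0:
                warnings.warn(
                    "apparent separation with zero penalty; refitting with "
                    "fallback ridge 1/n to keep coefficients finite")
                penalty = 1.0 / n
                beta, converged, gnorm = newton_logistic(Xs, y, penalty,
                                                         gtol=gtol,
                                                         maxiter=maxiter)
            if not converged:
                raise ConvergenceError(
                    f"logistic fit did not converge in {maxiter} iterations "
                    f"(final gradient norm {gnorm:.3e})")
    elif method == "sgd":
        beta = sgd_logistic(Xs, y, penalty, seed=seed)
        converged = True
    else:
        raise ValueError(f"unknown method {method!r}")

    k = len(selected_region_ids)
    return FittedModel(
        intercept=float(beta[0]),
        coefficients={int(r): float(b) for r, b in zip(selected_region_ids,
                                                       beta[1:1 + k])},
        covariate_coefficients={nm: float(b) for nm, b in
                                zip(names[k:], beta[1 + k:])},
        feature_scaling={nm: (float(c), float(s)) for nm, c, s in
                         zip(names, center, scale)},
        selected_region_ids=[int(r) for r in selected_region_ids],
        penalty=float(penalty),
        converged=bool(converged),
    )


def predict_probability(model: FittedModel, feature_row: dict) -> float:
    """Evaluate the logit equation for one subject given raw feature values.

    ``feature_row`` maps region id (int) and covariate name to raw values;
    a missing selected feature raises KeyError naming it.
    """
    z = model.intercept
    for name in model.feature_names:
        key: object = int(name) if name not in COVARIATE_NAMES else name
        if key not in feature_row:
            raise KeyError(f"feature_row is missing selected feature {key!r}")
        center, scale = model.feature_scaling[name]
        beta = (model.coefficients[key] if isinstance(key, int)
                else model.covariate_coefficients[key])
        z += beta * (float(feature_row[key]) - center) / scale
    return float(expit(z))


def _accuracy(model: FittedModel, features: FeatureTable,
              labels: pd.Series) -> float:
    pred = model.predict(features)
    return float((pred.to_numpy() == pd.Series(labels).loc[pred.index]
                  .to_numpy()).mean())


def ratio_sweep(features: FeatureTable, labels: pd.Series,
                ratios=(0.5, 0.6, 0.7, 0.8, 0.9), seeds=(0, 1, 2, 3, 4),
                rfe_target: int | None = None, penalty: float | None = None,
                overfit_margin: float = 0.25) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline (RFE on train, fit, test evaluation) per (ratio, seed).

    Returns a per-run frame and a per-ratio summary flagging ratios whose mean
    train-test accuracy gap exceeds ``overfit_margin`` (an overfitting sign,
    e.g. near-perfect training fits that collapse on small test sets).
    """
    from .screen import rfe_select  # local import to avoid a cycle

    ratios = list(ratios)
    seeds = list(seeds)
    if len(ratios) < 2 or len(seeds) < 2:
        raise ValueError("need at least 2 ratios and 2 seeds")
    rows = []
    for ratio in ratios:
        for seed in seeds:
            split = stratified_split(labels, ratio=ratio, seed=seed)
            train = features.subset(split.train_ids)
            test = features.subset(split.test_ids)
            target = rfe_target or max(1, len(features.region_ids) // 2)
            sel = rfe_select(train, labels.loc[split.train_ids], target,
                             seed=seed, penalty=penalty)
            mdl = fit_logistic(train, labels.loc[split.train_ids],
                               selected_region_ids=sel.selected_region_ids,
                               penalty=penalty, seed=seed)
            rows.append({
                "ratio": ratio, "seed": seed,
                "n_train": len(split.train_ids), "n_test": len(split.test_ids),
                "train_accuracy": _accuracy(mdl, train, labels),
                "test_accuracy": _accuracy(mdl, test, labels),
            })
    per_run = pd.DataFrame(rows)
    summary = (per_run.groupby("ratio")
               .agg(mean_test_accuracy=("test_accuracy", "mean"),
                    sd_test_accuracy=("test_accuracy", "std"),
                    mean_train_accuracy=("train_accuracy", "mean"))
               .reset_index())
    summary["gap"] = summary["mean_train_accuracy"] - summary["mean_test_accuracy"]
    summary["overfit_flag"] = summary["gap"] > overfit_margin
    return per_run, summary
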