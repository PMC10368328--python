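"""Classification models with repeated random subsampling cross-validation.

Each model is an L2-regularized logistic regression on features standardized
with training-set statistics.  Metric distributions come from repeated
random 70:30 train/test splits (500 by default): every iteration draws an
independent split, standardizes on the training portion only, fits, and
scores the untouched test portion — so no test information leaks into
training.  Coefficients for feature ranking are extracted from a single fit
on the entire dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from . import _engine
from .encoding import FeatureMatrix

METRICS = ("accuracy", "auroc", "precision", "recall", "f1")

# seed-stream context tags, so every pipeline stage has its own split stream
CTX_V1 = 1
CTX_V2 = 2
CTX_RFE = 3
CTX_PERMUTE = 4
CTX_COMPLEX = 5


@dataclass
class CVConfig:
    """Knobs of the CV engine.

    ``n_iterations`` random ``test_fraction`` hold-out splits per evaluation;
    ``C`` is the inverse L2 penalty strength on standardized features (1.0,
    the conventional default, keeps coefficients finite even on separable
    data so magnitude ranking stays well-defined).
    """

    n_iterations: int = 500
    test_fraction: float = 0.30
    C: float = 1.0
    max_solver_iterations: int = 2000
    tolerance: float = 1e-5
    master_seed: int = 0
    stratified: bool = False
    positive_label: str | None = None
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class FittedModel:
    """A single standardized logistic fit (coefficients in standardized space)."""

    coefficients: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Xs @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class CVSummary:
    """Per-iteration metrics plus everything needed for group-level analyses."""

    metrics: dict[str, np.ndarray]
    test_mask: np.ndarray = field(repr=False)   # (M, n) bool
    predictions: np.ndarray = field(repr=False)  # (M, n) bool (class-1 predicted)
    sample_ids: list[str] | None = None
    seed_context: tuple[int, ...] = ()
    mean_coef_abs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_iterations(self) -> int:
        return len(self.metrics["accuracy"])

    def mean(self, metric: str) -> float:
        return float(np.mean(self.metrics[metric]))

    def means(self) -> dict[str, float]:
        return {m: self.mean(m) for m in METRICS}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({m: self.metrics[m] for m in METRICS})
        df.insert(0, "iteration", np.arange(len(df)))
        return df

    def means_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.means(), fh, indent=1, sort_keys=True)


def _as_xy(X, y, config: CVConfig):
    if isinstance(X, FeatureMatrix):
        mat = np.asarray(X.values, dtype=np.float64)
        sample_ids = list(X.sample_ids)
        if y is None:
            yvec, _ = X.y(config.positive_label)
        else:
            yvec = np.asarray(y)
    else:
        mat = np.asarray(X, dtype=np.float64)
        sample_ids = None
        if y is None:
            raise ValueError("y is required when X is a plain array")
        yvec = np.asarray(y)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("X must be 2-D with >= 1 feature")
    yvec = yvec.astype(np.int8)
    if set(np.unique(yvec)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(yvec)) < 2:
        raise ValueError("both classes must be present in y")
    return mat, yvec, sample_ids


def fit_standardized_logistic(X, y=None, config: CVConfig | None = None) -> FittedModel:
    """One L2 logistic fit on standardized features (scikit-learn backed)."""
    config = config or CVConfig()
    mat, yvec, _ = _as_xy(X, y, config)
    scaler = StandardScaler().fit(mat)
    Xs = scaler.transform(mat)
    clf = LogisticRegression(
        C=config.C,
        solver="lbfgs",
        max_iter=config.max_solver_iterations,
        tol=min(config.tolerance, 1e-7),
    ).fit(Xs, yvec)
    return FittedModel(
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        center=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
    )


def full_data_coefficients(X, y=None, config: CVConfig | None = None) -> np.ndarray:
    """Signed standardized coefficients from one fit on all samples.

    This is the coefficient vector feature ranking reads: the entire dataset,
    not a split, informs it.
    """
    return fit_standardized_logistic(X, y, config).coefficients


def repeated_subsample_cv(
    X,
    y=None,
    config: CVConfig | None = None,
    seed_context: tuple[int, ...] = (CTX_V1, 0),
    collect_coefficients: bool = False,
    _warm=None,
) -> CVSummary:
    """Estimate metric distributions over repeated random train/test splits.

    Every iteration is independent: a fresh seeded split, standardization
    fit on the training portion only, one logistic fit, and all five metrics
    on the held-out portion.  The summary is a pure function of
    ``(X, y, config, seed_context)``.
    """
    config = config or CVConfig()
    mat, yvec, sample_ids = _as_xy(X, y, config)
    ss = _engine.iteration_seed_sequence(config.master_seed, *seed_context)
    train_mask = _engine.draw_splits(
        mat.shape[0], yvec, config.n_iterations, config.test_fraction, ss,
        stratified=config.stratified,
    )
    w0 = b0 = None
    if _warm is not None:
        w0, b0 = _warm
    W, b, mu, sigma = _engine.batch_fit(
        mat, yvec, train_mask,
        C=config.C, tol=config.tolerance,
        max_iter=config.max_solver_iterations, w0=w0, b0=b0,
    )
    prob = _engine.batch_probabilities(mat, W, b, mu, sigma)
    metrics, pred, test_mask = _engine.batch_metrics(prob, yvec, train_mask)
    summary = CVSummary(
        metrics=metrics,
        test_mask=test_mask,
        predictions=pred,
        sample_ids=sample_ids,
        seed_context=(config.master_seed, *seed_context),
        mean_coef_abs=np.abs(W).mean(axis=0) if collect_coefficients else None,
    )
    if _warm is not None or collect_coefficients:
        summary._fit_state = (W, b)  # type: ignore[attr-defined]
    return summary


def permuted_label_cv(
    X,
    y=None,
    config: CVConfig | None = None,
    seed_context: tuple[int, ...] = (CTX_V1, 0),
    mode: str = "per-iteration",
) -> CVSummary:
    """Null-model CV: randomized labels, everything else identical.

    Class counts are preserved exactly; split seeds, standardization,
    fitting and scoring match the true-label run, so the comparison
    isolates the label-feature association.

    ``mode="per-iteration"`` (default) draws an independent seeded label
    permutation for every CV iteration, so the null metric distribution
    averages over labelings rather than being conditioned on one arbitrary
    permutation — a single fixed permutation has its own dataset-specific
    achievable accuracy, which a many-iteration t-test will resolve as a
    spurious "signal".  ``mode="single"`` keeps one permutation for the
    whole run.
    """
    if mode not in ("per-iteration", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or CVConfig()
    mat, yvec, sample_ids = _as_xy(X, y, config)
    ss_perm = _engine.iteration_seed_sequence(
        config.master_seed, CTX_PERMUTE, *seed_context
    )
    if mode == "single":
        y_used = np.random.default_rng(ss_perm).permutation(yvec)
    else:
        children = ss_perm.spawn(config.n_iterations)
        y_used = np.stack(
            [np.random.default_rng(c).permutation(yvec) for c in children]
        )
    ss = _engine.iteration_seed_sequence(config.master_seed, *seed_context)
    train_mask = _engine.draw_splits(
        mat.shape[0], y_used, config.n_iterations, config.test_fraction, ss,
        stratified=config.stratified,
    )
    W, b, mu, sigma = _engine.batch_fit(
        mat, y_used, train_mask,
        C=config.C, tol=config.tolerance,
        max_iter=config.max_solver_iterations,
    )
    prob = _engine.batch_probabilities(mat, W, b, mu, sigma)
    metrics, pred, test_mask = _engine.batch_metrics(prob, y_used, train_mask)
    return CVSummary(
        metrics=metrics,
        test_mask=test_mask,
        predictions=pred,
        sample_ids=sample_ids,
        seed_context=(config.master_seed, CTX_PERMUTE, *seed_context),
    )


@dataclass
class ComparisonResult:
    """Two-sample t comparison of per-iteration metric distributions."""

    t_statistic: float
    p_raw: float
    p_adjusted: float
    family_size: int
    alpha: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "t": self.t_statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "m": self.family_size,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def compare_metric_distributions(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.001,
    m: int = 1,
    welch: bool = False,
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Classical Student's t-test with Bonferroni adjustment.

    Equal-variance by default (Welch behind a flag); ``alternative`` may be
    ``"two-sided"`` (default), ``"greater"`` (a exceeds b) or ``"less"`` for
    directional claims such as "significantly higher accuracy than the
    randomized-label model".  Two zero-variance samples with equal means
    compare as p = 1 by convention.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("metric samples must be nonempty")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t = np.inf if np.mean(a) > np.mean(b) else -np.inf
            gap_matches = (t > 0) if alternative == "greater" else (t < 0)
            p = 0.0 if alternative == "two-sided" or gap_matches else 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
        t, p = float(t), float(p)
    p_adj = min(1.0, m * p)
    return ComparisonResult(t, p, p_adj, m, alpha, p_adj < alpha)


def misclassification_by_group(
    cv: CVSummary, groups: Sequence[str], y: Sequence[int]
) -> pd.DataFrame:
    """Pooled per-group misclassification rates over all test-set appearances.

    For each group: (misclassified test appearances) / (total test
    appearances) summed over all iterations.  A group never drawn into a
    test set gets a NaN rate (undefined), not zero.
    """
    y = np.asarray(y).astype(bool)
    wrong = (cv.predictions != y[None, :]) & cv.test_mask
    appearances = cv.test_mask.sum(axis=0)
    errors = wrong.sum(axis=0)
    df = pd.DataFrame({"group": list(groups), "appearances": appearances, "errors": errors})
    agg = df.groupby("group", sort=True).sum().reset_index()
    agg["rate"] = np.where(
        agg["appearances"] > 0, agg["errors"] / agg["appearances"], np.nan
    )
    return agg


def majority_class_fraction(y: Sequence[int]) -> float:
    y = np.asarray(y)
    return float(max(np.mean(y), 1.0 - np.mean(y)))
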