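"""Vectorized multi-split L2 logistic regression engine.

Repeated random subsampling CV fits hundreds of independent logistic
regressions per feature subset; recursive feature elimination multiplies
that by the number of columns.  This module solves all splits of one step
as a single block-separable optimization:

    min_{W, b}  0.5 * sum_m ||W_m||^2
              + C * sum_m sum_{i in train_m} log(1 + exp(-t_im))

with t_im = y±_i * ((x_i - mu_m) / sigma_m . W_m + b_m), i.e. exactly the
objective scikit-learn's ``LogisticRegression(penalty='l2')`` minimizes on
features standardized by each split's own training statistics (intercept
unpenalized, biased-variance scaling).  Because standardization is affine,
the per-split score is computed as one BLAS matrix product on the *raw*
matrix, X @ (W_m / sigma_m), plus a per-split offset — no per-split copies
of X are made.  The stacked problem is minimized with warm-startable
L-BFGS; block separability makes the joint optimum identical to the
per-split optima.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_VAR_FLOOR = 1e-12


class SplitError(RuntimeError):
    """No valid train/test split could be drawn (class missing everywhere)."""


def iteration_seed_sequence(master_seed: int, *context: int) -> np.random.SeedSequence:
    """Deterministic seed stream for one CV context (stage, RFE step, ...)."""
    return np.random.SeedSequence([int(master_seed), *map(int, context)])


def draw_splits(
    n: int,
    y: np.ndarray,
    n_iterations: int,
    test_fraction: float,
    seed_sequence: np.random.SeedSequence,
    stratified: bool = False,
    max_redraws: int = 100,
) -> np.ndarray:
    """Draw ``n_iterations`` random train/test partitions as a boolean train mask.

    A split whose training or test portion lacks one of the two classes is
    redrawn (with the same per-iteration generator), so metrics that need
    both classes stay defined.  Splits depend only on the seed stream, ``n``
    and the labels — never on feature values — so two runs that share seeds
    share splits exactly.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    y = np.asarray(y)
    per_iteration_labels = y.ndim == 2
    classes = np.unique(y)
    train_mask = np.zeros((n_iterations, n), dtype=bool)
    children = seed_sequence.spawn(n_iterations)
    for m, child in enumerate(children):
        ym = y[m] if per_iteration_labels else y
        rng = np.random.default_rng(child)
        for _ in range(max_redraws):
            if stratified:
                test_idx = _stratified_test(ym, classes, n_test, rng)
            else:
                test_idx = rng.permutation(n)[:n_test]
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            if len(classes) < 2:
                break
            if (len(np.unique(ym[mask])) == 2) and (len(np.unique(ym[~mask])) == 2):
                break
        else:
            raise SplitError(
                f"could not draw a split with both classes in train and test "
                f"(n={n}, n_test={n_test})"
            )
        train_mask[m] = mask
    return train_mask


def _stratified_test(y, classes, n_test, rng):
    parts = []
    n = len(y)
    for c in classes:
        idx = np.flatnonzero(y == c)
        k = int(round(n_test * len(idx) / n))
        k = min(max(k, 1), len(idx) - 1)
        parts.append(rng.permutation(idx)[:k])
    return np.concatenate(parts)


def standardization_stats(X: np.ndarray, train_mask: np.ndarray):
    """Per-split training mean and scale (biased std; constant columns -> 1)."""
    tm = train_mask.astype(np.float64)
    ntr = tm.sum(axis=1)
    mu = (tm @ X) / ntr[:, None]
    ex2 = (tm @ (X * X)) / ntr[:, None]
    var = np.clip(ex2 - mu * mu, 0.0, None)
    sigma = np.sqrt(var)
    sigma[var < _VAR_FLOOR] = 1.0
    return mu, sigma


def batch_fit(
    X: np.ndarray,
    y: np.ndarray,
    train_mask: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 2000,
    w0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
):
    """Fit all splits' standardized logistic regressions at once.

    Returns ``(W, b, mu, sigma)``: coefficients in standardized-feature
    space (one row per split), intercepts, and the standardization stats.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    M, n = train_mask.shape
    p = X.shape[1]
    mu, sigma = standardization_stats(X, train_mask)
    tmf = train_mask.T.astype(np.float64)  # (n, M)
    # labels may vary per split (permutation nulls): (n,) or (M, n) -> (n, M)
    yc = y.T if y.ndim == 2 else y[:, None]
    ysign = 2.0 * yc - 1.0

    def objective(theta):
        W = theta[: M * p].reshape(M, p)
        b = theta[M * p :]
        V = W / sigma                                  # (M, p)
        logit = X @ V.T                                # (n, M)  BLAS
        logit += b - np.einsum("mp,mp->m", mu, V)
        t = ysign * logit
        loss = 0.5 * float(np.sum(W * W)) + C * float(np.sum(tmf * np.logaddexp(0.0, -t)))
        r = tmf * (expit(logit) - yc)                  # (n, M)
        r *= C
        g1 = X.T @ r                                   # (p, M)  BLAS
        rs = r.sum(axis=0)                             # (M,)
        gW = (g1.T - mu * rs[:, None]) / sigma
        gW += W
        return loss, np.concatenate([gW.ravel(), rs])

    if w0 is None:
        x0 = np.zeros(M * p + M)
    else:
        x0 = np.concatenate(
            [np.asarray(w0, dtype=np.float64).ravel(),
             np.zeros(M) if b0 is None else np.asarray(b0, dtype=np.float64)]
        )
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol, "maxcor": 15},
    )
    theta = res.x
    W = theta[: M * p].reshape(M, p)
    b = theta[M * p :]
    return W, b, mu, sigma


def batch_probabilities(X, W, b, mu, sigma):
    """Predicted class-1 probabilities for every sample under every split's model."""
    V = W / sigma
    logit = X @ V.T + (b - np.einsum("mp,mp->m", mu, V))
    return expit(logit)  # (n, M)


def batch_metrics(prob: np.ndarray, y: np.ndarray, train_mask: np.ndarray):
    """Held-out accuracy, AUROC, precision, recall, F1 per split.

    Predictions threshold probability at 0.5 (>= 0.5 -> positive); AUROC uses
    midranks so probability ties contribute 1/2.  Precision and F1 are 0 when
    undefined (no predicted positives), the usual zero-division convention.
    """
    n, M = prob.shape
    test_mask = ~train_mask  # (M, n)
    pred = (prob >= 0.5).T   # (M, n)
    y = np.asarray(y)
    ybool = y.astype(bool) if y.ndim == 2 else y.astype(bool)[None, :]

    n_test = test_mask.sum(axis=1).astype(np.float64)
    correct = (pred == ybool) & test_mask
    accuracy = correct.sum(axis=1) / n_test

    tp = (pred & ybool & test_mask).sum(axis=1).astype(np.float64)
    fp = (pred & ~ybool & test_mask).sum(axis=1).astype(np.float64)
    fn = (~pred & ybool & test_mask).sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )

    auroc = np.empty(M)
    from scipy.stats import rankdata

    for m in range(M):
        tmask = test_mask[m]
        pt = prob[tmask, m]
        yt = ybool[m if ybool.shape[0] == M else 0, tmask]
        npos = int(yt.sum())
        nneg = int((~yt).sum())
        if npos == 0 or nneg == 0:
            auroc[m] = np.nan
            continue
        ranks = rankdata(pt)
        auroc[m] = (ranks[yt].sum() - npos * (npos + 1) / 2.0) / (npos * nneg)

    return {
        "accuracy": accuracy,
        "auroc": auroc,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }, pred, test_mask
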