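"""Feature ranking and recursive feature elimination with cross-validation.

Two selection stages:

* the ten strongest features — the largest absolute coefficients of one
  logistic fit on the entire dataset (``strongest_k_features``);
* RFE-CV (``rfe_cv``) — starting from a feature set (canonically the full
  alignment), repeatedly evaluate by subsampling CV, eliminate the feature
  with the lowest mean absolute coefficient across the iteration's fits, and
  continue down to ``min_features`` regardless of accuracy plateaus.  The
  best-scoring step with at most ten active features is the "optimal"
  feature set; the in-zone flag marks optima whose mean accuracy reaches the
  0.9 floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _engine
from .cv import CTX_RFE, CVConfig, CVSummary, METRICS
from .encoding import FeatureMatrix

FeatureId = tuple[str, int]  # (gene, 1-based alignment position)


class SelectionError(ValueError):
    pass


@dataclass
class FeatureSet:
    """An ordered set of (gene, ap) feature identifiers with provenance."""

    ids: list[FeatureId]
    provenance: str = "v2"

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise SelectionError("duplicate feature ids")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g, _ in self.ids:
            seen.setdefault(g, None)
        return list(seen)

    def aps(self) -> list[int]:
        return [ap for _, ap in self.ids]

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


def strongest_k_features(
    coefs: np.ndarray, feature_ids: Sequence[FeatureId], k: int = 10
) -> FeatureSet:
    """The k features with largest |coefficient|; ties go to the lower ap.

    Returned in source (ap) order, as reports list them.  If k is at least
    the feature count, every feature is returned.
    """
    coefs = np.asarray(coefs, dtype=float)
    if coefs.size == 0:
        raise SelectionError("empty coefficient vector")
    if k < 1:
        raise SelectionError("k must be >= 1")
    if len(coefs) != len(feature_ids):
        raise SelectionError("coefficients and feature ids differ in length")
    order = sorted(
        range(len(coefs)),
        key=lambda i: (-abs(coefs[i]), feature_ids[i]),
    )
    chosen = sorted(order[: min(k, len(coefs))])
    return FeatureSet([feature_ids[i] for i in chosen], provenance="v2")


@dataclass
class RFEStep:
    """One elimination step: the active set, its CV means, and what was cut."""

    step_index: int
    active: list[FeatureId]
    means: dict[str, float]
    eliminated: FeatureId | None
    eliminated_value: float | None
    accuracy_sample: np.ndarray = field(repr=False)
    auroc_sample: np.ndarray = field(repr=False)
    summary: CVSummary | None = field(default=None, repr=False)


@dataclass
class OptimalResult:
    feature_set: FeatureSet
    means: dict[str, float]
    in_zone: bool
    step_index: int
    accuracy_sample: np.ndarray = field(repr=False)
    summary: CVSummary | None = field(default=None, repr=False)


@dataclass
class RFEPath:
    """Full elimination trajectory, largest feature set first."""

    gene_name: str
    steps: list[RFEStep]

    def step_sizes(self) -> list[int]:
        return [len(s.active) for s in self.steps]

    def elimination_order(self) -> list[FeatureId]:
        return [s.eliminated for s in self.steps if s.eliminated is not None]

    def to_json(self, path) -> None:
        payload = {
            "gene": self.gene_name,
            "steps": [
                {
                    "step": s.step_index,
                    "n_features": len(s.active),
                    "active": [[g, int(ap)] for g, ap in s.active],
                    "means": {k: round(v, 6) for k, v in s.means.items()},
                    "eliminated": None if s.eliminated is None
                    else [s.eliminated[0], int(s.eliminated[1])],
                    "criterion_value": None if s.eliminated_value is None
                    else round(float(s.eliminated_value), 8),
                }
                for s in self.steps
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def rfe_cv(
    fm: FeatureMatrix,
    y=None,
    config: CVConfig | None = None,
    min_features: int = 2,
    criterion: str = "mean-abs-coef",
    retain_summaries_below: int = 12,
    resplit_per_step: bool = False,
) -> RFEPath:
    """Recursive feature elimination driven by subsampling-CV coefficients.

    Per step: run the full repeated-subsampling CV on the active features,
    record metric means, compute each feature's mean absolute standardized
    coefficient across the step's fits, and eliminate the minimum (ties:
    the higher alignment position goes).  The path always continues down to
    ``min_features`` — there is no early stop at an accuracy plateau, so
    small feature combinations are always evaluated.

    ``criterion="most-often-weakest"`` instead eliminates the feature most
    frequently ranked weakest across the step's individual fits.

    By default every step reuses one fixed set of seeded splits, so
    step-to-step metric differences are paired (attributable to the removed
    feature, not to split noise) and paths for different genes or encodings
    of the same data share their CV splits exactly;
    ``resplit_per_step=True`` draws fresh seeded splits at each step
    instead.  Full CV summaries (with per-iteration predictions) are
    retained only for steps with fewer than ``retain_summaries_below``
    features to bound memory.
    """
    config = config or CVConfig()
    if min_features < 1:
        raise SelectionError("min_features must be >= 1")
    if criterion not in ("mean-abs-coef", "most-often-weakest"):
        raise SelectionError(f"unknown criterion {criterion!r}")
    if fm.n_features < min_features:
        raise SelectionError(
            f"{fm.n_features} features < min_features={min_features}"
        )
    if y is None:
        yvec, _ = fm.y(config.positive_label)
    else:
        yvec = np.asarray(y).astype(np.int8)
    X_all = np.asarray(fm.values, dtype=np.float64)
    ids_all = fm.feature_ids()
    active = list(range(fm.n_features))
    gene = fm.column_meta["gene"].iloc[0] if fm.n_features else ""

    steps: list[RFEStep] = []
    W_warm = None
    b_warm = None
    step_index = 0
    shared_mask = None
    while True:
        X = X_all[:, active]
        if resplit_per_step or shared_mask is None:
            seed_step = step_index if resplit_per_step else 0
            ss = _engine.iteration_seed_sequence(config.master_seed, CTX_RFE, seed_step)
            shared_mask = _engine.draw_splits(
                X.shape[0], yvec, config.n_iterations, config.test_fraction, ss,
                stratified=config.stratified,
            )
        train_mask = shared_mask
        W, b, mu, sigma = _engine.batch_fit(
            X, yvec, train_mask,
            C=config.C, tol=config.tolerance,
            max_iter=config.max_solver_iterations,
            w0=W_warm, b0=b_warm,
        )
        prob = _engine.batch_probabilities(X, W, b, mu, sigma)
        metrics, pred, test_mask = _engine.batch_metrics(prob, yvec, train_mask)
        means = {m: float(np.mean(metrics[m])) for m in METRICS}

        summary = None
        if len(active) < retain_summaries_below:
            summary = CVSummary(
                metrics=metrics,
                test_mask=test_mask,
                predictions=pred,
                sample_ids=list(fm.sample_ids),
                seed_context=(config.master_seed, CTX_RFE,
                              step_index if resplit_per_step else 0),
                mean_coef_abs=np.abs(W).mean(axis=0),
            )

        if len(active) <= min_features:
            steps.append(
                RFEStep(step_index, [ids_all[i] for i in active], means,
                        None, None, metrics["accuracy"], metrics["auroc"], summary)
            )
            break

        if criterion == "mean-abs-coef":
            score = np.abs(W).mean(axis=0)
        else:
            weakest = np.abs(W).argmin(axis=1)
            score = -np.bincount(weakest, minlength=len(active)).astype(float)
            # most negative = most often weakest; min of score eliminates it
        # eliminate min score; ties -> higher alignment position
        best = min(
            range(len(active)),
            key=lambda j: (score[j], -ids_all[active[j]][1], ids_all[active[j]][0]),
        )
        eliminated_id = ids_all[active[best]]
        steps.append(
            RFEStep(step_index, [ids_all[i] for i in active], means,
                    eliminated_id, float(score[best]) if criterion == "mean-abs-coef"
                    else float(-score[best]),
                    metrics["accuracy"], metrics["auroc"], summary)
        )
        del active[best]
        W_warm = np.delete(W, best, axis=1)
        b_warm = b
        step_index += 1

    return RFEPath(gene, steps)


def optimal_subset(
    path: RFEPath,
    max_features: int = 10,
    accuracy_floor: float = 0.9,
) -> OptimalResult:
    """Best-scoring step with at most ``max_features`` active features.

    Ties on mean accuracy prefer fewer features, then higher mean AUROC.
    The in-zone flag is true when the chosen step's mean accuracy reaches
    the accuracy floor (the "optimal zone" of ten-or-fewer features at >= 0.9
    accuracy); when no step reaches it the best of the bad is still returned,
    flagged out of zone.
    """
    if not path.steps:
        raise SelectionError("empty RFE path")
    candidates = [s for s in path.steps if len(s.active) <= max_features]
    if not candidates:
        raise SelectionError(
            f"no step with <= {max_features} features "
            f"(smallest step has {min(path.step_sizes())})"
        )
    best = max(
        candidates,
        key=lambda s: (s.means["accuracy"], -len(s.active), s.means["auroc"]),
    )
    return OptimalResult(
        feature_set=FeatureSet(list(best.active), provenance="v3"),
        means=dict(best.means),
        in_zone=best.means["accuracy"] >= accuracy_floor,
        step_index=best.step_index,
        accuracy_sample=best.accuracy_sample,
        summary=best.summary,
    )
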