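"""Feature ranking, RFE-CV paths and optimal-subset extraction."""

import numpy as np
import pytest

from convscreen import (
    CVConfig,
    FeatureSet,
    SelectionError,
    encode_alignment,
    full_data_coefficients,
    optimal_subset,
    rfe_cv,
    strongest_k_features,
)
from convscreen.selection import RFEPath, RFEStep


def _step(idx, active, acc, auroc=0.5, eliminated=None):
    return RFEStep(
        step_index=idx,
        active=[("g", ap) for ap in active],
        means={"accuracy": acc, "auroc": auroc, "precision": 0.0,
               "recall": 0.0, "f1": 0.0},
        eliminated=None if eliminated is None else ("g", eliminated),
        eliminated_value=None if eliminated is None else 0.1,
        accuracy_sample=np.full(5, acc),
        auroc_sample=np.full(5, auroc),
    )


class TestStrongestK:
    def test_picks_largest_magnitudes_in_ap_order(self):
        ids = [("g", ap) for ap in (1, 2, 3, 4, 5)]
        coefs = [0.1, -2.0, 0.5, 1.5, -0.2]
        fs = strongest_k_features(coefs, ids, k=3)
        assert list(fs) == [("g", 2), ("g", 3), ("g", 4)]

    def test_magnitude_tie_goes_to_lower_ap(self):
        ids = [("g", ap) for ap in (1, 2, 3)]
        fs = strongest_k_features([1.0, -1.0, 1.0], ids, k=2)
        assert list(fs) == [("g", 1), ("g", 2)]

    def test_k_larger_than_p_returns_all(self):
        ids = [("g", 1), ("g", 2)]
        assert len(strongest_k_features([0.3, 0.1], ids, k=10)) == 2

    def test_errors(self):
        with pytest.raises(SelectionError):
            strongest_k_features([], [], k=1)
        with pytest.raises(SelectionError):
            strongest_k_features([1.0], [("g", 1)], k=0)
        with pytest.raises(SelectionError):
            strongest_k_features([1.0, 2.0], [("g", 1)], k=1)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SelectionError, match="duplicate"):
            FeatureSet([("g", 1), ("g", 1)])


class TestRFECV:
    def test_path_shrinks_by_one_to_min_features(self, random_xy, tiny_dataset):
        alignments, _ = tiny_dataset
        fm = encode_alignment(alignments["sigA"])
        path = rfe_cv(fm, config=CVConfig(n_iterations=10, master_seed=5),
                      min_features=2)
        assert path.step_sizes() == list(range(fm.n_features, 1, -1))
        assert path.steps[-1].eliminated is None
        # every eliminated feature leaves the next step's active set
        for prev, nxt in zip(path.steps, path.steps[1:]):
            assert set(prev.active) - set(nxt.active) == {prev.eliminated}

    def test_deterministic(self, tiny_dataset):
        alignments, _ = tiny_dataset
        fm = encode_alignment(alignments["noiseB"])
        config = CVConfig(n_iterations=10, master_seed=5)
        a = rfe_cv(fm, config=config)
        b = rfe_cv(fm, config=config)
        assert a.elimination_order() == b.elimination_order()
        for sa, sb in zip(a.steps, b.steps):
            assert sa.means == sb.means

    def test_recovers_planted_columns(self, tiny_dataset, fast_config):
        alignments, truth = tiny_dataset
        fm = encode_alignment(alignments["sigA"])
        path = rfe_cv(fm, config=fast_config)
        best = optimal_subset(path)
        planted = set(truth.planted_aps("sigA"))
        recovered = planted & {ap for _, ap in best.feature_set}
        assert len(recovered) >= 2  # high-penetrance signal survives RFE
        assert best.means["accuracy"] > 0.85

    def test_perfect_pair_reaches_accuracy_one(self):
        n = 40
        y = (np.arange(n) % 2).astype(np.int8)
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(n, 4)).astype(np.int16)
        X[:, 1] = y  # a single perfectly informative column
        from convscreen.encoding import FeatureMatrix
        import pandas as pd

        fm = FeatureMatrix(
            values=X,
            column_meta=pd.DataFrame({"gene": "g", "ap": [1, 2, 3, 4]}),
            sample_ids=[f"s{i}" for i in range(n)],
            labels=["C4" if v else "C3" for v in y],
        )
        path = rfe_cv(fm, config=CVConfig(n_iterations=15, master_seed=2))
        best = optimal_subset(path)
        assert ("g", 2) in list(best.feature_set)
        assert best.means["accuracy"] == 1.0
        assert best.in_zone

    def test_most_often_weakest_criterion_runs(self, tiny_dataset, fast_config):
        alignments, _ = tiny_dataset
        fm = encode_alignment(alignments["noiseB"])
        path = rfe_cv(fm, config=fast_config, criterion="most-often-weakest")
        assert path.step_sizes()[0] == fm.n_features

    def test_resplit_per_step_changes_path_metrics(self, tiny_dataset):
        alignments, _ = tiny_dataset
        fm = encode_alignment(alignments["noiseB"])
        config = CVConfig(n_iterations=10, master_seed=5)
        shared = rfe_cv(fm, config=config)
        fresh = rfe_cv(fm, config=config, resplit_per_step=True)
        accs_shared = [s.means["accuracy"] for s in shared.steps]
        accs_fresh = [s.means["accuracy"] for s in fresh.steps]
        assert accs_shared[0] == accs_fresh[0]  # step 0 shares the seed
        assert accs_shared[1:] != accs_fresh[1:]

    def test_errors(self, tiny_dataset, fast_config):
        alignments, _ = tiny_dataset
        fm = encode_alignment(alignments["noiseB"])
        with pytest.raises(SelectionError, match="min_features"):
            rfe_cv(fm, config=fast_config, min_features=0)
        with pytest.raises(SelectionError, match="criterion"):
            rfe_cv(fm, config=fast_config, criterion="coin-flip")
        with pytest.raises(SelectionError, match="min_features"):
            rfe_cv(fm.subset([0]), config=fast_config, min_features=2)

    def test_json_export(self, tiny_dataset, fast_config, tmp_path):
        import json

        alignments, _ = tiny_dataset
        fm = encode_alignment(alignments["noiseB"])
        path = rfe_cv(fm, config=fast_config)
        out = tmp_path / "path.json"
        path.to_json(out)
        payload = json.loads(out.read_text())
        assert payload["gene"] == "noiseB"
        assert len(payload["steps"]) == len(path.steps)


class TestOptimalSubset:
    def test_best_accuracy_within_budget(self):
        path = RFEPath("g", [
            _step(0, range(1, 13), 0.99, eliminated=12),   # too wide: ignored
            _step(1, range(1, 11), 0.91, eliminated=10),
            _step(2, range(1, 10), 0.95, eliminated=9),
            _step(3, range(1, 9), 0.93, eliminated=None),
        ])
        best = optimal_subset(path, max_features=10)
        assert best.step_index == 2
        assert best.in_zone

    def test_accuracy_tie_prefers_fewer_features(self):
        path = RFEPath("g", [
            _step(0, range(1, 6), 0.9, eliminated=5),
            _step(1, range(1, 5), 0.9, eliminated=None),
        ])
        assert optimal_subset(path).step_index == 1

    def test_full_tie_prefers_higher_auroc(self):
        path = RFEPath("g", [
            _step(0, range(1, 5), 0.9, auroc=0.97, eliminated=4),
            _step(1, range(1, 5), 0.9, auroc=0.91, eliminated=None),
        ])
        assert optimal_subset(path).step_index == 0

    def test_out_of_zone_flagged_not_raised(self):
        path = RFEPath("g", [_step(0, range(1, 4), 0.7, eliminated=None)])
        best = optimal_subset(path, accuracy_floor=0.9)
        assert not best.in_zone
        assert best.means["accuracy"] == 0.7

    def test_no_step_within_budget_raises(self):
        path = RFEPath("g", [_step(0, range(1, 20), 0.9, eliminated=None)])
        with pytest.raises(SelectionError, match="no step"):
            optimal_subset(path, max_features=10)

    def test_empty_path_raises(self):
        with pytest.raises(SelectionError, match="empty"):
            optimal_subset(RFEPath("g", []))
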