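"""Property-based tests (seeded and derandomized) plus invariance checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from convscreen import (
    CVConfig,
    LabeledAlignment,
    build_column_keys,
    build_reference_map,
    decode_alignment,
    encode_alignment,
    labels_to_binary,
    mean_pairwise_distance,
    permute_keys,
    rfe_cv,
    strongest_k_features,
    translate_cds,
)
from convscreen import optimal_subset
from convscreen._engine import draw_splits, iteration_seed_sequence

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")

ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"


@st.composite
def alignments(draw, min_rows=2, max_rows=8, min_cols=1, max_cols=12):
    n = draw(st.integers(min_rows, max_rows))
    length = draw(st.integers(min_cols, max_cols))
    rows = [
        "".join(draw(st.sampled_from(ALPHABET)) for _ in range(length))
        for _ in range(n)
    ]
    return LabeledAlignment("g", [f"s{i}" for i in range(n)], rows)


class TestEncodingProperties:
    @given(alignments())
    def test_encode_decode_round_trip(self, aln):
        keys = build_column_keys(aln)
        fm = encode_alignment(aln, keys)
        assert decode_alignment(fm, keys) == aln.rows

    @given(alignments(), st.integers(0, 2**16))
    def test_shuffled_keys_still_round_trip(self, aln, seed):
        keys = permute_keys(build_column_keys(aln), mode="full-shuffle", seed=seed)
        fm = encode_alignment(aln, keys)
        assert decode_alignment(fm, keys) == aln.rows

    @given(alignments())
    def test_codes_are_dense_from_zero(self, aln):
        keys = build_column_keys(aln)
        for key in keys.keys:
            assert sorted(key.values()) == list(range(len(key)))


class TestMPDProperties:
    @given(alignments(min_rows=3))
    def test_row_order_invariance(self, aln):
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_samples)
        shuffled = LabeledAlignment(
            "g",
            [aln.sample_ids[i] for i in perm],
            [aln.rows[i] for i in perm],
        )
        a = mean_pairwise_distance(aln)
        b = mean_pairwise_distance(shuffled)
        assert a.mpd == pytest.approx(b.mpd)

    @given(alignments(min_rows=2))
    def test_bounds(self, aln):
        rec = mean_pairwise_distance(aln)
        assert 0.0 <= rec.mpd <= aln.length

    @given(alignments(min_rows=2))
    def test_identical_rows_give_zero(self, aln):
        clones = LabeledAlignment(
            "g", ["a", "b", "c"], [aln.rows[0]] * 3
        )
        assert mean_pairwise_distance(clones).mpd == 0.0


class TestReferenceMapProperties:
    @given(alignments(min_rows=2, min_cols=1))
    def test_mapped_positions_are_consecutive(self, aln):
        from dataclasses import replace

        aln = replace(aln, reference_id=aln.sample_ids[0])
        rmap = build_reference_map(aln)
        ref_row = aln.rows[0]
        mapped = [rmap.ap_to_ref[ap] for ap in range(1, aln.length + 1)]
        expected_count = sum(ch != "-" for ch in ref_row)
        non_null = [v for v in mapped if v is not None]
        assert non_null == list(range(1, expected_count + 1))
        for ap, ch in enumerate(ref_row, start=1):
            assert (rmap.ap_to_ref[ap] is None) == (ch == "-")


_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class TestTranslationProperties:
    @given(st.lists(st.sampled_from(_CODONS), min_size=1, max_size=30),
           st.booleans())
    def test_matches_biopython(self, codons, add_stop):
        from Bio.Seq import Seq

        cds = "".join(codons) + ("TAA" if add_stop else "")
        ours = translate_cds(cds)
        ref = str(Seq("".join(codons)).translate(table=11))
        assert ours == ref


class TestLabelProperties:
    @given(st.lists(st.sampled_from(["C3", "C4"]), min_size=2, max_size=30)
           .filter(lambda ls: len(set(ls)) == 2))
    def test_binary_encoding_counts(self, labels):
        y, pos = labels_to_binary(labels)
        assert pos == "C4"
        assert int(y.sum()) == labels.count("C4")


class TestSplitProperties:
    @given(st.integers(10, 80), st.floats(0.25, 0.5), st.integers(0, 2**16))
    def test_partition_and_sizes(self, n, frac, seed):
        # test fraction bounded below so the test portion can hold both classes
        y = np.arange(n) % 2
        ss = iteration_seed_sequence(seed, 1, 0)
        mask = draw_splits(n, y, 7, frac, ss)
        n_test = min(max(int(round(n * frac)), 1), n - 1)
        assert mask.shape == (7, n)
        assert ((~mask).sum(axis=1) == n_test).all()
        for m in range(7):
            assert len(np.unique(y[mask[m]])) == 2
            assert len(np.unique(y[~mask[m]])) == 2


class TestStrongestKProperties:
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=40),
           st.integers(1, 15))
    def test_selected_magnitudes_dominate(self, coefs, k):
        ids = [("g", i + 1) for i in range(len(coefs))]
        chosen = set(strongest_k_features(coefs, ids, k=k))
        mags = {fid: abs(c) for fid, c in zip(ids, coefs)}
        worst_in = min(mags[f] for f in chosen)
        best_out = max(
            (mags[f] for f in ids if f not in chosen), default=-1.0
        )
        assert worst_in >= best_out


class TestBinaryEncodingInvariance:
    """Swapping the two codes of binary columns is affine, so the whole
    screen outcome is invariant on alignments made of binary columns only."""

    def _binary_alignment(self):
        rng = np.random.default_rng(12)
        n, length = 30, 20
        y = (np.arange(n) % 2)
        cols = []
        for j in range(length):
            a, b = ("A", "S") if j % 2 else ("L", "F")
            if j in (4, 11):  # two perfectly informative columns
                col = np.where(y == 1, b, a)
            else:
                col = np.where(rng.random(n) < 0.3, b, a)
            cols.append(col)
        rows = ["".join(c[i] for c in cols) for i in range(n)]
        ids = [f"s{i}" for i in range(n)]
        return LabeledAlignment(
            "bin", ids, rows,
            labels={s: ("C4" if y[i] else "C3") for i, s in enumerate(ids)},
        )

    def test_optimal_positions_identical_under_swap(self):
        aln = self._binary_alignment()
        keys = build_column_keys(aln)
        swapped = permute_keys(keys, fraction=1.0, mode="swap-binary", seed=3)
        config = CVConfig(n_iterations=15, master_seed=9)
        best_a = optimal_subset(rfe_cv(encode_alignment(aln, keys), config=config))
        best_b = optimal_subset(rfe_cv(encode_alignment(aln, swapped), config=config))
        assert list(best_a.feature_set) == list(best_b.feature_set)
        for metric, value in best_a.means.items():
            assert best_b.means[metric] == pytest.approx(value, abs=1e-9)
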