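"""Ordinal encoding of alignment columns.

Each alignment column gets its own key mapping every character observed in
that column (amino acids, ambiguity letters, or the gap) to an integer code
in ``0..N-1`` where N is the number of distinct characters.  Most columns in
conserved protein alignments are binary, so the feature matrix is
predominantly 0/1.  Codes are assigned in descending character frequency
(ties broken alphabetically) so code 0 is always the modal state; any
deterministic assignment works — the screen's outcome is invariant to the
per-column code labelling, which :func:`permute_keys` lets one verify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import LabeledAlignment, labels_to_binary


class EncodingError(ValueError):
    pass


@dataclass
class ColumnKeys:
    """Per-column character -> integer code mappings for one gene."""

    gene_name: str
    keys: list[dict[str, int]] = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.keys)

    def to_json(self, path) -> None:
        payload = [
            {"gene": self.gene_name, "ap": i + 1, "mapping": k}
            for i, k in enumerate(self.keys)
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ColumnKeys":
        with open(path) as fh:
            payload = json.load(fh)
        payload.sort(key=lambda e: e["ap"])
        return cls(payload[0]["gene"], [e["mapping"] for e in payload])


@dataclass
class FeatureMatrix:
    """Samples x columns integer matrix plus column metadata.

    ``column_meta`` is a DataFrame with columns ``gene`` and ``ap`` (1-based
    alignment position), one row per feature, so any selected feature maps
    back to its source column unambiguously.
    """

    values: np.ndarray
    column_meta: pd.DataFrame
    sample_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise EncodingError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.sample_ids):
            raise EncodingError("row count != number of samples")
        if self.values.shape[1] != len(self.column_meta):
            raise EncodingError("column count != metadata rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_ids(self) -> list[tuple[str, int]]:
        return list(zip(self.column_meta["gene"], self.column_meta["ap"].astype(int)))

    def y(self, positive: str | None = None):
        if self.labels is None:
            raise EncodingError("feature matrix is unlabeled")
        return labels_to_binary(self.labels, positive)

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            column_meta=self.column_meta.iloc[idx].reset_index(drop=True),
            sample_ids=self.sample_ids,
            labels=self.labels,
        )

    def select_ids(self, ids: Sequence[tuple[str, int]]) -> "FeatureMatrix":
        lookup = {fid: i for i, fid in enumerate(self.feature_ids())}
        try:
            return self.subset([lookup[fid] for fid in ids])
        except KeyError as exc:
            raise EncodingError(f"unknown feature id {exc.args[0]}") from exc

    def to_tsv(self, path) -> None:
        """Two-row header (gene, ap), then one row per sample."""
        genes = list(self.column_meta["gene"])
        aps = [str(a) for a in self.column_meta["ap"]]
        with open(path, "w") as fh:
            fh.write("\t".join(["gene"] + genes) + "\n")
            fh.write("\t".join(["ap"] + aps) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write("\t".join([sid] + [str(int(v)) for v in row]) + "\n")


def build_column_keys(aln: LabeledAlignment) -> ColumnKeys:
    """Create per-column keys: codes by descending frequency, ties alphabetical."""
    keys: list[dict[str, int]] = []
    for j in range(aln.length):
        counts = Counter(row[j] for row in aln.rows)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        keys.append({ch: code for code, (ch, _) in enumerate(ranked)})
    return ColumnKeys(aln.gene_name, keys)


def encode_alignment(
    aln: LabeledAlignment, keys: ColumnKeys | None = None
) -> FeatureMatrix:
    """Vectorize an alignment into its ordinal feature matrix.

    When ``keys`` is omitted they are built from the alignment itself, in
    which case encoding can never fail.  With external keys, a character not
    present in a column's key raises naming the offending sample and column.
    """
    if keys is None:
        keys = build_column_keys(aln)
    if keys.n_columns != aln.length:
        raise EncodingError(
            f"{aln.gene_name}: keys cover {keys.n_columns} columns, "
            f"alignment has {aln.length}"
        )
    values = np.empty((aln.n_samples, aln.length), dtype=np.int16)
    for j, key in enumerate(keys.keys):
        for i, row in enumerate(aln.rows):
            ch = row[j]
            if ch not in key:
                raise EncodingError(
                    f"{aln.gene_name}: character {ch!r} of sample "
                    f"{aln.sample_ids[i]!r} absent from key at ap {j + 1}"
                )
            values[i, j] = key[ch]
    meta = pd.DataFrame(
        {"gene": aln.gene_name, "ap": np.arange(1, aln.length + 1, dtype=int)}
    )
    return FeatureMatrix(
        values=values,
        column_meta=meta,
        sample_ids=list(aln.sample_ids),
        labels=list(aln.label_list()) if aln.labels is not None else None,
    )


def decode_alignment(fm: FeatureMatrix, keys: ColumnKeys) -> list[str]:
    """Invert :func:`encode_alignment`; the per-column key is a bijection."""
    inverse = [{code: ch for ch, code in key.items()} for key in keys.keys]
    rows = []
    for i in range(fm.n_samples):
        rows.append("".join(inverse[j][int(fm.values[i, j])] for j in range(fm.n_features)))
    return rows


def permute_keys(
    keys: ColumnKeys,
    fraction: float = 1.0,
    mode: str = "swap-binary",
    seed: int = 0,
) -> ColumnKeys:
    """Relabel column codes to probe encoding robustness.

    ``swap-binary``: for a seeded random subset of columns of the given
    fraction, exchange codes 0 and 1 (columns with more than two states get a
    seeded transposition of two of their codes).  ``full-shuffle``: every
    column's code assignment becomes a seeded random permutation of 0..N-1.
    Single-state columns are unchanged in either mode.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if mode not in ("swap-binary", "full-shuffle"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    n = keys.n_columns
    new_keys: list[dict[str, int]] = [dict(k) for k in keys.keys]
    if mode == "swap-binary":
        n_pick = int(round(fraction * n))
        chosen = rng.choice(n, size=n_pick, replace=False) if n_pick else []
        for j in sorted(int(c) for c in np.asarray(chosen)):
            key = new_keys[j]
            m = len(key)
            if m < 2:
                continue
            if m == 2:
                a, b = 0, 1
            else:
                a, b = sorted(rng.choice(m, size=2, replace=False).tolist())
            swap = {a: b, b: a}
            new_keys[j] = {ch: swap.get(c, c) for ch, c in key.items()}
    else:  # full-shuffle relabels every column regardless of fraction
        for j in range(n):
            key = new_keys[j]
            m = len(key)
            if m < 2:
                continue
            perm = rng.permutation(m)
            new_keys[j] = {ch: int(perm[c]) for ch, c in key.items()}
    return ColumnKeys(keys.gene_name, new_keys)
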