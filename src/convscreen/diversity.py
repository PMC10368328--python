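"""Alignment diversity statistics and accuracy correlations.

Mean pairwise distance (MPD) — the average number of differing columns over
all unordered sequence pairs — measures how much raw variation an alignment
offers a classifier.  Correlating per-gene MPD (computed on one phenotype
class only, so variation tied to the phenotype itself is excluded), raw
alignment length, and length-normalized MPD against optimal model accuracy
shows how much of the classification signal mere information content
explains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import LabeledAlignment


class DiversityError(ValueError):
    pass


@dataclass
class DiversityRecord:
    """MPD and its per-100-residue normalization for one alignment subset.

    Gap handling: a gap versus a residue counts as a difference; two gaps
    count as identical (shared absence is not variation).  Comparison is
    case-insensitive.
    """

    gene_name: str
    subset: str
    n_sequences: int
    length: int
    mpd: float
    mpd_per_100: float


def mean_pairwise_distance(
    aln: LabeledAlignment,
    subset_label: str | None = None,
    subset_name: str | None = None,
) -> DiversityRecord:
    """Average count of differing columns over all unordered sequence pairs.

    ``subset_label`` restricts the computation to samples carrying that
    phenotype label (e.g. the ancestral class only).
    """
    rows = aln.rows
    name = subset_name or ("all" if subset_label is None else subset_label)
    if subset_label is not None:
        labels = aln.label_list()
        rows = [r for r, l in zip(rows, labels) if l == subset_label]
    n = len(rows)
    if n < 2:
        raise DiversityError(
            f"{aln.gene_name}: need >= 2 sequences for pairwise distances (got {n})"
        )
    arr = np.frombuffer("".join(r.upper() for r in rows).encode("ascii"),
                        dtype=np.uint8).reshape(n, aln.length)
    total = 0
    for i in range(n - 1):
        total += int((arr[i + 1 :] != arr[i]).sum())
    n_pairs = n * (n - 1) // 2
    mpd = total / n_pairs
    return DiversityRecord(
        gene_name=aln.gene_name,
        subset=name,
        n_sequences=n,
        length=aln.length,
        mpd=mpd,
        mpd_per_100=mpd * 100.0 / aln.length,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input (r undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DiversityError("vectors differ in length")
    if len(x) < 3:
        raise DiversityError("need >= 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DiversityError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def diversity_table(records: Sequence[DiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_name for r in records],
            "subset": [r.subset for r in records],
            "n_seqs": [r.n_sequences for r in records],
            "length": [r.length for r in records],
            "mpd": [r.mpd for r in records],
            "mpd_per_100": [r.mpd_per_100 for r in records],
        }
    )


def accuracy_correlates(
    records: Sequence[DiversityRecord],
    accuracies: Mapping[str, float],
) -> tuple[dict[str, float], pd.DataFrame]:
    """Correlate per-gene MPD, length and MPD/100 with optimal model accuracy.

    Returns the three r values plus a scatter-ready per-gene table.  Every
    record's gene must have an accuracy; fewer than three genes, or constant
    accuracies, leave r undefined and raise.
    """
    genes = [r.gene_name for r in records]
    missing = [g for g in genes if g not in accuracies]
    if missing:
        raise DiversityError(f"no accuracy for genes {missing}")
    if len(genes) < 3:
        raise DiversityError("need >= 3 genes for correlation analysis")
    table = diversity_table(records)
    table["accuracy"] = [accuracies[g] for g in genes]
    acc = table["accuracy"].to_numpy()
    r_values = {
        "mpd_vs_accuracy": pearson_correlation(table["mpd"], acc),
        "length_vs_accuracy": pearson_correlation(table["length"], acc),
        "mpd_per_100_vs_accuracy": pearson_correlation(table["mpd_per_100"], acc),
    }
    return r_values, table
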