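"""End-to-end screen orchestration and report writing.

Stages per gene: ordinal encoding -> v1 model (all alignment columns,
repeated-subsampling CV) -> full-data coefficients -> ten strongest features
-> v2 model CV -> RFE-CV starting from the full-length alignment -> optimal
(<= 10 feature) v3 set.  Around the per-gene screen sit the permutation-label
null battery, complex-level models, diversity correlations and per-group
misclassification summaries.  All randomness flows from one master seed, so
a rerun with the same configuration reproduces every report file byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import LabeledAlignment, build_reference_map
from .complexes import ComplexSpec, combine_complex, format_feature, screen_complex
from .cv import (
    CTX_V1,
    CTX_V2,
    CVConfig,
    compare_metric_distributions,
    full_data_coefficients,
    majority_class_fraction,
    misclassification_by_group,
    permuted_label_cv,
    repeated_subsample_cv,
)
from .diversity import accuracy_correlates, diversity_table, mean_pairwise_distance
from .encoding import ColumnKeys, FeatureMatrix, build_column_keys, encode_alignment
from .selection import (
    FeatureSet,
    OptimalResult,
    RFEPath,
    optimal_subset,
    rfe_cv,
    strongest_k_features,
)

log = logging.getLogger("convscreen")

METRIC_HEADERS = ["ROC AUC", "Precision", "Recall", "F1", "Acc"]
_METRIC_KEYS = ["auroc", "precision", "recall", "f1", "accuracy"]


class PipelineError(ValueError):
    pass


@dataclass
class GeneScreenResult:
    gene: str
    n_columns: int
    v1_means: dict[str, float]
    v1_accuracy_sample: np.ndarray = field(repr=False)
    v1_auroc_sample: np.ndarray = field(repr=False)
    v2_set: FeatureSet | None = None
    v2_means: dict[str, float] | None = None
    rfe_path: RFEPath | None = field(default=None, repr=False)
    optimal: OptimalResult | None = None
    ref_positions: list[str] | None = None
    flagged_short: bool = False


@dataclass
class ScreenReport:
    genes: dict[str, GeneScreenResult]
    gene_order: list[str]
    top_comparisons: list[dict]
    config: CVConfig
    max_features: int
    min_features: int
    accuracy_floor: float

    def ranking(self, stage: str = "v1") -> list[str]:
        """Genes ranked by the stage's mean accuracy, best first."""
        def key(g):
            r = self.genes[g]
            if stage == "v1":
                return r.v1_means["accuracy"]
            if stage == "v2":
                return -1.0 if r.v2_means is None else r.v2_means["accuracy"]
            if stage == "v3":
                return -1.0 if r.optimal is None else r.optimal.means["accuracy"]
            raise ValueError(f"unknown stage {stage!r}")
        return sorted(self.gene_order, key=lambda g: (-key(g), g))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.gene_order:
            r = self.genes[g]
            row = {
                "Gene": g,
                "Initial Features": r.n_columns,
                "Optimal Features (ap)": ""
                if r.optimal is None
                else ",".join(str(ap) for _, ap in r.optimal.feature_set),
                "Residue Positions (reference)": ""
                if r.ref_positions is None
                else ",".join(r.ref_positions),
            }
            means = {} if r.optimal is None else r.optimal.means
            for header, key in zip(METRIC_HEADERS, _METRIC_KEYS):
                row[header] = means.get(key, float("nan"))
            row["In Zone"] = "" if r.optimal is None else str(r.optimal.in_zone)
            row["v1 Acc"] = r.v1_means["accuracy"]
            row["v2 Acc"] = float("nan") if r.v2_means is None else r.v2_means["accuracy"]
            row["Flagged Short"] = str(r.flagged_short)
            rows.append(row)
        return pd.DataFrame(rows)


def _check_consistency(alignments: Mapping[str, LabeledAlignment]) -> None:
    if not alignments:
        raise PipelineError("no alignments supplied")
    genes = sorted(alignments)
    first = alignments[genes[0]]
    if first.labels is None:
        raise PipelineError(f"{genes[0]}: alignment is unlabeled")
    for g in genes[1:]:
        aln = alignments[g]
        if aln.labels is None:
            raise PipelineError(f"{g}: alignment is unlabeled")
        if aln.sample_ids != first.sample_ids:
            raise PipelineError(f"{g}: sample set differs from {genes[0]}")
        if aln.labels != first.labels:
            raise PipelineError(f"{g}: labels differ from {genes[0]}")


def encode_all(
    alignments: Mapping[str, LabeledAlignment],
    keys: Mapping[str, ColumnKeys] | None = None,
) -> dict[str, FeatureMatrix]:
    return {
        g: encode_alignment(alignments[g], None if keys is None else keys[g])
        for g in sorted(alignments)
    }


def screen_genes(
    alignments: Mapping[str, LabeledAlignment],
    config: CVConfig | None = None,
    keys: Mapping[str, ColumnKeys] | None = None,
    max_features: int = 10,
    min_features: int = 2,
    accuracy_floor: float = 0.9,
    k_strongest: int = 10,
    rfe_from: str = "full",
    rfe_genes: Sequence[str] | None = None,
    percentile: float = 0.8,
) -> ScreenReport:
    """Run the v1 -> v2 -> v3 screen over all genes.

    ``rfe_from="full"`` (canonical) starts elimination from the full-length
    alignment; ``"v2"`` is a cheaper non-canonical variant that starts from
    the ten strongest features.  ``rfe_genes`` restricts the RFE stage to a
    gene subset (others keep v1/v2 results only).  Genes with fewer columns
    than ``min_features`` are reported with v1 metrics only and flagged.
    """
    config = config or CVConfig()
    if rfe_from not in ("full", "v2"):
        raise PipelineError(f"rfe_from must be 'full' or 'v2', got {rfe_from!r}")
    _check_consistency(alignments)
    gene_order = sorted(alignments)
    matrices = encode_all(alignments, keys)
    results: dict[str, GeneScreenResult] = {}
    for gi, gene in enumerate(gene_order):
        fm = matrices[gene]
        log.info("screening %s (%d samples x %d columns)", gene,
                 fm.n_samples, fm.n_features)
        v1 = repeated_subsample_cv(fm, config=config, seed_context=(CTX_V1, gi))
        res = GeneScreenResult(
            gene=gene,
            n_columns=fm.n_features,
            v1_means=v1.means(),
            v1_accuracy_sample=v1.metrics["accuracy"],
            v1_auroc_sample=v1.metrics["auroc"],
        )
        coefs = full_data_coefficients(fm, config=config)
        res.v2_set = strongest_k_features(coefs, fm.feature_ids(), k=k_strongest)
        v2_fm = fm.select_ids(list(res.v2_set))
        v2 = repeated_subsample_cv(v2_fm, config=config, seed_context=(CTX_V2, gi))
        res.v2_means = v2.means()

        if fm.n_features < min_features:
            res.flagged_short = True
        elif rfe_genes is None or gene in rfe_genes:
            start_fm = fm if rfe_from == "full" else v2_fm
            res.rfe_path = rfe_cv(
                start_fm, config=config, min_features=min_features
            )
            res.optimal = optimal_subset(
                res.rfe_path, max_features=max_features,
                accuracy_floor=accuracy_floor,
            )
            aln = alignments[gene]
            if aln.reference_id is not None:
                rmap = build_reference_map(aln)
                res.ref_positions = [
                    rmap.format_position(ap) for _, ap in res.optimal.feature_set
                ]
            log.info(
                "%s: v1 acc %.4f, v3 acc %.4f with %d features", gene,
                res.v1_means["accuracy"], res.optimal.means["accuracy"],
                len(res.optimal.feature_set),
            )
        results[gene] = res

    report = ScreenReport(
        genes=results,
        gene_order=gene_order,
        top_comparisons=[],
        config=config,
        max_features=max_features,
        min_features=min_features,
        accuracy_floor=accuracy_floor,
    )
    report.top_comparisons = _top_vs_percentile(report, percentile)
    return report


def _top_vs_percentile(report: ScreenReport, percentile: float) -> list[dict]:
    """Compare each top gene's v1 accuracy sample to the percentile comparator.

    The comparator is the gene whose v1 mean accuracy sits at the given
    percentile of the per-gene distribution; every gene ranked above it is
    tested against it (Student's t, Bonferroni over the number of tests).
    """
    order = sorted(
        report.gene_order, key=lambda g: report.genes[g].v1_means["accuracy"]
    )
    G = len(order)
    if G < 3:
        return []
    comp_idx = min(G - 1, max(0, int(np.ceil(percentile * G)) - 1))
    comparator = order[comp_idx]
    top = order[comp_idx + 1 :]
    m = max(len(top), 1)
    out = []
    for gene in top:
        cmp = compare_metric_distributions(
            report.genes[gene].v1_accuracy_sample,
            report.genes[comparator].v1_accuracy_sample,
            m=m,
            welch=report.config.welch,
        )
        out.append({"gene": gene, "comparator": comparator, **cmp.to_dict()})
    return out


def run_null_battery(
    alignments: Mapping[str, LabeledAlignment],
    config: CVConfig | None = None,
    keys: Mapping[str, ColumnKeys] | None = None,
    report: ScreenReport | None = None,
) -> pd.DataFrame:
    """Permutation-label nulls per gene, compared to the true-label v1 runs.

    Labels are replaced by seeded class-count-preserving permutations (a
    fresh permutation per CV iteration) and the identical CV procedure (same
    split seeds) is repeated; accuracy and AUROC distributions are then
    compared by a one-sided Student's t (true > permuted — the battery tests
    the directional claim that a gene classifies better than chance, so a
    gene whose true-label accuracy falls below its null by dataset luck is a
    non-finding, not a detection) with Bonferroni correction over the whole
    battery (two tests per gene).
    """
    config = config or CVConfig()
    _check_consistency(alignments)
    gene_order = sorted(alignments)
    matrices = encode_all(alignments, keys)
    m_family = 2 * len(gene_order)
    rows = []
    for gi, gene in enumerate(gene_order):
        fm = matrices[gene]
        if report is not None and gene in report.genes:
            true_acc = report.genes[gene].v1_accuracy_sample
            true_auroc = report.genes[gene].v1_auroc_sample
        else:
            true = repeated_subsample_cv(fm, config=config, seed_context=(CTX_V1, gi))
            true_acc = true.metrics["accuracy"]
            true_auroc = true.metrics["auroc"]
        null = permuted_label_cv(fm, config=config, seed_context=(CTX_V1, gi))
        cmp_acc = compare_metric_distributions(
            true_acc, null.metrics["accuracy"], m=m_family, welch=config.welch,
            alternative="greater",
        )
        cmp_auc = compare_metric_distributions(
            true_auroc, null.metrics["auroc"], m=m_family, welch=config.welch,
            alternative="greater",
        )
        log.info("%s null: true acc %.4f vs permuted %.4f (p_adj %.3g)", gene,
                 float(np.mean(true_acc)), null.mean("accuracy"), cmp_acc.p_adjusted)
        rows.append(
            {
                "gene": gene,
                "true_acc_mean": float(np.mean(true_acc)),
                "null_acc_mean": null.mean("accuracy"),
                "acc_t": cmp_acc.t_statistic,
                "acc_p_adjusted": cmp_acc.p_adjusted,
                "acc_significant": cmp_acc.significant,
                "true_auroc_mean": float(np.mean(true_auroc)),
                "null_auroc_mean": null.mean("auroc"),
                "auroc_t": cmp_auc.t_statistic,
                "auroc_p_adjusted": cmp_auc.p_adjusted,
                "auroc_significant": cmp_auc.significant,
            }
        )
    return pd.DataFrame(rows)


def screen_complexes(
    matrices: Mapping[str, FeatureMatrix],
    roster: Mapping[str, ComplexSpec],
    config: CVConfig | None = None,
    max_features: int = 10,
) -> tuple[pd.DataFrame, dict[str, RFEPath]]:
    """Combine and screen every complex whose subunits are all available."""
    config = config or CVConfig()
    rows, paths = [], {}
    for name in sorted(roster):
        spec = roster[name]
        missing = [g for g in spec.genes if g not in matrices]
        if missing:
            log.warning("complex %s skipped: missing subunits %s", name, missing)
            continue
        combined = combine_complex(matrices, spec, config=config)
        path, best = screen_complex(combined, config=config, max_features=max_features)
        paths[name] = path
        row = {
            "Complex": name,
            "Combined Subunits": ",".join(spec.genes),
            "Optimal Features (Subunit-ap)": ",".join(
                format_feature(f) for f in best.feature_set
            ),
        }
        for header, key in zip(METRIC_HEADERS, _METRIC_KEYS):
            row[header] = best.means[key]
        row["In Zone"] = str(best.in_zone)
        rows.append(row)
    return pd.DataFrame(rows), paths


def diversity_report(
    alignments: Mapping[str, LabeledAlignment],
    report: ScreenReport,
    subset_label: str | None = None,
) -> tuple[dict[str, float | None], pd.DataFrame]:
    """Per-gene MPD (ancestral class only by default) vs optimal accuracy."""
    gene_order = [
        g for g in report.gene_order if report.genes[g].optimal is not None
    ]
    if subset_label is None:
        first = alignments[report.gene_order[0]]
        labels = sorted(set(first.label_list()))
        subset_label = labels[0]  # class 0: lexicographically earlier
    records = [
        mean_pairwise_distance(alignments[g], subset_label=subset_label)
        for g in gene_order
    ]
    accuracies = {
        g: report.genes[g].optimal.means["accuracy"] for g in gene_order
    }
    try:
        r_values, table = accuracy_correlates(records, accuracies)
    except Exception as exc:  # undefined correlation or too few genes
        log.warning("diversity correlation unavailable: %s", exc)
        table = diversity_table(records)
        table["accuracy"] = [accuracies[g] for g in gene_order]
        r_values = {
            "mpd_vs_accuracy": None,
            "length_vs_accuracy": None,
            "mpd_per_100_vs_accuracy": None,
        }
    return r_values, table


def group_misclassification_report(
    alignments: Mapping[str, LabeledAlignment],
    report: ScreenReport,
    group_name: str = "subtype",
) -> pd.DataFrame:
    """Pooled per-group misclassification of each gene's optimal model."""
    rows = []
    for gene in report.gene_order:
        res = report.genes[gene]
        if res.optimal is None or res.optimal.summary is None:
            continue
        aln = alignments[gene]
        if aln.groups is None:
            continue
        groups = aln.group_list(group_name)
        y, _ = aln_y(aln, report.config.positive_label)
        table = misclassification_by_group(res.optimal.summary, groups, y)
        table.insert(0, "gene", gene)
        rows.append(table)
    if not rows:
        return pd.DataFrame(columns=["gene", "group", "appearances", "errors", "rate"])
    return pd.concat(rows, ignore_index=True)


def aln_y(aln: LabeledAlignment, positive: str | None = None):
    from .alignment import labels_to_binary

    return labels_to_binary(aln.label_list(), positive)


# ---------------------------------------------------------------------------
# Report writing


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    return out


def config_hash(config: CVConfig) -> str:
    payload = json.dumps(vars(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_reports(
    outdir,
    report: ScreenReport,
    alignments: Mapping[str, LabeledAlignment] | None = None,
    null_table: pd.DataFrame | None = None,
    complex_table: pd.DataFrame | None = None,
    group_name: str = "subtype",
) -> dict[str, Path]:
    """Write all report tables; content is deterministic given config + seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _format_frame(df).to_csv(path, sep="\t", index=False)
        written[name] = path

    _write("screen_report.tsv", report.to_frame())
    if report.top_comparisons:
        _write("top_model_comparisons.tsv", pd.DataFrame(report.top_comparisons))
    if null_table is not None:
        _write("null_report.tsv", null_table)
    if complex_table is not None:
        _write("complex_report.tsv", complex_table)

    rfe_payload = {}
    for gene in report.gene_order:
        path_obj = report.genes[gene].rfe_path
        if path_obj is None:
            continue
        rfe_payload[gene] = {
            "step_sizes": path_obj.step_sizes(),
            "eliminated": [
                [g, int(ap)] for g, ap in path_obj.elimination_order()
            ],
            "accuracy_by_step": [
                round(s.means["accuracy"], 6) for s in path_obj.steps
            ],
        }
    with open(outdir / "rfe_paths.json", "w") as fh:
        json.dump(rfe_payload, fh, indent=1, sort_keys=True)
    written["rfe_paths.json"] = outdir / "rfe_paths.json"

    if alignments is not None:
        r_values, div_table = diversity_report(alignments, report)
        _write("diversity.tsv", div_table)
        with open(outdir / "diversity_correlations.json", "w") as fh:
            json.dump(r_values, fh, indent=1, sort_keys=True)
        written["diversity_correlations.json"] = outdir / "diversity_correlations.json"
        mis = group_misclassification_report(alignments, report, group_name)
        _write("misclassification_by_group.tsv", mis)

    meta = {
        "master_seed": report.config.master_seed,
        "n_iterations": report.config.n_iterations,
        "test_fraction": report.config.test_fraction,
        "config_hash": config_hash(report.config),
        "genes": report.gene_order,
        "ranking_v1": report.ranking("v1"),
        "ranking_v3": report.ranking("v3"),
    }
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    written["run_meta.json"] = outdir / "run_meta.json"
    return written
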