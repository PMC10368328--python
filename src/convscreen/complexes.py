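"""Multi-subunit "complex" models.

A protein complex is screened by taking each constituent subunit's ten
strongest features (largest absolute full-data coefficients), concatenating
them across subunits, and re-running RFE-CV on the combined matrix to an
optimal cross-subunit feature set of at most ten features.  Optimal features
are reported as ``subunit-ap`` so each one maps back to its source gene and
alignment column.

The default roster covers the plastid-encoded complexes: the NDH complex,
ATP synthase, cytochrome b6f, both photosystems (PSII without PsbN, whose
membership in the supercomplex is doubtful) and the two ribosomal subunit
sets (50S without Rpl32, which is absent from several grass plastomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cv import CVConfig, full_data_coefficients
from .encoding import FeatureMatrix
from .selection import OptimalResult, RFEPath, optimal_subset, rfe_cv, strongest_k_features


class ComplexError(ValueError):
    pass


@dataclass
class ComplexSpec:
    name: str
    genes: list[str]
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ComplexError(f"{self.name}: a complex needs >= 2 subunits")
        if len(self.genes) != len(set(self.genes)):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ComplexError(f"{self.name}: duplicate subunits {dupes}")


DEFAULT_COMPLEXES: dict[str, ComplexSpec] = {
    spec.name: spec
    for spec in [
        ComplexSpec("NDH", [f"ndh{c}" for c in "ABCDEFGHIJK"]),
        ComplexSpec("ATP_synthase", ["atpA", "atpB", "atpE", "atpF", "atpH", "atpI"]),
        ComplexSpec("cyt_b6f", ["petA", "petB", "petD", "petG", "petL", "petN"]),
        ComplexSpec("PSI", ["psaA", "psaB", "psaC", "psaI", "psaJ"]),
        ComplexSpec(
            "PSII",
            ["psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
             "psbJ", "psbK", "psbL", "psbM", "psbT", "psbZ"],
            notes="PsbN excluded: likely not a constituent of the supercomplex",
        ),
        ComplexSpec(
            "50S",
            ["rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl33", "rpl36"],
            notes="Rpl32 excluded: absent from several grass plastomes",
        ),
        ComplexSpec(
            "30S",
            ["rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14",
             "rps15", "rps16", "rps18", "rps19"],
        ),
    ]
}


def load_complex_roster(path) -> dict[str, ComplexSpec]:
    """Roster YAML: ``{complex_name: [gene, gene, ...]}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: ComplexSpec(name, list(genes)) for name, genes in raw.items()}


def combine_complex(
    matrices: Mapping[str, FeatureMatrix],
    spec: ComplexSpec,
    config: CVConfig | None = None,
    k_per_subunit: int = 10,
) -> FeatureMatrix:
    """Concatenate each subunit's k strongest features in roster order.

    Subunits with fewer than k columns contribute all of them.  All subunits
    must share the identical sample set and labels.
    """
    config = config or CVConfig()
    missing = [g for g in spec.genes if g not in matrices]
    if missing:
        raise ComplexError(f"{spec.name}: no feature matrix for {missing}")
    first = matrices[spec.genes[0]]
    offenders = [
        g for g in spec.genes
        if matrices[g].sample_ids != first.sample_ids
        or matrices[g].labels != first.labels
    ]
    if offenders:
        raise ComplexError(
            f"{spec.name}: sample set/labels disagree for subunits {offenders}"
        )
    parts, metas = [], []
    for gene in spec.genes:
        fm = matrices[gene]
        coefs = full_data_coefficients(fm, config=config)
        top = strongest_k_features(coefs, fm.feature_ids(), k=k_per_subunit)
        sub = fm.select_ids(list(top))
        parts.append(sub.values)
        metas.append(sub.column_meta)
    return FeatureMatrix(
        values=np.concatenate(parts, axis=1),
        column_meta=pd.concat(metas, ignore_index=True),
        sample_ids=list(first.sample_ids),
        labels=list(first.labels) if first.labels is not None else None,
    )


def screen_complex(
    combined: FeatureMatrix,
    config: CVConfig | None = None,
    max_features: int = 10,
    min_features: int = 2,
) -> tuple[RFEPath, OptimalResult]:
    """RFE-CV the combined matrix and extract the optimal cross-subunit set."""
    config = config or CVConfig()
    path = rfe_cv(combined, config=config, min_features=min_features)
    best = optimal_subset(path, max_features=max_features)
    return path, best


def format_feature(feature_id: tuple[str, int]) -> str:
    """Human-readable subunit-position label, e.g. ``ndhI-25``."""
    gene, ap = feature_id
    return f"{gene}-{ap}"
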