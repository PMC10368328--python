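"""Aligned sequence containers, label handling, translation and coordinates.

The screen operates on gapped amino-acid multiple sequence alignments in
which every sample (species) carries a binary phenotype label (for example
C3 vs C4 photosynthetic type).  Alignment columns are addressed by 1-based
alignment position ("ap"); an optional reference sequence allows reporting
the same column as a 1-based residue number in that sequence's ungapped
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

GAP = "-"

_IUPAC_NUC = set("ACGTURYSWKMBDHVN")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, too few records...)."""


class LabelError(ValueError):
    """Raised for invalid or incomplete phenotype label tables."""


class TranslationError(ValueError):
    """Raised for untranslatable coding sequences."""


@dataclass
class LabeledAlignment:
    """A gapped protein alignment with optional per-sample annotations.

    Parameters
    ----------
    gene_name:
        Identifier of the locus the alignment derives from.
    sample_ids:
        Unique sample (species/accession) identifiers, one per row.
    rows:
        Equal-length uppercase strings over amino-acid letters, ambiguity
        letters and the gap character ``-``.
    labels:
        Optional mapping sample id -> phenotype label.  At most two distinct
        label values may occur.
    groups:
        Optional mapping sample id -> {annotation name: value}, e.g.
        biochemical subtype or lineage.
    reference_id:
        Optional sample id used for residue renumbering.
    """

    gene_name: str
    sample_ids: list[str]
    rows: list[str]
    labels: dict[str, str] | None = None
    groups: dict[str, dict[str, str]] | None = None
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.rows):
            raise AlignmentError("sample_ids and rows differ in length")
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise AlignmentError(f"{self.gene_name}: duplicate sample ids")
        if not self.rows:
            raise AlignmentError(f"{self.gene_name}: empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.gene_name}: ragged rows, lengths {sorted(lengths)}"
            )
        if self.length < 1:
            raise AlignmentError(f"{self.gene_name}: zero-length alignment")
        self.rows = [r.upper() for r in self.rows]
        if self.labels is not None:
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise LabelError(f"{self.gene_name}: unlabeled samples {missing}")
            values = set(self.labels[s] for s in self.sample_ids)
            if len(values) > 2:
                raise LabelError(
                    f"{self.gene_name}: labels must be binary, got {sorted(values)}"
                )
        if self.reference_id is not None and self.reference_id not in self.sample_ids:
            raise AlignmentError(
                f"{self.gene_name}: reference id {self.reference_id!r} not a sample"
            )

    @property
    def n_samples(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def label_list(self) -> list[str]:
        if self.labels is None:
            raise LabelError(f"{self.gene_name}: alignment is unlabeled")
        return [self.labels[s] for s in self.sample_ids]

    def group_list(self, name: str) -> list[str]:
        if self.groups is None:
            raise LabelError(f"{self.gene_name}: no group annotations")
        return [self.groups.get(s, {}).get(name, "NA") for s in self.sample_ids]

    def subset(self, sample_ids: Sequence[str]) -> "LabeledAlignment":
        wanted = set(sample_ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        ref = self.reference_id if self.reference_id in wanted else None
        return LabeledAlignment(
            gene_name=self.gene_name,
            sample_ids=[self.sample_ids[i] for i in keep],
            rows=[self.rows[i] for i in keep],
            labels=(
                {self.sample_ids[i]: self.labels[self.sample_ids[i]] for i in keep}
                if self.labels is not None
                else None
            ),
            groups=(
                {s: self.groups[s] for s in (self.sample_ids[i] for i in keep) if s in self.groups}
                if self.groups is not None
                else None
            ),
            reference_id=ref,
        )


def positive_label(aln_or_labels, override: str | None = None) -> str:
    """Class-1 ("positive") label: lexicographically later unless overridden.

    A fixed orientation keeps AUROC and coefficient signs deterministic;
    with C3/C4 labels the C4 state is positive.
    """
    if isinstance(aln_or_labels, LabeledAlignment):
        values = sorted(set(aln_or_labels.label_list()))
    else:
        values = sorted(set(aln_or_labels))
    if override is not None:
        if override not in values:
            raise LabelError(f"positive label {override!r} not among {values}")
        return override
    return values[-1]


def labels_to_binary(labels: Sequence[str], positive: str | None = None):
    """Map string labels to a 0/1 integer vector; returns (y, positive_label)."""
    import numpy as np

    pos = positive_label(list(labels), positive)
    y = np.asarray([1 if v == pos else 0 for v in labels], dtype=np.int8)
    return y, pos


# ---------------------------------------------------------------------------
# FASTA / label-table IO


def read_alignment(path, gene_name: str | None = None) -> LabeledAlignment:
    """Read a gapped FASTA alignment into an unlabeled :class:`LabeledAlignment`.

    Record order is preserved and residues are uppercased.  Fewer than two
    records is an error: every downstream statistic is pairwise or
    supervised and undefined on a single sequence.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise AlignmentError(f"{path}: no FASTA records")
    if len(records) < 2:
        raise AlignmentError(f"{path}: need >= 2 aligned records")
    name = gene_name if gene_name is not None else path.stem
    return LabeledAlignment(
        gene_name=name,
        sample_ids=[r.id for r in records],
        rows=[str(r.seq) for r in records],
    )


def write_alignment(aln: LabeledAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.sample_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def read_label_table(path) -> pd.DataFrame:
    """Read a label TSV: ``sample_id<TAB>label[<TAB>group...]`` with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise LabelError(f"{path}: header must contain sample_id and label")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise LabelError(f"{path}: duplicate sample ids {dup}")
    return df


def write_label_table(labels: Mapping[str, str], path,
                      groups: Mapping[str, Mapping[str, str]] | None = None) -> None:
    group_cols: list[str] = []
    if groups:
        seen: dict[str, None] = {}
        for g in groups.values():
            for k in g:
                seen.setdefault(k, None)
        group_cols = list(seen)
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "label"] + group_cols) + "\n")
        for sid in labels:
            extra = [groups.get(sid, {}).get(c, "NA") if groups else "NA"
                     for c in group_cols]
            fh.write("\t".join([sid, labels[sid]] + extra) + "\n")


def attach_labels(
    aln: LabeledAlignment,
    table: pd.DataFrame | Mapping[str, str],
    drop_unlabeled: bool = False,
) -> LabeledAlignment:
    """Attach binary phenotype labels (and any group columns) to an alignment.

    Every sample must appear in the table unless ``drop_unlabeled`` is set,
    in which case uncovered samples are removed from the alignment.
    """
    if isinstance(table, pd.DataFrame):
        label_map = dict(zip(table["sample_id"], table["label"]))
        group_cols = [c for c in table.columns if c not in ("sample_id", "label")]
        group_map: dict[str, dict[str, str]] = {
            row["sample_id"]: {c: row[c] for c in group_cols}
            for _, row in table.iterrows()
        } if group_cols else {}
    else:
        label_map = dict(table)
        group_map = {}

    covered = [s for s in aln.sample_ids if s in label_map]
    missing = [s for s in aln.sample_ids if s not in label_map]
    if missing and not drop_unlabeled:
        raise LabelError(
            f"{aln.gene_name}: samples missing from label table: {missing}"
        )
    base = aln.subset(covered) if missing else aln
    labels = {s: label_map[s] for s in base.sample_ids}
    if len(set(labels.values())) > 2:
        raise LabelError(
            f"{aln.gene_name}: more than two label values: "
            f"{sorted(set(labels.values()))}"
        )
    return replace(
        base,
        labels=labels,
        groups={s: group_map[s] for s in base.sample_ids if s in group_map} or None,
    )


# ---------------------------------------------------------------------------
# Translation (plastid / bacterial genetic code, NCBI table 11)


def translate_cds(nuc: str, table_id: int = 11, trim_partial: bool = False) -> str:
    """Translate a coding sequence, stripping a single terminal stop codon.

    Uses the bacterial/plant-plastid genetic code by default.  There is no
    start-codon special-casing: internal fidelity is what matters when the
    product is aligned.  An internal stop codon is an error reporting the
    1-based codon index; ambiguous nucleotides translate through Biopython's
    ambiguity resolution (to 'X' when the amino acid is not determined).
    """
    seq = nuc.strip().upper().replace("U", "T")
    bad = sorted(set(seq) - _IUPAC_NUC)
    if bad:
        raise TranslationError(f"non-IUPAC nucleotide characters: {bad}")
    rem = len(seq) % 3
    if rem:
        if not trim_partial:
            raise TranslationError(
                f"length {len(seq)} not divisible by 3 (set trim_partial to drop "
                f"the trailing {rem} nt)"
            )
        seq = seq[: len(seq) - rem]
    if not seq:
        return ""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)
    out: list[str] = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in stops:
            if i == n_codons - 1:
                break  # single terminal stop stripped
            raise TranslationError(
                f"internal stop codon {codon} at codon {i + 1}"
            )
        if codon in table.forward_table:
            out.append(table.forward_table[codon])
        else:
            # ambiguous codon: defer to Biopython's ambiguity handling
            aa = str(Seq(codon).translate(table=table_id))
            if aa == "*":
                if i == n_codons - 1:
                    break
                raise TranslationError(
                    f"internal stop codon {codon} at codon {i + 1}"
                )
            out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# Alignment position -> reference residue numbering


@dataclass
class ReferenceMap:
    """Maps 1-based alignment positions to 1-based reference residue numbers.

    Positions where the reference row carries a gap are unmapped (``None``)
    and are reported as such rather than silently shifted.
    """

    gene_name: str
    reference_id: str
    ap_to_ref: dict[int, int | None] = field(repr=False)

    def ref_position(self, ap: int) -> int | None:
        return self.ap_to_ref[ap]

    def format_position(self, ap: int) -> str:
        ref = self.ap_to_ref[ap]
        return f"{ap}(unmapped)" if ref is None else str(ref)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_name,
                "ap": list(self.ap_to_ref),
                "ref_pos": [
                    "unmapped" if v is None else v for v in self.ap_to_ref.values()
                ],
            }
        )


def build_reference_map(aln: LabeledAlignment) -> ReferenceMap:
    """Number alignment columns by cumulative non-gap count in the reference row."""
    if aln.reference_id is None:
        raise AlignmentError(f"{aln.gene_name}: no reference_id set")
    row = aln.rows[aln.sample_ids.index(aln.reference_id)]
    ap_to_ref: dict[int, int | None] = {}
    count = 0
    for ap, ch in enumerate(row, start=1):
        if ch == GAP:
            ap_to_ref[ap] = None
        else:
            count += 1
            ap_to_ref[ap] = count
    return ReferenceMap(aln.gene_name, aln.reference_id, ap_to_ref)
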