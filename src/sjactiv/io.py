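"""Readers and writers for junction tables, count matrices, mutation/segment
tables and serialized classifier models.

Conventions established here and relied on by every other module:

* Genomic coordinates are 1-based inclusive. Input in 0-based half-open
  convention can be converted on read via ``dialect="zero_based_half_open"``.
* Junction count matrices are junctions x samples with nonnegative integer
  entries; per-sample totals are always recomputed from the matrix.
* Models are serialized as JSON with full-precision floats so that a
  write -> read round trip is numerically exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .errors import ModelVersionError, SchemaError, ValidationError

MODEL_FORMAT_VERSION = "1"

_JUNCTION_COLUMNS = ["junction_id", "chrom", "start", "end", "strand", "annotated"]
_MUTATION_COLUMNS = ["sample_id", "gene", "variant_class"]
_SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Segment_Mean"]

KNOWN_GENES = {"KEAP1", "NFE2L2", "CUL3"}


@dataclass(frozen=True)
class JunctionRecord:
    """One splicing junction: the two genomic boundary coordinates of an
    excised intron, plus whether the junction appears in reference
    transcript annotation."""

    junction_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    annotated: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"junction {self.junction_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"junction {self.junction_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic alteration. ``gene`` collapses to 'other' for genes outside
    the KEAP1-NRF2 system; oncogenicity defaults to 'Unannotated' when the
    annotation column is absent."""

    sample_id: str
    gene: str
    variant_class: str
    exon: int | None = None
    oncogenicity: str = "Unannotated"
    protein_change: str | None = None


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment with its log2 copy-ratio (Segment_Mean)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    segment_mean: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: start > end"
            )


class CountMatrix:
    """Junction-by-sample matrix of nonnegative integer read counts.

    ``sample_totals`` are recomputed column sums — they are never trusted
    from upstream metadata, since selection-time normalization depends on
    them being exact.
    """

    def __init__(self, junction_ids: Sequence[str], sample_ids: Sequence[str], counts):
        counts = np.asarray(counts)
        if counts.shape != (len(junction_ids), len(sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(junction_ids)} junctions x {len(sample_ids)} samples"
            )
        if counts.size and not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValidationError("count matrix contains non-integer entries")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if len(set(junction_ids)) != len(junction_ids):
            raise ValidationError("duplicate junction ids in count matrix")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids in count matrix")
        self.junction_ids = list(junction_ids)
        self.sample_ids = list(sample_ids)
        self.counts = counts
        self._jidx = {j: i for i, j in enumerate(self.junction_ids)}
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def row(self, junction_id: str) -> np.ndarray:
        return self.counts[self._jidx[junction_id]]

    def junction_index(self, junction_id: str) -> int:
        return self._jidx[junction_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sidx[sample_id]

    def value(self, junction_id: str, sample_id: str) -> int:
        return int(self.counts[self._jidx[junction_id], self._sidx[sample_id]])

    def __eq__(self, other):
        return (
            isinstance(other, CountMatrix)
            and self.junction_ids == other.junction_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self):
        return f"CountMatrix({len(self.junction_ids)} junctions x {len(self.sample_ids)} samples)"


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_junction_table(path, dialect: str = "one_based") -> list[JunctionRecord]:
    """Read a TSV of junctions.

    Required columns: junction_id, chrom, start, end, strand, annotated.
    ``dialect`` is "one_based" (default, 1-based inclusive) or
    "zero_based_half_open" (BED-like; start is shifted by +1 on read).
    """
    if dialect not in ("one_based", "zero_based_half_open"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _JUNCTION_COLUMNS, f"junction table {path}")
    records = []
    seen = set()
    offset = 1 if dialect == "zero_based_half_open" else 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is header
        jid = str(row.junction_id)
        if jid in seen:
            raise ValidationError(f"{path} line {i}: duplicate junction_id {jid!r}")
        seen.add(jid)
        try:
            rec = JunctionRecord(
                junction_id=jid,
                chrom=str(row.chrom),
                start=int(row.start) + offset,
                end=int(row.end),
                strand=str(row.strand),
                annotated=_parse_bool(row.annotated),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
        records.append(rec)
    return records


def _parse_bool(x) -> bool:
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"cannot parse boolean {x!r}")


def write_junction_table(records: Sequence[JunctionRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "junction_id": r.junction_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "annotated": r.annotated,
            }
            for r in records
        ],
        columns=_JUNCTION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path, fmt: str | None = None, junctions: Sequence[JunctionRecord] | None = None) -> CountMatrix:
    """Read a junction-by-sample count matrix.

    ``fmt`` is "tsv" (dense; first column junction ids, header sample ids) or
    "matrixmarket" (a .mtx file with sibling ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` label files); inferred from the extension if omitted.
    If ``junctions`` is given, the matrix rows must exactly match its ids.
    """
    path = Path(path)
    if fmt is None:
        fmt = "matrixmarket" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        cm = CountMatrix([str(j) for j in df.index], [str(s) for s in df.columns], df.to_numpy())
    elif fmt == "matrixmarket":
        mat = mmread(path)
        rows = Path(str(path)[: -len(path.suffix)] + ".rows.txt").read_text().split()
        cols = Path(str(path)[: -len(path.suffix)] + ".cols.txt").read_text().split()
        dense = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        cm = CountMatrix(rows, cols, dense)
    else:
        raise ValueError(f"unknown count matrix format {fmt!r}")
    if junctions is not None:
        jids = [j.junction_id for j in junctions]
        if jids != cm.junction_ids:
            raise ValidationError(
                "count matrix rows do not match the junction table "
                f"({len(cm.junction_ids)} rows vs {len(jids)} junctions)"
            )
    return cm


def write_count_matrix(cm: CountMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "matrixmarket" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.DataFrame(cm.counts, index=cm.junction_ids, columns=cm.sample_ids)
        df.to_csv(path, sep="\t", index_label="junction_id")
    elif fmt == "matrixmarket":
        mmwrite(str(path), coo_matrix(cm.counts), field="integer")
        stem = str(path)[: -len(path.suffix)]
        Path(stem + ".rows.txt").write_text("\n".join(cm.junction_ids) + "\n")
        Path(stem + ".cols.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count matrix format {fmt!r}")


def read_mutations(path) -> list[MutationRecord]:
    """Read a MAF-like TSV of somatic alterations.

    Required columns: sample_id, gene, variant_class. Optional: exon,
    oncogenicity, protein_change. Gene symbols outside the KEAP1-NRF2
    system are collapsed to 'other' (permissive parse, no error).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _MUTATION_COLUMNS, f"mutation table {path}")
    has_onc = "oncogenicity" in df.columns
    has_exon = "exon" in df.columns
    has_prot = "protein_change" in df.columns
    records = []
    for row in df.itertuples(index=False):
        gene = str(row.gene)
        if gene not in KNOWN_GENES:
            gene = "other"
        exon = None
        if has_exon and not pd.isna(row.exon) and str(row.exon).strip() != "":
            exon = int(float(row.exon))
        onc = "Unannotated"
        if has_onc and not pd.isna(row.oncogenicity) and str(row.oncogenicity).strip() != "":
            onc = str(row.oncogenicity)
        prot = None
        if has_prot and not pd.isna(row.protein_change):
            prot = str(row.protein_change)
        records.append(
            MutationRecord(
                sample_id=str(row.sample_id),
                gene=gene,
                variant_class=str(row.variant_class),
                exon=exon,
                oncogenicity=onc,
                protein_change=prot,
            )
        )
    return records


def write_mutations(records: Sequence[MutationRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "variant_class": r.variant_class,
                "exon": r.exon,
                "oncogenicity": r.oncogenicity,
                "protein_change": r.protein_change,
            }
            for r in records
        ],
        columns=["sample_id", "gene", "variant_class", "exon", "oncogenicity", "protein_change"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[SegmentRecord]:
    """Read a SEG-like TSV (columns Sample, Chromosome, Start, End, Segment_Mean)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _SEG_COLUMNS, f"segment table {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SegmentRecord(
                    sample_id=str(row.Sample),
                    chrom=str(row.Chromosome),
                    start=int(row.Start),
                    end=int(row.End),
                    segment_mean=float(row.Segment_Mean),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_segments(records: Sequence[SegmentRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "Sample": r.sample_id,
                "Chromosome": r.chrom,
                "Start": r.start,
                "End": r.end,
                "Segment_Mean": r.segment_mean,
            }
            for r in records
        ],
        columns=_SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def save_model(model, path) -> None:
    """Serialize a ClassifierModel to JSON (full-precision floats)."""
    payload = {"format_version": MODEL_FORMAT_VERSION}
    payload.update(model.to_dict())
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path):
    """Load a ClassifierModel saved by :func:`save_model`."""
    from .classifier import ClassifierModel

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"model file {path} has format version {version!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION!r}"
        )
    return ClassifierModel.from_dict(payload)


def read_labels(path) -> pd.DataFrame:
    """Read a sample-label TSV (sample_id, top_mutation_class, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "label"], f"label table {path}")
    return df


def write_labels(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
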