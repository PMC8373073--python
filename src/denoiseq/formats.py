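"""Readers/writers for the standard formats the pipeline touches.

Internal conventions
--------------------
* Count matrices are genes x samples, raw (un-normalized) counts. Fractional
  values are legal because the noise-removal step adds a real-valued offset.
* Genomic coordinates are 0-based half-open internally. GTF/GFF3 (1-based
  inclusive) are converted at the boundary; BED is already half-open.
* Duplicate gene identifiers are an error, never silently aggregated:
  aggregation would change the abundance ranks the thresholding depends on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ConfigError, InputOutputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExonRecord",
    "ExonAnnotation",
    "CellMetadata",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "read_cell_metadata",
]


@dataclass
class CountMatrix:
    """A genes x samples matrix of non-negative raw counts.

    Counts may be fractional (the denoising offset adds the mean threshold
    to every entry), but never negative.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if self.counts.size and np.nanmin(self.counts) < 0:
            raise ValidationError("negative entries in count matrix")
        if self.counts.size and not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite entries in count matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(dtype=float),
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None


@dataclass(frozen=True)
class ExonRecord:
    """One exon, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    exon_rank: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )


@dataclass
class ExonAnnotation:
    """Exon records grouped by transcript; supplies transcript-space mapping."""

    records: list[ExonRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], ExonRecord] = {}
        for rec in self.records:
            key = (rec.transcript_id, rec.exon_rank)
            if key in seen:
                raise ValidationError(
                    f"duplicate exon rank {rec.exon_rank} in transcript "
                    f"{rec.transcript_id}"
                )
            seen[key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def transcripts(self) -> dict[str, list[ExonRecord]]:
        """Exons per transcript, sorted by exon rank."""
        out: dict[str, list[ExonRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.transcript_id, []).append(rec)
        for tid in out:
            out[tid].sort(key=lambda r: r.exon_rank)
        return out

    def genes(self) -> dict[str, list[ExonRecord]]:
        out: dict[str, list[ExonRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.gene_id, []).append(rec)
        return out


@dataclass
class CellMetadata:
    """Per-cell grouping labels (cell_id -> e.g. donor, time point)."""

    table: pd.DataFrame  # index: cell_id; columns: label keys

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate cell ids in metadata: {dups[:5]}")

    def labels(self, key: str) -> pd.Series:
        if key not in self.table.columns:
            raise ConfigError(f"metadata key {key!r} not present")
        return self.table[key]


# ---------------------------------------------------------------------------
# count matrices


def _infer_matrix_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    if suffix == ".mtx":
        return "mtx_triplet"
    raise ConfigError(f"cannot infer count-matrix format from {path.name!r}")


def read_count_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a genes x samples count matrix.

    Supported formats: ``csv``/``tsv`` (first column gene id, header row
    sample ids) and ``mtx_triplet`` (MatrixMarket file with companion
    ``features.tsv`` and ``barcodes.tsv`` in the same directory, genes as
    rows).
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"count matrix not found: {path}")
    fmt = format or _infer_matrix_format(path)
    if fmt in {"csv", "tsv"}:
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: empty file") from None
        except (pd.errors.ParserError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from None
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"{path}: duplicated gene identifiers {dups[:5]}")
        values = df.apply(pd.to_numeric, errors="coerce")
        bad = values.isna() & df.notna()
        if bad.to_numpy().any():
            row = int(np.argwhere(bad.to_numpy())[0, 0])
            raise ParseError(
                f"{path}: non-numeric entry at data line {row + 2}"
            )
        return CountMatrix.from_frame(values)
    if fmt == "mtx_triplet":
        features = path.parent / "features.tsv"
        barcodes = path.parent / "barcodes.tsv"
        if not features.exists() or not barcodes.exists():
            raise InputOutputError(
                f"mtx_triplet requires features.tsv and barcodes.tsv next to {path}"
            )
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
        gene_ids = [
            line.split("\t")[0].strip()
            for line in features.read_text().splitlines()
            if line.strip()
        ]
        sample_ids = [
            line.strip() for line in barcodes.read_text().splitlines() if line.strip()
        ]
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"{path}: matrix shape {dense.shape} inconsistent with "
                f"{len(gene_ids)} features / {len(sample_ids)} barcodes"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError(f"{path}: duplicated gene identifiers")
        return CountMatrix(gene_ids, sample_ids, dense)
    raise ConfigError(f"unknown count-matrix format {fmt!r}")


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a count matrix; round-trips through :func:`read_count_matrix`."""
    path = Path(path)
    fmt = format or _infer_matrix_format(path)
    try:
        if fmt in {"csv", "tsv"}:
            sep = "," if fmt == "csv" else "\t"
            df = matrix.to_frame()
            df.index.name = "gene_id"
            # repr-based float formatting keeps full precision in text
            df.to_csv(path, sep=sep, float_format="%.17g")
        elif fmt == "mtx_triplet":
            sparse = scipy.sparse.coo_matrix(matrix.counts)
            scipy.io.mmwrite(str(path), sparse)
            (path.parent / "features.tsv").write_text(
                "".join(f"{g}\n" for g in matrix.gene_ids)
            )
            (path.parent / "barcodes.tsv").write_text(
                "".join(f"{s}\n" for s in matrix.sample_ids)
            )
        else:
            raise ConfigError(f"unknown count-matrix format {fmt!r}")
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from None


# ---------------------------------------------------------------------------
# annotation

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")


def _parse_attributes(attr_field: str, dialect: str) -> dict[str, str]:
    pattern = _GTF_ATTR if dialect == "gtf" else _GFF3_ATTR
    return dict(pattern.findall(attr_field))


def read_annotation(path: str | Path, format: str | None = None) -> ExonAnnotation:
    """Read exon annotation from GTF, GFF3, or BED.

    GTF/GFF3 use 1-based inclusive coordinates and are converted to the
    internal 0-based half-open convention; BED intervals are taken as-is.
    Only ``exon`` feature lines are kept from GTF/GFF3. Overlapping exons of
    one transcript are retained as distinct records (and logged).
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"annotation not found: {path}")
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"gtf": "gtf", "gff3": "gff3", "gff": "gff3", "bed": "bed"}.get(suffix)
        if format is None:
            raise ConfigError(f"cannot infer annotation format from {path.name!r}")
    if format not in {"gtf", "gff3", "bed"}:
        raise ConfigError(f"unknown annotation format {format!r}")

    records: list[ExonRecord] = []
    rank_counter: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if format == "bed":
                if len(fields) < 3:
                    raise ValueError("fewer than 3 BED columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
                strand = fields[5] if len(fields) > 5 else "+"
                rank_counter[name] = rank_counter.get(name, 0) + 1
                records.append(
                    ExonRecord(chrom, start, end, strand, name, name,
                               rank_counter[name])
                )
            else:
                if len(fields) < 9:
                    raise ValueError("fewer than 9 GTF/GFF3 columns")
                if fields[2].lower() != "exon":
                    continue
                chrom, start, end, strand = (
                    fields[0], int(fields[3]), int(fields[4]), fields[6],
                )
                attrs = _parse_attributes(fields[8], "gtf" if format == "gtf" else "gff3")
                tid = attrs.get("transcript_id") or attrs.get("Parent")
                gid = attrs.get("gene_id") or attrs.get("gene") or tid
                if tid is None:
                    raise ValueError("exon without transcript_id/Parent")
                rank = attrs.get("exon_number")
                if rank is None:
                    rank_counter[tid] = rank_counter.get(tid, 0) + 1
                    rank = rank_counter[tid]
                # GTF/GFF3 1-based inclusive -> 0-based half-open
                records.append(
                    ExonRecord(chrom, start - 1, end, strand, gid, tid, int(rank))
                )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None

    annotation = ExonAnnotation(records)
    for tid, exons in annotation.transcripts().items():
        ordered = sorted(exons, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                logger.info("transcript %s has overlapping exons (retained)", tid)
                break
    return annotation


def read_cell_metadata(path: str | Path) -> CellMetadata:
    """Read a TSV of cell metadata: first column cell_id, rest label keys."""
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"metadata not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    return CellMetadata(df)
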