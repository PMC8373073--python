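"""Noise removal: drop genes below threshold in every sample, offset the rest.

A gene is removed only when its count is below the sample-specific noise
threshold in *every* sample — a gene reliably expressed in even one sample is
kept everywhere. The arithmetic mean of the per-sample thresholds is then
added to every retained entry, lifting the matrix minimum away from zero so
that downstream fold-change-based methods do not inflate differences between
very low abundances.

Alignment files can be filtered with the same every-sample rule: reads
assigned to genes that fail it are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .errors import ValidationError
from .formats import CountMatrix, ExonAnnotation
from .thresholding import NoiseThresholds

logger = logging.getLogger(__name__)

__all__ = ["DenoiseReport", "filter_count_matrix", "filter_alignments"]


@dataclass
class DenoiseReport:
    """Bookkeeping of one noise-removal pass."""

    genes_in: int
    genes_removed: int
    genes_retained: int
    mean_threshold: float
    theta: dict[str, float]

    def __post_init__(self) -> None:
        if self.genes_in != self.genes_removed + self.genes_retained:
            raise ValidationError("removed + retained must equal input genes")

    def to_dict(self) -> dict:
        return {
            "genes_in": self.genes_in,
            "genes_removed": self.genes_removed,
            "genes_retained": self.genes_retained,
            "mean_threshold": self.mean_threshold,
            "theta": self.theta,
        }


def _aligned_thetas(matrix: CountMatrix, thresholds: NoiseThresholds) -> np.ndarray:
    missing = set(matrix.sample_ids) - set(thresholds.sample_ids)
    if missing:
        raise ValidationError(
            f"thresholds missing for samples: {sorted(missing)}"
        )
    return np.array([thresholds.theta_for(s) for s in matrix.sample_ids])


def removal_mask(matrix: CountMatrix, thresholds: NoiseThresholds) -> np.ndarray:
    """Boolean mask of genes to remove: below theta in every determined sample."""
    theta = _aligned_thetas(matrix, thresholds)
    determined = np.isfinite(theta)
    if not determined.any():
        raise ValidationError("no sample has a determined threshold")
    below = matrix.counts[:, determined] < theta[determined]
    return below.all(axis=1)


def filter_count_matrix(
    matrix: CountMatrix,
    thresholds: NoiseThresholds,
    round_counts: bool = False,
) -> tuple[CountMatrix, DenoiseReport]:
    """Remove every-sample-noisy genes and add the mean threshold offset.

    Counts equal to the threshold survive (strict "below"). The offset is the
    mean of the determined per-sample thresholds, added after removal, so the
    output minimum equals ``mean_threshold + min(retained raw counts)``.
    Output counts are real-valued unless ``round_counts`` requests
    round-half-even integers for downstream tools that insist on integers.
    """
    remove = removal_mask(matrix, thresholds)
    offset = thresholds.mean_threshold
    keep = ~remove
    if not keep.any():
        logger.warning("all %d genes fall below the noise thresholds", matrix.n_genes)
    counts = matrix.counts[keep, :] + offset
    if round_counts:
        counts = np.round(counts)
    filtered = CountMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
        counts=counts,
    )
    theta_map = dict(zip(thresholds.sample_ids, (float(t) for t in thresholds.theta)))
    report = DenoiseReport(
        genes_in=matrix.n_genes,
        genes_removed=int(remove.sum()),
        genes_retained=int(keep.sum()),
        mean_threshold=float(offset),
        theta=theta_map,
    )
    logger.info(
        "removed %d of %d genes; offset %.4g added to retained entries",
        report.genes_removed, report.genes_in, offset,
    )
    return filtered, report


def _failing_genes(
    abundances: pd.DataFrame, thresholds: NoiseThresholds
) -> set[str]:
    theta = np.array([thresholds.theta_for(s) for s in abundances.columns])
    determined = np.isfinite(theta)
    if not determined.any():
        raise ValidationError("no sample has a determined threshold")
    below = abundances.to_numpy()[:, determined] < theta[determined]
    return {g for g, fail in zip(abundances.index, below.all(axis=1)) if fail}


def filter_alignments(
    bam_paths: Mapping[str, str | Path],
    annotation: ExonAnnotation,
    thresholds: NoiseThresholds,
    abundances: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Drop alignments of genes that fall below the threshold in every sample.

    ``abundances`` is a gene x sample table (e.g. the abundance frame of a
    :class:`~denoiseq.transcript_approach.TranscriptProfileSet` aggregated per
    gene). Reads not assigned to any annotated gene are kept and counted.
    Output BAMs carry an extra @PG record.
    """
    failing = _failing_genes(abundances, thresholds)
    logger.info("%d gene(s) fail the every-sample rule", len(failing))

    trees: dict[str, IntervalTree] = {}
    for rec in annotation.records:
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec.gene_id)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    for sample, path in bam_paths.items():
        path = Path(path)
        out_path = out_dir / f"{path.stem}.denoised.bam"
        n_unassigned = 0
        with pysam.AlignmentFile(str(path), "rb") as bam:
            header = bam.header.to_dict()
            header.setdefault("PG", []).append(
                {"ID": "denoiseq", "PN": "denoiseq", "CL": "filter-bam"}
            )
            with pysam.AlignmentFile(str(out_path), "wb", header=header) as out:
                for read in bam.fetch(until_eof=True):
                    genes: set[str] = set()
                    if not read.is_unmapped and read.reference_name in trees:
                        for blk_start, blk_end in read.get_blocks():
                            for iv in trees[read.reference_name].overlap(
                                blk_start, blk_end
                            ):
                                genes.add(iv.data)
                    if not genes:
                        n_unassigned += 1
                        out.write(read)
                    elif genes - failing:
                        # keep unless every overlapped gene fails
                        out.write(read)
        pysam.index(str(out_path))
        if n_unassigned:
            logger.info(
                "%s: %d unassigned alignment(s) kept", path.name, n_unassigned
            )
        outputs[sample] = out_path
    return outputs
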