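"""Per-transcript coverage profiles from alignments and their cross-sample
point-to-point consistency (p2pPCC).

For each transcript, the expression profile in a sample is the point sum of
the abundances of reads incident to every transcript position (exons
concatenated in rank order, minus-strand transcripts reversed). Per-read
alignments contribute +1 per covered position; collapsed small-RNA reads can
carry a multiplicity suffix ``_xN`` in the read name.

The point-to-point Pearson correlation between a transcript's profile in one
sample and in every other sample, averaged, is a proxy for how
deterministically reads are distributed across the transcript: for
low-abundance transcripts the placement of the few reads is stochastic and
the correlation is low, while abundant transcripts yield reproducible
profiles. Binning these correlations on log2 abundance ranges yields the
boxplot statistics the IQR threshold method consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .binning import BinnedStats, bin_similarity_values
from .errors import InputOutputError, ValidationError
from .formats import ExonAnnotation, ExonRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptProfileSet",
    "build_profiles",
    "p2p_correlation",
    "transcript_similarity_table",
    "bin_by_abundance",
]

_COLLAPSED_NAME = re.compile(r"_x(\d+)$")


@dataclass
class TranscriptProfileSet:
    """Coverage profiles per (transcript, sample) with summed abundances.

    ``profiles[transcript][sample]`` is the positional coverage vector in
    transcript space; ``abundance.loc[transcript, sample]`` is the total
    abundance assigned (number of alignment increments, or the sum of
    collapsed-read multiplicities).
    """

    sample_ids: list[str]
    profiles: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    abundance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.abundance is None:
            self.abundance = pd.DataFrame(
                0.0, index=list(self.profiles), columns=self.sample_ids
            )
        for tid, per_sample in self.profiles.items():
            lengths = {len(v) for v in per_sample.values()}
            if len(lengths) > 1:
                raise ValidationError(
                    f"transcript {tid}: profile lengths differ across samples"
                )
            for vec in per_sample.values():
                if vec.size and vec.min() < 0:
                    raise ValidationError(f"transcript {tid}: negative coverage")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.profiles)


def _transcript_position_map(
    exons: Sequence[ExonRecord],
) -> tuple[str, list[tuple[int, int, int]], int]:
    """Per-exon (genomic_start, genomic_end, transcript_offset) and length.

    Exons are concatenated in rank order; for minus-strand transcripts the
    final profile vector is reversed so position 0 is the transcript 5' end.
    """
    chrom = exons[0].chrom
    offset = 0
    segments = []
    for exon in exons:
        if exon.chrom != chrom:
            raise ValidationError(
                f"transcript {exon.transcript_id} spans multiple chromosomes"
            )
        segments.append((exon.start, exon.end, offset))
        offset += exon.end - exon.start
    return chrom, segments, offset


def _read_abundance(read: pysam.AlignedSegment, collapsed_names: bool) -> float:
    if collapsed_names:
        m = _COLLAPSED_NAME.search(read.query_name or "")
        if m:
            return float(m.group(1))
    return 1.0


def build_profiles(
    bam_paths: Mapping[str, str | Path | Sequence[str | Path]],
    annotation: ExonAnnotation,
    collapsed_names: bool = False,
    include_secondary: bool = False,
) -> TranscriptProfileSet:
    """Point-sum coverage profiles per transcript and sample from BAM files.

    ``bam_paths`` maps sample id to a coordinate-sorted, indexed BAM path —
    or to a list of paths whose coverage is summed, which treats a group of
    concatenated alignment files (e.g. cells pooled into a pseudo-sample) as
    one sample. Every primary alignment overlapping an exon adds its
    abundance to each transcript position it covers and increments the
    transcript's abundance once.
    """
    if not len(annotation):
        raise ValidationError("empty annotation")
    transcripts = annotation.transcripts()
    sample_ids = list(bam_paths)

    layouts = {
        tid: _transcript_position_map(exons) for tid, exons in transcripts.items()
    }
    profiles: dict[str, dict[str, np.ndarray]] = {
        tid: {s: np.zeros(layouts[tid][2]) for s in sample_ids} for tid in transcripts
    }
    abundance = pd.DataFrame(0.0, index=list(transcripts), columns=sample_ids)

    for sample in sample_ids:
        paths = bam_paths[sample]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        for path in paths:
            path = Path(path)
            if not path.exists():
                raise InputOutputError(f"alignment file not found: {path}")
            index_missing = not (
                Path(str(path) + ".bai").exists()
                or path.with_suffix(".bai").exists()
                or Path(str(path) + ".csi").exists()
            )
            if index_missing:
                raise InputOutputError(f"BAM index missing for {path}")
            with pysam.AlignmentFile(str(path), "rb") as bam:
                valid_chroms = set(bam.references)
                for tid, exons in transcripts.items():
                    chrom, segments, length = layouts[tid]
                    if chrom not in valid_chroms:
                        logger.warning(
                            "chromosome %s absent from %s header; skipping "
                            "transcript %s", chrom, path.name, tid,
                        )
                        continue
                    coverage = profiles[tid][sample]
                    seen: set[tuple] = set()
                    for start, end, offset in segments:
                        for read in bam.fetch(chrom, start, end):
                            if read.is_unmapped:
                                continue
                            if not include_secondary and (
                                read.is_secondary or read.is_supplementary
                            ):
                                continue
                            key = (read.query_name, read.flag, read.reference_start)
                            weight = _read_abundance(read, collapsed_names)
                            covered = False
                            for blk_start, blk_end in read.get_blocks():
                                lo = max(blk_start, start)
                                hi = min(blk_end, end)
                                if lo < hi:
                                    coverage[
                                        offset + lo - start : offset + hi - start
                                    ] += weight
                                    covered = True
                            if covered and key not in seen:
                                seen.add(key)
                                abundance.loc[tid, sample] += weight
    # minus-strand reversal once, after all files of every sample are summed
    for tid, exons in transcripts.items():
        if exons[0].strand == "-":
            for sample in sample_ids:
                profiles[tid][sample] = profiles[tid][sample][::-1]

    return TranscriptProfileSet(
        sample_ids=sample_ids, profiles=profiles, abundance=abundance
    )


def p2p_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Point-to-point Pearson correlation of two positional coverage vectors.

    Zero-variance input on either side (e.g. an unexpressed transcript)
    yields 0: a flat profile carries no evidence of reproducible signal.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def transcript_similarity_table(profiles: TranscriptProfileSet) -> pd.DataFrame:
    """Per (transcript, sample): abundance and mean p2pPCC vs other samples.

    Columns: ``transcript_id``, ``sample_id``, ``abundance``, ``similarity``.
    """
    if len(profiles.sample_ids) < 2:
        raise ValidationError("need >= 2 samples to assess profile consistency")
    rows = []
    for tid in profiles.transcript_ids:
        per_sample = profiles.profiles[tid]
        for j in profiles.sample_ids:
            sims = [
                p2p_correlation(per_sample[j], per_sample[k])
                for k in profiles.sample_ids
                if k != j
            ]
            rows.append(
                {
                    "transcript_id": tid,
                    "sample_id": j,
                    "abundance": float(profiles.abundance.loc[tid, j]),
                    "similarity": float(np.mean(sims)),
                }
            )
    return pd.DataFrame(rows)


def bin_by_abundance(
    records: pd.DataFrame, base: float = 2.0
) -> dict[str, BinnedStats]:
    """Per-sample log-spaced abundance binning of p2pPCC records."""
    if records.empty:
        raise ValidationError("no records to bin")
    out = {}
    for sample, chunk in records.groupby("sample_id", sort=False):
        out[str(sample)] = bin_similarity_values(
            chunk["abundance"].to_numpy(), chunk["similarity"].to_numpy(), base=base
        )
    return out
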