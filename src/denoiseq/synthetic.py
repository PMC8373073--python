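"""Synthetic data generators with the statistical structure the method assumes.

Three generators cover the pipeline's inputs:

* :func:`generate_count_matrix` — a count matrix with a designed noise floor
  ``F``: genes whose base abundance lies above ``F`` share that abundance
  across samples (Poisson counts around a common mean with small lognormal
  sample wobble, hence correlated), while genes below ``F`` are drawn
  independently per sample at comparable magnitudes (hence uncorrelated).
  This realizes the defining feature of technical noise in sequencing
  counts: cross-sample similarity rises with abundance, from a flat floor to
  a reproducible-signal plateau around ``F``.
* :func:`generate_coverage_experiment` — per-transcript read placements:
  each transcript owns one smooth positive shape shared by all samples;
  every sample drops its assigned number of reads multinomially by that
  shape. Few reads place stochastically (low p2pPCC), many reads converge to
  the shape (p2pPCC -> 1). Emits valid SAM text plus the exact pileup truth.
* :func:`generate_network_variants` — weighted networks with planted binary
  edge flips and exact per-gene Hamming ground truth.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ValidationError
from .formats import CountMatrix, ExonAnnotation, ExonRecord
from .network import WeightedNetwork
from .transcript_approach import TranscriptProfileSet

__all__ = [
    "NoiseFloorDesign",
    "generate_count_matrix",
    "CoverageExperiment",
    "generate_coverage_experiment",
    "generate_network_variants",
    "sam_to_indexed_bam",
]

ABUNDANCE_LOG2_RANGE = (0.0, 14.0)  # base abundances log-uniform on [1, 2^14]


@dataclass(frozen=True)
class NoiseFloorDesign:
    """Design of a noise-floor count matrix.

    ``noise_floor`` is the abundance below which quantification is
    uncorrelated across samples; ``signal_dispersion`` is the lognormal sigma
    of the per-(gene, sample) wobble on the shared signal mean.
    """

    n_genes: int = 5000
    n_samples: int = 4
    noise_floor: float = 32.0
    signal_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_floor <= 0:
            raise ValidationError("noise_floor must be positive")
        if self.n_samples < 2:
            raise ValidationError("need at least two samples")
        if self.n_genes < 1:
            raise ValidationError("need at least one gene")


def generate_count_matrix(
    design: NoiseFloorDesign,
) -> tuple[CountMatrix, np.ndarray]:
    """Count matrix with a designed noise floor, plus per-gene truth labels.

    Returns the matrix and an array of labels ``"signal"``/``"noise"``
    partitioning the genes.
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = ABUNDANCE_LOG2_RANGE
    lam = 2.0 ** rng.uniform(lo, hi, design.n_genes)
    is_signal = lam >= design.noise_floor

    counts = np.zeros((design.n_genes, design.n_samples))
    n_signal = int(is_signal.sum())
    if n_signal:
        eps = rng.lognormal(
            mean=0.0, sigma=design.signal_dispersion,
            size=(n_signal, design.n_samples),
        )
        counts[is_signal] = rng.poisson(lam[is_signal, None] * eps)
    n_noise = design.n_genes - n_signal
    if n_noise:
        # independent per-sample abundance at comparable (sub-floor) magnitude
        log2_floor = np.log2(design.noise_floor)
        lam_noise = 2.0 ** rng.uniform(
            lo, max(lo + 1e-9, log2_floor), size=(n_noise, design.n_samples)
        )
        counts[~is_signal] = rng.poisson(lam_noise)

    matrix = CountMatrix(
        gene_ids=[f"g{i:05d}" for i in range(design.n_genes)],
        sample_ids=[f"s{j + 1}" for j in range(design.n_samples)],
        counts=counts,
    )
    labels = np.where(is_signal, "signal", "noise")
    return matrix, labels


def _smooth_shape(length: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth, strictly positive profile shape over transcript positions."""
    rough = rng.normal(size=length)
    width = max(5, length // 20)
    kernel = np.exp(-0.5 * (np.linspace(-3, 3, width) ** 2))
    kernel /= kernel.sum()
    smooth = np.convolve(rough, kernel, mode="same")
    shape = np.exp(smooth)
    return shape / shape.sum()


@dataclass
class CoverageExperiment:
    """Ground truth and lazily rendered SAM text of a coverage simulation.

    ``placements[sample][transcript]`` holds the number of reads starting at
    every admissible start position; ``truth`` contains the exact pileups the
    alignment reader must reproduce.
    """

    transcript_ids: list[str]
    transcript_length: int
    read_length: int
    depths: dict[str, int]  # transcript -> assigned depth
    sample_ids: list[str]
    placements: dict[str, dict[str, np.ndarray]]
    truth: TranscriptProfileSet = field(repr=False)

    def sam_text(self, sample_id: str) -> str:
        """Valid coordinate-sorted SAM for one sample."""
        lines = ["@HD\tVN:1.6\tSO:coordinate"]
        for tid in self.transcript_ids:
            lines.append(f"@SQ\tSN:{tid}\tLN:{self.transcript_length}")
        rl = self.read_length
        seq = "A" * rl
        qual = "I" * rl
        for tid in self.transcript_ids:
            starts = self.placements[sample_id][tid]
            serial = 0
            for start in np.nonzero(starts)[0]:
                for _ in range(int(starts[start])):
                    lines.append(
                        f"r_{tid}_{sample_id}_{serial}\t0\t{tid}\t{start + 1}\t60"
                        f"\t{rl}M\t*\t0\t0\t{seq}\t{qual}"
                    )
                    serial += 1
        return "\n".join(lines) + "\n"

    def write_sam(self, sample_id: str, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.sam_text(sample_id))
        return path

    def annotation(self) -> ExonAnnotation:
        """Single-exon annotation matching the synthetic references."""
        return ExonAnnotation(
            [
                ExonRecord(tid, 0, self.transcript_length, "+", tid, tid, 1)
                for tid in self.transcript_ids
            ]
        )

    def write_annotation_bed(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [
            f"{tid}\t0\t{self.transcript_length}\t{tid}\t0\t+"
            for tid in self.transcript_ids
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    def to_indexed_bams(self, out_dir: str | Path) -> dict[str, Path]:
        """Render every sample to a coordinate-sorted, indexed BAM."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bams = {}
        for sample in self.sample_ids:
            sam_path = out_dir / f"{sample}.sam"
            self.write_sam(sample, sam_path)
            bams[sample] = sam_to_indexed_bam(sam_path, out_dir / f"{sample}.bam")
        return bams


def sam_to_indexed_bam(sam_path: str | Path, bam_path: str | Path) -> Path:
    """Convert coordinate-sorted SAM text into an indexed BAM."""
    sam_path, bam_path = Path(sam_path), Path(bam_path)
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        with pysam.AlignmentFile(str(bam_path), "wb", template=sam) as bam:
            for read in sam.fetch(until_eof=True):
                bam.write(read)
    pysam.index(str(bam_path))
    return bam_path


def generate_coverage_experiment(
    n_transcripts: int = 8,
    transcript_length: int = 500,
    depths=(5, 50, 500, 5000),
    n_samples: int = 2,
    seed: int = 0,
    read_length: int = 50,
) -> CoverageExperiment:
    """Multinomial read placements over shared per-transcript shapes.

    Depths are assigned to transcripts cyclically from the ladder. Each
    sample's reads are placed independently, so cross-sample profile
    correlation grows with depth.
    """
    if read_length > transcript_length:
        raise ValidationError("read length exceeds transcript length")
    if any(d < 0 for d in depths):
        raise ValidationError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    transcript_ids = [f"tx{i:03d}" for i in range(n_transcripts)]
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    depth_map = {
        tid: int(depths[i % len(depths)]) for i, tid in enumerate(transcript_ids)
    }

    n_starts = transcript_length - read_length + 1
    placements: dict[str, dict[str, np.ndarray]] = {s: {} for s in sample_ids}
    profiles: dict[str, dict[str, np.ndarray]] = {tid: {} for tid in transcript_ids}
    abundance = pd.DataFrame(0.0, index=transcript_ids, columns=sample_ids)

    for tid in transcript_ids:
        start_probs = _smooth_shape(transcript_length, rng)[:n_starts]
        start_probs = start_probs / start_probs.sum()
        for sample in sample_ids:
            starts = rng.multinomial(depth_map[tid], start_probs)
            placements[sample][tid] = starts
            # exact pileup via the difference-array trick
            diff = np.zeros(transcript_length + 1)
            np.add.at(diff, np.arange(n_starts), starts)
            np.add.at(diff, np.arange(n_starts) + read_length, -starts)
            profiles[tid][sample] = np.cumsum(diff[:-1])
            abundance.loc[tid, sample] = float(starts.sum())

    truth = TranscriptProfileSet(
        sample_ids=sample_ids, profiles=profiles, abundance=abundance
    )
    return CoverageExperiment(
        transcript_ids=transcript_ids,
        transcript_length=transcript_length,
        read_length=read_length,
        depths=depth_map,
        sample_ids=sample_ids,
        placements=placements,
        truth=truth,
    )


def generate_network_variants(
    n_genes: int,
    flip_counts: dict[str, int],
    seed: int = 0,
    labels_base: str = "-F-N",
) -> tuple[dict[str, WeightedNetwork], dict[str, pd.Series]]:
    """Weighted networks whose binarizations differ by planted edge flips.

    The base network's off-diagonal weights come from two well-separated
    clouds (low: U(0, 0.2); high: U(0.8, 1.0)) in equal numbers — ``n(n-1)``
    is always even — so the off-diagonal median falls strictly between the
    clouds and binarization is exact. A variant with ``k`` planted flips
    swaps the values of ``k/2`` low and ``k/2`` high off-diagonal positions,
    preserving the weight multiset (hence the median) while flipping exactly
    ``k`` binary entries. ``k`` must therefore be even.

    Returns the labeled networks (the base under ``labels_base``) and the
    exact per-gene Hamming distances of each variant against the base.
    """
    if n_genes < 2:
        raise ValidationError("need at least two genes")
    max_flips = n_genes * (n_genes - 1)
    rng = np.random.default_rng(seed)

    offdiag = [(i, j) for i in range(n_genes) for j in range(n_genes) if i != j]
    m = len(offdiag)
    half = m // 2
    values = np.concatenate(
        [rng.uniform(0.0, 0.2, half), rng.uniform(0.8, 1.0, m - half)]
    )
    values = values[rng.permutation(m)]
    base = np.zeros((n_genes, n_genes))
    for (i, j), v in zip(offdiag, values):
        base[i, j] = v

    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    networks = {labels_base: WeightedNetwork(gene_ids, base.copy())}
    truths: dict[str, pd.Series] = {
        labels_base: pd.Series(0, index=gene_ids, name="hamming")
    }

    median = np.median(values)
    low_positions = [p for p, v in zip(offdiag, values) if v <= median]
    high_positions = [p for p, v in zip(offdiag, values) if v > median]

    for label, k in flip_counts.items():
        if k < 0 or k > max_flips:
            raise ValidationError(f"flip count {k} out of range for {n_genes} genes")
        if k % 2 != 0:
            raise ValidationError(
                "flip counts must be even: flips are planted as low/high value "
                "swaps so the network median is preserved exactly"
            )
        k_half = k // 2
        if k_half > min(len(low_positions), len(high_positions)):
            raise ValidationError(f"flip count {k} too large for the cloud sizes")
        lows = rng.choice(len(low_positions), size=k_half, replace=False)
        highs = rng.choice(len(high_positions), size=k_half, replace=False)
        weights = base.copy()
        flipped_rows = np.zeros(n_genes, dtype=int)
        for li, hi_ in zip(lows, highs):
            (i1, j1), (i2, j2) = low_positions[li], high_positions[hi_]
            weights[i1, j1], weights[i2, j2] = weights[i2, j2], weights[i1, j1]
            flipped_rows[i1] += 1
            flipped_rows[i2] += 1
        networks[label] = WeightedNetwork(gene_ids, weights)
        truths[label] = pd.Series(flipped_rows, index=gene_ids, name="hamming")

    return networks, truths
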