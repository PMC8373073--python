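"""One-call pipeline: similarity profiling -> noise thresholds -> removal.

:func:`run_pipeline` wires the three stages together for either input
approach (count matrix, or alignments + annotation), resolves the "auto"
hyper-parameters (window length, similarity threshold), and writes
deterministic, machine-readable outputs plus a run manifest recording every
resolved parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .count_approach import (
    SimilarityProfile,
    WindowSpec,
    default_window_spec,
    infer_window_length_entropy,
    infer_window_length_monotony,
    profile_all_samples,
)
from .denoise import DenoiseReport, filter_count_matrix
from .errors import ConfigError, ValidationError
from .formats import (
    CountMatrix,
    read_annotation,
    read_cell_metadata,
    read_count_matrix,
    write_count_matrix,
)
from .single_cell import metadata_grouping, random_grouping, summarize_pseudo_samples
from .synthetic import sam_to_indexed_bam
from .thresholding import (
    DEFAULT_GRID,
    NoiseThresholds,
    optimize_similarity_threshold,
    profile_to_binned_stats,
    threshold_from_binned_stats,
    threshold_from_profile_line,
)
from .transcript_approach import (
    bin_by_abundance,
    build_profiles,
    transcript_similarity_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_profiles_tsv", "read_profiles_tsv"]

DEFAULT_METHODS = {"counts": "boxplot_median", "transcripts": "boxplot_IQR"}


@dataclass
class RunConfig:
    """Resolved or resolvable options of one pipeline run."""

    approach: str  # "counts" | "transcripts"
    matrix: str | None = None
    bams: list[str] = field(default_factory=list)
    annotation: str | None = None
    measure: str = "pearson"
    window_length: int | str = "auto"  # "auto" = 10% of genes
    step_fraction: float = 0.05
    window_inference: str = "default"  # default | monotony | entropy
    method: str | None = None  # None -> per-approach default
    c: float | str = "auto"
    smoothing_width: int = 5
    group_by: str | None = None  # metadata key, or "random"
    metadata: str | None = None
    n_groups: int = 5
    collapsed_names: bool = False
    round_counts: bool = False
    seed: int = 0
    out_dir: str = "denoiseq_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.approach not in {"counts", "transcripts"}:
            raise ConfigError(f"unknown approach {self.approach!r}")
        if self.approach == "counts" and not self.matrix:
            raise ConfigError("counts approach requires a count matrix")
        if self.approach == "transcripts" and (not self.bams or not self.annotation):
            raise ConfigError("transcripts approach requires BAM/SAM files and annotation")
        if self.group_by == "random" and self.n_groups < 2:
            raise ConfigError("random grouping needs n_groups >= 2")
        if self.group_by and self.group_by != "random" and not self.metadata:
            raise ConfigError("metadata grouping requires a metadata table")


def write_profiles_tsv(profiles: dict[str, SimilarityProfile], path: Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample": p.sample_id,
                "window_abundance": p.window_abundance,
                "similarity": p.window_similarity,
            }
        )
        for p in profiles.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_profiles_tsv(path: str | Path) -> dict[str, SimilarityProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "window_abundance", "similarity"}
    if not required.issubset(df.columns):
        raise ValidationError(f"profile table needs columns {sorted(required)}")
    out = {}
    for sample, chunk in df.groupby("sample", sort=False):
        out[str(sample)] = SimilarityProfile(
            str(sample),
            chunk["window_abundance"].to_numpy(),
            chunk["similarity"].to_numpy(),
        )
    return out


def _resolve_window_spec(config: RunConfig, matrix: CountMatrix) -> WindowSpec:
    if config.window_length == "auto":
        if config.window_inference == "default":
            return default_window_spec(matrix.n_genes, step_fraction=config.step_fraction)
        n = matrix.n_genes
        candidates = sorted(
            {max(2, round(f * n)) for f in (0.02, 0.05, 0.10, 0.20, 0.40)}
        )
        if config.window_inference == "monotony":
            length = infer_window_length_monotony(
                matrix, candidates, config.measure, config.step_fraction
            )
        elif config.window_inference == "entropy":
            length = infer_window_length_entropy(
                matrix, candidates, config.measure, step_fraction=config.step_fraction
            )
        else:
            raise ConfigError(f"unknown window inference {config.window_inference!r}")
        return WindowSpec(length, max(1, round(config.step_fraction * length)))
    length = int(config.window_length)
    return WindowSpec(length, max(1, round(config.step_fraction * length)))


def _thresholds_fixed_c(
    per_sample, c: float, method: str, smoothing_width: int
) -> NoiseThresholds:
    thetas = []
    for data in per_sample.values():
        if method == "line_smoothed":
            thetas.append(threshold_from_profile_line(data, c, smoothing_width))
        else:
            binned = (
                profile_to_binned_stats(data)
                if isinstance(data, SimilarityProfile)
                else data
            )
            statistic = "median" if method == "boxplot_median" else "Q1"
            thetas.append(threshold_from_binned_stats(binned, c, statistic))
    return NoiseThresholds(list(per_sample), np.asarray(thetas), c, method)


def run_pipeline(
    config: RunConfig,
) -> tuple[NoiseThresholds, CountMatrix, DenoiseReport]:
    """Execute profile -> threshold -> filter and write all outputs.

    Outputs in ``config.out_dir``: ``profile.tsv`` (per-sample
    abundance/similarity relation), ``thresholds.tsv``, ``denoised.tsv``,
    ``report.json``, and ``manifest.json`` with the resolved parameters.
    On error, partially written outputs are removed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        resolved: dict = {"approach": config.approach, "seed": config.seed}

        stage = "similarity"
        if config.approach == "counts":
            matrix = read_count_matrix(config.matrix)
            if config.group_by:
                if config.group_by == "random":
                    grouping = random_grouping(
                        matrix.sample_ids, config.n_groups, config.seed
                    )
                else:
                    metadata = read_cell_metadata(config.metadata)
                    grouping = metadata_grouping(metadata, config.group_by)
                cell_matrix = matrix
                matrix = summarize_pseudo_samples(matrix, grouping)
                resolved["grouping"] = grouping.provenance
            else:
                cell_matrix = None
            spec = _resolve_window_spec(config, matrix)
            resolved["window_length"] = spec.window_length
            resolved["step"] = spec.step
            profiles = profile_all_samples(matrix, spec, config.measure)
            per_sample: dict = profiles
            abundance_matrix = matrix
        else:
            annotation = read_annotation(config.annotation)
            bam_paths = {}
            for raw in config.bams:
                path = Path(raw)
                sample = path.stem
                if path.suffix.lower() == ".sam":
                    path = sam_to_indexed_bam(path, out_dir / f"{sample}.bam")
                    written.append(path)
                bam_paths[sample] = path
            profile_set = build_profiles(
                bam_paths, annotation, collapsed_names=config.collapsed_names
            )
            table = transcript_similarity_table(profile_set)
            per_sample = bin_by_abundance(table)
            profiles = None
            abundance_matrix = CountMatrix(
                gene_ids=list(profile_set.abundance.index),
                sample_ids=list(profile_set.abundance.columns),
                counts=profile_set.abundance.to_numpy(),
            )
            cell_matrix = None
            table_path = out_dir / "p2p.tsv"
            table.to_csv(table_path, sep="\t", index=False, float_format="%.17g")
            written.append(table_path)

        if profiles is not None:
            profile_path = out_dir / "profile.tsv"
            write_profiles_tsv(profiles, profile_path)
            written.append(profile_path)

        stage = "thresholding"
        method = config.method or DEFAULT_METHODS[config.approach]
        resolved["method"] = method
        resolved["measure"] = config.measure
        if config.c == "auto":
            c_star, thresholds = optimize_similarity_threshold(
                per_sample, DEFAULT_GRID, method, smoothing_width=config.smoothing_width
            )
        else:
            c_star = float(config.c)
            thresholds = _thresholds_fixed_c(
                per_sample, c_star, method, config.smoothing_width
            )
        resolved["c"] = c_star
        thresholds_path = out_dir / "thresholds.tsv"
        thresholds.to_frame().to_csv(
            thresholds_path, sep="\t", index=False, float_format="%.17g"
        )
        written.append(thresholds_path)

        stage = "noise removal"
        denoised, report = filter_count_matrix(
            abundance_matrix, thresholds, round_counts=config.round_counts
        )
        if cell_matrix is not None:
            # apply the pseudo-sample decision to the cell-level matrix and
            # add the same mean threshold offset
            keep = set(denoised.gene_ids)
            keep_mask = np.array([g in keep for g in cell_matrix.gene_ids])
            denoised = CountMatrix(
                [g for g, k in zip(cell_matrix.gene_ids, keep_mask) if k],
                list(cell_matrix.sample_ids),
                cell_matrix.counts[keep_mask, :] + thresholds.mean_threshold,
            )
        denoised_path = out_dir / "denoised.tsv"
        write_count_matrix(denoised, denoised_path)
        written.append(denoised_path)

        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(report_path)

        manifest = {
            "package": "denoiseq",
            "version": __version__,
            "inputs": {
                "matrix": Path(config.matrix).name if config.matrix else None,
                "bams": [Path(b).name for b in config.bams],
                "annotation": (
                    Path(config.annotation).name if config.annotation else None
                ),
            },
            "resolved": resolved,
            # paths reduced to basenames so identical runs in different
            # directories produce identical manifests
            "config": {
                **asdict(config),
                "matrix": Path(config.matrix).name if config.matrix else None,
                "bams": [Path(b).name for b in config.bams],
                "annotation": (
                    Path(config.annotation).name if config.annotation else None
                ),
                "metadata": Path(config.metadata).name if config.metadata else None,
                "out_dir": Path(config.out_dir).name,
            },
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return thresholds, denoised, report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, (ValidationError, ConfigError)):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise
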