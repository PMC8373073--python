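"""Pseudo-sample summarization of single-cell count matrices.

Individual cells are too shallow and too variable for the sliding-window
abundance-similarity profile to stabilize: correlations plateau at weakly
positive values over a wide abundance range. Grouping cells into a small
number of pseudo-samples — randomly, or by a metadata key such as donor —
and averaging their counts (arithmetic mean per gene) recovers the
noise-floor-to-signal transition the thresholding needs. Thresholds
estimated on pseudo-samples live on the per-cell mean scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .formats import CellMetadata, CountMatrix

__all__ = [
    "CellGrouping",
    "random_grouping",
    "metadata_grouping",
    "summarize_pseudo_samples",
]


@dataclass
class CellGrouping:
    """Assignment of every cell to exactly one pseudo-sample."""

    assignment: dict[str, str]  # cell_id -> pseudo_sample_id
    provenance: str

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValidationError("empty grouping")

    @property
    def pseudo_sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for group in self.assignment.values():
            seen.setdefault(group)
        return list(seen)

    def members(self, pseudo_sample_id: str) -> list[str]:
        return [c for c, g in self.assignment.items() if g == pseudo_sample_id]


def random_grouping(cell_ids, n_groups: int, seed: int) -> CellGrouping:
    """Deal shuffled cells into ``n_groups`` parts of near-equal size.

    Sizes differ by at most one; remainder cells go one-per-group to the
    earliest groups. Deterministic for a fixed seed.
    """
    cell_ids = [str(c) for c in cell_ids]
    if n_groups < 2:
        raise ValidationError("need at least 2 pseudo-samples")
    if n_groups > len(cell_ids):
        raise ValidationError("more groups than cells")
    rng = np.random.default_rng(seed)
    shuffled = [cell_ids[i] for i in rng.permutation(len(cell_ids))]
    base, remainder = divmod(len(cell_ids), n_groups)
    assignment: dict[str, str] = {}
    pos = 0
    for g in range(n_groups):
        size = base + (1 if g < remainder else 0)
        for cell in shuffled[pos : pos + size]:
            assignment[cell] = f"pseudo_{g + 1}"
        pos += size
    return CellGrouping(assignment, provenance=f"random(seed={seed}, n_groups={n_groups})")


def metadata_grouping(metadata: CellMetadata, key: str) -> CellGrouping:
    """One pseudo-sample per distinct value of a metadata key (e.g. donor)."""
    labels = metadata.labels(key)
    missing = labels.index[labels.isna()].tolist()
    if missing:
        raise ValidationError(
            f"metadata key {key!r} missing for cells: {missing[:10]}"
        )
    assignment = {str(cell): str(value) for cell, value in labels.items()}
    return CellGrouping(assignment, provenance=f"metadata(key={key})")


def summarize_pseudo_samples(
    matrix: CountMatrix, grouping: CellGrouping
) -> CountMatrix:
    """Arithmetic-mean counts per pseudo-sample; gene order preserved."""
    missing = [c for c in grouping.assignment if c not in set(matrix.sample_ids)]
    if missing:
        raise ValidationError(f"cells absent from matrix: {missing[:10]}")
    uncovered = set(matrix.sample_ids) - set(grouping.assignment)
    if uncovered:
        raise ValidationError(
            f"matrix cells not covered by grouping: {sorted(uncovered)[:10]}"
        )
    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    pseudo_ids = grouping.pseudo_sample_ids
    out = np.empty((matrix.n_genes, len(pseudo_ids)))
    for g, pid in enumerate(pseudo_ids):
        cols = [col_index[c] for c in grouping.members(pid)]
        out[:, g] = matrix.counts[:, cols].mean(axis=1)
    return CountMatrix(list(matrix.gene_ids), pseudo_ids, out)
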