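"""Log-spaced abundance binning of similarity observations.

Shared by the transcript approach (per-transcript p2pPCC records) and the
count approach's boxplot-style thresholding (per-window similarities): both
reduce an (abundance, similarity) cloud to per-bin quartile summaries over
bins ``[base^k, base^(k+1))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["BinnedStats", "bin_similarity_values"]


@dataclass
class BinnedStats:
    """Quartile summaries of similarity per log-spaced abundance bin.

    Bins are contiguous and non-overlapping, ordered by increasing
    abundance. A dedicated lowest bin (lower bound 0) holds zero-abundance
    observations. Empty bins have count 0 and NaN quartiles.
    """

    lower: np.ndarray  # per-bin lower abundance bound (inclusive)
    upper: np.ndarray  # per-bin upper abundance bound (exclusive)
    count: np.ndarray
    q1: np.ndarray
    median: np.ndarray
    q3: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.lower)
        for arr in (self.upper, self.count, self.q1, self.median, self.q3):
            if len(arr) != n:
                raise ValidationError("BinnedStats arrays must share one length")
        if n == 0:
            raise ValidationError("BinnedStats must have at least one bin")
        if np.any(self.lower[1:] != self.upper[:-1]):
            raise ValidationError("bins must be contiguous")
        populated = self.count > 0
        q = (self.q1[populated], self.median[populated], self.q3[populated])
        if np.any(q[0] > q[1]) or np.any(q[1] > q[2]):
            raise ValidationError("quartiles must satisfy Q1 <= median <= Q3")

    @property
    def n_bins(self) -> int:
        return len(self.lower)


def bin_similarity_values(
    abundance: np.ndarray, similarity: np.ndarray, base: float = 2.0
) -> BinnedStats:
    """Bin similarity observations into ``[base^k, base^(k+1))`` abundance bins.

    Zero-abundance observations go to a dedicated lowest bin ``[0, base^k0)``
    where ``k0`` is the exponent of the smallest positive abundance; they
    never push the threshold upward. Quartiles use linear interpolation.
    """
    abundance = np.asarray(abundance, dtype=float)
    similarity = np.asarray(similarity, dtype=float)
    if abundance.size == 0:
        raise ValidationError("no observations to bin")
    if abundance.shape != similarity.shape:
        raise ValidationError("abundance and similarity must align")
    if np.any(abundance < 0):
        raise ValidationError("abundances must be non-negative")

    positive = abundance > 0
    has_zero_bin = bool((~positive).any())
    if positive.any():
        k_lo = int(np.floor(np.log(abundance[positive].min()) / np.log(base)))
        k_hi = int(np.floor(np.log(abundance[positive].max()) / np.log(base)))
        edges = base ** np.arange(k_lo, k_hi + 2, dtype=float)
        lower, upper = edges[:-1], edges[1:]
        if has_zero_bin:
            lower = np.concatenate([[0.0], lower])
            upper = np.concatenate([[edges[0]], upper])
    else:
        k_lo = 0
        lower, upper = np.array([0.0]), np.array([1.0])

    n_bins = len(lower)
    count = np.zeros(n_bins, dtype=int)
    q1 = np.full(n_bins, np.nan)
    med = np.full(n_bins, np.nan)
    q3 = np.full(n_bins, np.nan)

    # assign: zeros to bin 0 (when present), positives by exponent
    idx = np.zeros(abundance.shape, dtype=int)
    offset = 1 if has_zero_bin else 0
    if positive.any():
        # digitize instead of floor(log(...)) to keep edge values exact
        idx[positive] = np.digitize(abundance[positive], edges, right=False) - 1 + offset

    for b in range(n_bins):
        vals = similarity[idx == b]
        count[b] = vals.size
        if vals.size:
            q1[b], med[b], q3[b] = np.percentile(vals, [25, 50, 75])

    return BinnedStats(lower, upper, count, q1, med, q3)
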