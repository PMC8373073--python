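"""Signal/noise abundance thresholds from abundance-similarity relations.

A similarity threshold ``c`` (the hyper-parameter) is translated into a
per-sample abundance threshold theta: the abundance above which cross-sample
similarity consistently stays above ``c``. Genes quantified below theta in a
sample are considered technically unreliable there.

Two threshold rules are provided:

* line method — the similarity curve (ordered by ascending window abundance)
  is smoothed with a centered moving average; theta is the abundance of the
  first window from which the smoothed similarity never drops below ``c``.
* boxplot methods — observations are binned on log-spaced abundance ranges;
  theta is the lower bound of the first bin from which the chosen statistic
  (median, or Q1 for the IQR variant) stays strictly above ``c`` across all
  populated higher bins.

``c`` itself is chosen from a grid by minimizing the coefficient of
variation (population standard deviation / mean) of the per-sample
thresholds — the value that makes the thresholds most consistent across
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinnedStats, bin_similarity_values
from .count_approach import SimilarityProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseThresholds",
    "UNDETERMINED",
    "threshold_from_profile_line",
    "threshold_from_binned_stats",
    "coefficient_of_variation",
    "optimize_similarity_threshold",
    "profile_to_binned_stats",
    "DEFAULT_GRID",
]

UNDETERMINED = float("nan")
DEFAULT_GRID = np.round(np.arange(0.05, 0.95 + 1e-9, 0.01), 2)
DEFAULT_SMOOTHING_WIDTH = 5

METHODS = ("line_smoothed", "boxplot_median", "boxplot_IQR")


@dataclass
class NoiseThresholds:
    """Per-sample noise thresholds theta plus the similarity threshold used.

    ``theta`` uses NaN as the "undetermined" sentinel (no abundance at which
    similarity consistently exceeds ``c``). The mean threshold — the offset
    later added to the count matrix — averages determined thetas only.
    """

    sample_ids: list[str]
    theta: np.ndarray
    similarity_threshold: float
    method: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.theta) != len(self.sample_ids):
            raise ValidationError("one theta per sample required")
        determined = self.theta[np.isfinite(self.theta)]
        if determined.size and determined.min() < 0:
            raise ValidationError("thresholds must be non-negative")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")

    @property
    def mean_threshold(self) -> float:
        determined = self.theta[np.isfinite(self.theta)]
        if determined.size == 0:
            raise ValidationError("all samples undetermined; no mean threshold")
        return float(determined.mean())

    @property
    def n_undetermined(self) -> int:
        return int(np.count_nonzero(~np.isfinite(self.theta)))

    def theta_for(self, sample_id: str) -> float:
        try:
            return float(self.theta[self.sample_ids.index(sample_id)])
        except ValueError:
            raise ValidationError(f"no threshold for sample {sample_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "theta": self.theta,
                "c": self.similarity_threshold,
                "method": self.method,
            }
        )


def _suffix_first_true(condition: np.ndarray) -> int | None:
    """Index of the first position from which ``condition`` holds throughout."""
    ok = np.logical_and.accumulate(condition[::-1])[::-1]
    hits = np.nonzero(ok)[0]
    return int(hits[0]) if hits.size else None


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    if width % 2 != 1 or width < 1:
        raise ValidationError("smoothing_width must be odd and >= 1")
    if width == 1:
        return values.astype(float)
    return (
        pd.Series(values).rolling(width, center=True, min_periods=1).mean().to_numpy()
    )


def threshold_from_profile_line(
    profile: SimilarityProfile,
    c: float,
    smoothing_width: int = DEFAULT_SMOOTHING_WIDTH,
    attainable_range: tuple[float, float] = (-1.0, 1.0),
) -> float:
    """Line-method theta: first abundance from which smoothed similarity >= c.

    Returns NaN (undetermined) when the smoothed curve never settles at or
    above ``c``.
    """
    if len(profile) == 0:
        raise ValidationError("empty similarity profile")
    lo, hi = attainable_range
    if not lo <= c <= hi:
        raise ValidationError(
            f"similarity threshold {c} outside attainable range [{lo}, {hi}]"
        )
    order = np.argsort(profile.window_abundance, kind="stable")
    abundance = profile.window_abundance[order]
    smoothed = _moving_average(profile.window_similarity[order], smoothing_width)
    idx = _suffix_first_true(smoothed >= c)
    if idx is None:
        logger.warning(
            "sample %s: smoothed similarity never reaches %.3g; "
            "threshold undetermined", profile.sample_id, c,
        )
        return UNDETERMINED
    return float(abundance[idx])


def threshold_from_binned_stats(
    binned: BinnedStats, c: float, statistic: str = "Q1"
) -> float:
    """Boxplot-method theta from per-bin quartiles.

    theta is the lower abundance bound of the first populated bin whose
    statistic (``Q1`` for the IQR method, ``median`` for the boxplot-median
    method) is strictly greater than ``c`` in that bin and every populated
    higher-abundance bin; empty bins are skipped when carrying the
    consistency check. NaN when no bin qualifies.
    """
    if statistic not in {"Q1", "median"}:
        raise ValidationError("statistic must be 'Q1' or 'median'")
    populated = binned.count > 0
    if not populated.any():
        raise ValidationError("binned statistics contain no populated bins")
    stat = binned.q1 if statistic == "Q1" else binned.median
    values = stat[populated]
    lowers = binned.lower[populated]
    idx = _suffix_first_true(values > c)
    if idx is None:
        return UNDETERMINED
    return float(lowers[idx])


def coefficient_of_variation(values) -> float:
    """Population standard deviation divided by the arithmetic mean."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValidationError("empty value collection")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return float(values.std(ddof=0) / mean)


def profile_to_binned_stats(
    profile: SimilarityProfile, base: float = 2.0
) -> BinnedStats:
    """Summarize a window profile into log-spaced abundance bins."""
    return bin_similarity_values(
        profile.window_abundance, profile.window_similarity, base=base
    )


def _thetas_at(
    per_sample: Mapping[str, SimilarityProfile | BinnedStats],
    c: float,
    method: str,
    smoothing_width: int,
) -> np.ndarray:
    thetas = []
    for sample_id, data in per_sample.items():
        if method == "line_smoothed":
            if not isinstance(data, SimilarityProfile):
                raise ValidationError("line method requires SimilarityProfile inputs")
            thetas.append(threshold_from_profile_line(data, c, smoothing_width))
        else:
            binned = (
                profile_to_binned_stats(data)
                if isinstance(data, SimilarityProfile)
                else data
            )
            statistic = "median" if method == "boxplot_median" else "Q1"
            thetas.append(threshold_from_binned_stats(binned, c, statistic))
    return np.asarray(thetas, dtype=float)


def optimize_similarity_threshold(
    per_sample: Mapping[str, SimilarityProfile | BinnedStats],
    grid: Sequence[float] | None = None,
    method: str = "boxplot_median",
    groups: Mapping[str, str] | None = None,
    smoothing_width: int = DEFAULT_SMOOTHING_WIDTH,
) -> tuple[float, NoiseThresholds]:
    """Choose the similarity threshold minimizing threshold dispersion.

    For every candidate ``c`` in the grid the per-sample thetas are computed
    and their coefficient of variation taken over samples with determined
    thresholds (a candidate needs at least two to be eligible). When a
    sample grouping is given (e.g. replicates or time points), the mean
    within-group CV is minimized instead. Ties break toward smaller ``c``.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if grid is None:
        grid = DEFAULT_GRID
    grid = sorted(float(c) for c in grid)
    if not grid:
        raise ValidationError("empty threshold grid")

    best: tuple[float, float, np.ndarray] | None = None  # (cv, c, thetas)
    for c in grid:
        thetas = _thetas_at(per_sample, c, method, smoothing_width)
        determined = np.isfinite(thetas)
        if determined.sum() < 2:
            continue
        try:
            if groups is None:
                cv = coefficient_of_variation(thetas[determined])
            else:
                sample_ids = list(per_sample)
                group_cvs = []
                for g in sorted(set(groups.values())):
                    members = [
                        i
                        for i, s in enumerate(sample_ids)
                        if groups.get(s) == g and determined[i]
                    ]
                    if len(members) >= 2:
                        group_cvs.append(coefficient_of_variation(thetas[members]))
                if not group_cvs:
                    continue
                cv = float(np.mean(group_cvs))
        except ValidationError:
            continue  # zero-mean thresholds carry no dispersion information
        if best is None or cv < best[0]:
            best = (cv, c, thetas)

    if best is None:
        raise ValidationError(
            "no eligible similarity threshold: every grid value leaves fewer "
            "than two samples with a determined theta; try a coarser grid or "
            "a different threshold method"
        )
    cv, c_star, thetas = best
    n_undet = int(np.count_nonzero(~np.isfinite(thetas)))
    if n_undet:
        logger.warning(
            "%d sample(s) have undetermined thresholds at c*=%.3g; they are "
            "excluded from the CV and the mean threshold", n_undet, c_star,
        )
    result = NoiseThresholds(
        sample_ids=list(per_sample),
        theta=thetas,
        similarity_threshold=c_star,
        method=method,
        metadata={"cv": cv, "grid_size": len(grid)},
    )
    logger.info(
        "optimized similarity threshold c*=%.3g (CV=%.4g); mean theta=%.4g",
        c_star, cv, result.mean_threshold,
    )
    return c_star, result
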