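"""Similarity and inverted-dissimilarity measures for cross-sample comparison.

Every registered measure obeys a single contract: larger output means the
two expression vectors are more alike. Correlation coefficients are used
directly; distances and divergences are mapped through
:func:`invert_dissimilarity` (``1 / (1 + d)``) so that zero distance becomes
the maximal similarity of 1 and the output stays bounded.

The Pearson correlation coefficient is the default measure. Spearman,
Euclidean distance, Kullback-Leibler divergence (symmetrized) and
Jensen-Shannon divergence are also registered; the registry is extensible
via :func:`register_measure`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.stats
from scipy.spatial.distance import jensenshannon

from .errors import ConfigError, ValidationError

__all__ = [
    "SimilarityMeasure",
    "MEASURES",
    "get_measure",
    "register_measure",
    "compute_similarity",
    "invert_dissimilarity",
    "quarter_range_threshold",
]

_EPS = 1e-12  # pseudo-count so divergences tolerate zero counts


@dataclass(frozen=True)
class SimilarityMeasure:
    """A named measure with its range metadata.

    ``is_dissimilarity`` marks measures whose raw value grows with
    *difference*; those are inverted before being returned so the uniform
    "higher = more similar" contract holds. ``bounds`` gives the attainable
    output range after any inversion, or None if effectively unbounded below.
    """

    name: str
    func: Callable[[np.ndarray, np.ndarray], float]
    is_dissimilarity: bool
    bounds: tuple[float, float] | None


def invert_dissimilarity(d: float) -> float:
    """Map a non-negative dissimilarity onto (0, 1], decreasing in ``d``."""
    if d < 0:
        raise ValidationError(f"dissimilarity must be non-negative, got {d}")
    return 1.0 / (1.0 + d)


def _as_distribution(x: np.ndarray) -> np.ndarray:
    x = x + _EPS
    return x / x.sum()


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return float(scipy.stats.spearmanr(x, y).statistic)


def _euclidean(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.linalg.norm(x - y))


def _kl_symmetric(x: np.ndarray, y: np.ndarray) -> float:
    p, q = _as_distribution(x), _as_distribution(y)
    return float(0.5 * (scipy.stats.entropy(p, q) + scipy.stats.entropy(q, p)))


def _js_divergence(x: np.ndarray, y: np.ndarray) -> float:
    p, q = _as_distribution(x), _as_distribution(y)
    # scipy returns the JS *distance* (sqrt of the divergence, base e)
    return float(jensenshannon(p, q) ** 2)


MEASURES: dict[str, SimilarityMeasure] = {}


def register_measure(measure: SimilarityMeasure) -> None:
    MEASURES[measure.name] = measure


register_measure(SimilarityMeasure("pearson", _pearson, False, (-1.0, 1.0)))
register_measure(SimilarityMeasure("spearman", _spearman, False, (-1.0, 1.0)))
register_measure(SimilarityMeasure("euclidean", _euclidean, True, None))
register_measure(SimilarityMeasure("kl", _kl_symmetric, True, (0.0, 1.0)))
register_measure(SimilarityMeasure("js", _js_divergence, True, (0.0, 1.0)))

_CORRELATION_MEASURES = {"pearson", "spearman"}


def get_measure(name: str | SimilarityMeasure) -> SimilarityMeasure:
    if isinstance(name, SimilarityMeasure):
        return name
    try:
        return MEASURES[name]
    except KeyError:
        raise ConfigError(
            f"unknown similarity measure {name!r}; registered: {sorted(MEASURES)}"
        ) from None


def compute_similarity(
    x: np.ndarray, y: np.ndarray, measure: str | SimilarityMeasure = "pearson"
) -> float:
    """Similarity between two equal-length vectors; higher = more similar.

    Correlation measures return 0 when either vector has zero variance: an
    all-constant window (typically all zeros) carries no evidence of
    consistent signal across samples. Dissimilarity measures are passed
    through :func:`invert_dissimilarity`.
    """
    measure = get_measure(measure)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("similarity requires 1-D vectors of length >= 2")
    if measure.name in _CORRELATION_MEASURES:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0
    value = measure.func(x, y)
    if measure.is_dissimilarity:
        return invert_dissimilarity(value)
    return value


def quarter_range_threshold(similarity_values) -> float:
    """First-cut similarity threshold: min + 1/4 of the observed range.

    For a measure whose usable range is unknown a priori, a quarter of the
    full observed range separates the flat noise regime from the signal
    plateau well enough to seed the data-driven threshold search.
    """
    values = np.asarray(list(similarity_values), dtype=float)
    if values.size < 2:
        raise ValidationError("need at least two similarity values")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValidationError("similarity range is zero; threshold undefined")
    return lo + 0.25 * (hi - lo)
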