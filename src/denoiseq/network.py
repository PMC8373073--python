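"""Robustness assessment of gene-network topologies under noise filtering.

Weighted adjacency matrices produced by network-inference tools are rescaled
to [0, 100] for cross-tool comparability, binarized at the network's overall
median off-diagonal edge weight (strictly above the median -> edge present),
and compared variant-against-variant with per-gene Hamming distances over the
binary edge vectors. A per-gene distance counts how many of that gene's
connections were gained or lost between two processing variants (e.g.
noise-filtered vs not, quantile-normalized vs not); a Kruskal-Wallis rank
test across the pairwise distance distributions assesses whether the
processing combinations differ globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "BinaryNetwork",
    "read_weight_matrix",
    "rescale_weights",
    "binarize_by_median",
    "node_degrees",
    "per_gene_hamming",
    "kruskal_test",
    "compare_variants",
]


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


@dataclass
class WeightedNetwork:
    """Square matrix of real edge weights between genes."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValidationError("weights must be square and match gene_ids")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class BinaryNetwork:
    """0/1 adjacency with an empty diagonal (no self-edges)."""

    gene_ids: list[str]
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges)
        n = len(self.gene_ids)
        if self.edges.shape != (n, n):
            raise ValidationError("edges must be square and match gene_ids")
        if not np.isin(self.edges, (0, 1)).all():
            raise ValidationError("edges must be 0/1")
        if np.any(np.diag(self.edges) != 0):
            raise ValidationError("self-edges are not allowed")
        self.edges = self.edges.astype(np.int8)


def read_weight_matrix(path: str | Path) -> WeightedNetwork:
    """Read a square TSV (header + row names are gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column gene ids differ")
    return WeightedNetwork([str(g) for g in df.index], df.to_numpy(dtype=float))


def rescale_weights(net: WeightedNetwork) -> WeightedNetwork:
    """Affine min-max map of off-diagonal weights onto [0, 100]; diagonal 0."""
    mask = _offdiag_mask(net.n_genes)
    values = net.weights[mask]
    if values.size == 0 or values.min() == values.max():
        raise ValidationError(
            "off-diagonal weights are constant; rescaling is undefined"
        )
    lo, hi = values.min(), values.max()
    scaled = np.zeros_like(net.weights)
    scaled[mask] = (net.weights[mask] - lo) / (hi - lo) * 100.0
    return WeightedNetwork(list(net.gene_ids), scaled)


def binarize_by_median(net: WeightedNetwork) -> BinaryNetwork:
    """Edge present iff its weight is strictly above the network's median.

    The median is taken over all off-diagonal weights of the network. Weights
    equal to the median map to 0. Invariant to affine rescaling of the
    weights, so binarizing before or after :func:`rescale_weights` gives the
    same network.
    """
    mask = _offdiag_mask(net.n_genes)
    median = np.median(net.weights[mask])
    edges = np.zeros(net.weights.shape, dtype=np.int8)
    edges[mask] = (net.weights[mask] > median).astype(np.int8)
    return BinaryNetwork(list(net.gene_ids), edges)


def node_degrees(net: BinaryNetwork) -> pd.Series:
    """Total edges connected to each gene (symmetrized presence).

    An edge recorded in both directions counts once: presence is the
    element-wise OR of the adjacency with its transpose.
    """
    sym = net.edges | net.edges.T
    return pd.Series(sym.sum(axis=1), index=net.gene_ids, name="degree")


def per_gene_hamming(a: BinaryNetwork, b: BinaryNetwork) -> pd.Series:
    """Per-gene Hamming distance between the two networks' edge vectors.

    A gene's edge vector is its adjacency row with the diagonal entry
    dropped; the distance counts connections gained or lost between ``a``
    and ``b``.
    """
    if a.gene_ids != b.gene_ids:
        raise ValidationError("networks must share the gene set and order")
    mask = _offdiag_mask(len(a.gene_ids))
    diff = (a.edges != b.edges) & mask
    return pd.Series(diff.sum(axis=1), index=a.gene_ids, name="hamming")


def kruskal_test(distributions: Mapping[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value across labeled distance distributions.

    Degenerate input (every value identical across all groups) carries no
    rank information; (NaN, NaN) is returned and a note logged.
    """
    if len(distributions) < 2:
        raise ValidationError("need at least two distributions")
    groups = [np.asarray(v, dtype=float) for v in distributions.values()]
    pooled = np.concatenate(groups)
    if pooled.size == 0 or np.ptp(pooled) == 0:
        logger.info("no variation across distance distributions; test degenerate")
        return float("nan"), float("nan")
    result = scipy.stats.kruskal(*groups)
    return float(result.statistic), float(result.pvalue)


def compare_variants(
    networks: Mapping[str, WeightedNetwork | BinaryNetwork],
) -> dict:
    """All-versus-all per-gene Hamming distances across processing variants.

    ``networks`` maps variant labels (conventionally -F-N, +F-N, -F+N, +F+N
    for the filtered/normalized combinations) to networks sharing one gene
    set. Weighted inputs are binarized at their own median first. Returns the
    per-pair distance distributions, the Kruskal-Wallis H statistic and
    p-value across them, and per-variant node degrees.
    """
    if len(networks) < 2:
        raise ValidationError("need at least two variants to compare")
    binary: dict[str, BinaryNetwork] = {}
    for label, net in networks.items():
        binary[label] = (
            net if isinstance(net, BinaryNetwork) else binarize_by_median(net)
        )
    gene_sets = {tuple(b.gene_ids) for b in binary.values()}
    if len(gene_sets) != 1:
        raise ValidationError("all variants must share the gene set and order")

    distributions = {
        f"{la} vs {lb}": per_gene_hamming(binary[la], binary[lb]).to_numpy()
        for la, lb in combinations(binary, 2)
    }
    statistic, pvalue = kruskal_test(distributions)
    return {
        "distributions": distributions,
        "kruskal_H": statistic,
        "kruskal_p": pvalue,
        "degenerate": bool(np.isnan(statistic)),
        "node_degrees": {label: node_degrees(b) for label, b in binary.items()},
    }
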