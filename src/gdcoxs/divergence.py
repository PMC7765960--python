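"""Sample-wise distance matrices for one condition of a gene set.

The method's own distance is the Renyi quadratic divergence between two
samples, estimated as the log ratio of their densities under the
condition's fitted model:

    D2(S_i || S_j) = log f(S_i) - log f(S_j)

which is antisymmetric in the pair and has rank-one difference structure
(every entry is ``a_i - a_j`` for the vector ``a`` of per-sample log
densities). The Gaussian normalising constants cancel in the ratio, so
for the shrinkage-normal model the entry reduces to minus one half of the
difference of Mahalanobis quadratic forms.

Benchmark distances (Euclidean, Manhattan, Mahalanobis) are provided for
the Mantel-statistic comparators; these are ordinary symmetric metrics
over sample vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist, squareform

from .density import (
    GaussianModel,
    fit_shrinkage_gaussian,
    log_density_samples,
    product_kernel_log_density_samples,
)

__all__ = [
    "DistanceMetric",
    "SampleDistanceMatrix",
    "renyi_distance_matrix",
    "renyi_distance_matrix_from_log_densities",
    "benchmark_distance_matrix",
    "upper_triangle",
]


class DistanceMetric(str, Enum):
    RENYI = "renyi"
    RENYI_KERNEL = "renyi_kernel"
    EUCLIDEAN = "euclidean"
    MANHATTAN = "manhattan"
    MAHALANOBIS = "mahalanobis"


#: Metrics that produce ordinary symmetric, non-negative distances.
SYMMETRIC_METRICS = (
    DistanceMetric.EUCLIDEAN,
    DistanceMetric.MANHATTAN,
    DistanceMetric.MAHALANOBIS,
)


@dataclass
class SampleDistanceMatrix:
    """Square matrix of pairwise sample distances within one condition.

    For the (antisymmetric) divergence metrics ``values[i, j]`` is the log
    density ratio of samples i and j; for the benchmark metrics it is an
    ordinary distance. The diagonal is always zero.
    """

    values: np.ndarray
    sample_ids: list[str]
    metric: DistanceMetric

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.metric = DistanceMetric(self.metric)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        return upper_triangle(self)


def upper_triangle(dm: SampleDistanceMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle entries (i < j) in row-major order.

    For ``n`` samples the result has length ``n (n - 1) / 2`` and is
    ordered (0,1), (0,2), ..., (0,n-1), (1,2), ... — the pair ordering
    shared by the copy-number and expression distance vectors when the
    interaction score correlates them.
    """
    values = dm.values if isinstance(dm, SampleDistanceMatrix) else np.asarray(dm)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for an upper triangle")
    iu = np.triu_indices(n, k=1)
    return values[iu]


def renyi_distance_matrix_from_log_densities(
    log_densities: np.ndarray,
    sample_ids: list[str] | None = None,
    metric: DistanceMetric = DistanceMetric.RENYI,
) -> SampleDistanceMatrix:
    """Build the antisymmetric divergence matrix ``a_i - a_j`` from the
    vector of per-sample log densities."""
    a = np.asarray(log_densities, dtype=float)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(a.size)]
    return SampleDistanceMatrix(a[:, None] - a[None, :], list(sample_ids), metric)


def renyi_distance_matrix(
    x: np.ndarray, model: GaussianModel, sample_ids: list[str] | None = None
) -> SampleDistanceMatrix:
    """Renyi quadratic divergences between all sample pairs of a condition.

    ``x`` is the condition's genes x samples sub-matrix and ``model`` the
    shrinkage normal fitted on the same slice. Computed from the n log
    densities (O(n d^2) overall), never per pair.
    """
    a = log_density_samples(model, x)
    return renyi_distance_matrix_from_log_densities(a, sample_ids, DistanceMetric.RENYI)


def kernel_renyi_distance_matrix(
    x: np.ndarray,
    bandwidths: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> SampleDistanceMatrix:
    """Divergence matrix under the product-kernel density (dCoxS baseline)."""
    a = product_kernel_log_density_samples(x, bandwidths)
    return renyi_distance_matrix_from_log_densities(
        a, sample_ids, DistanceMetric.RENYI_KERNEL
    )


def benchmark_distance_matrix(
    x: np.ndarray,
    metric: DistanceMetric | str,
    sample_ids: list[str] | None = None,
    precision: np.ndarray | None = None,
) -> SampleDistanceMatrix:
    """Symmetric benchmark distances between sample columns.

    ``metric`` is one of ``euclidean``, ``manhattan`` or ``mahalanobis``.
    The Mahalanobis metric uses the inverse shrinkage covariance of the
    same condition slice (fitted on the fly unless ``precision`` is
    given), so a singular sample covariance can never arise.
    """
    metric = DistanceMetric(metric)
    x = np.asarray(x, dtype=float)
    obs = x.T  # samples in rows
    if metric is DistanceMetric.EUCLIDEAN:
        values = cdist(obs, obs, metric="euclidean")
    elif metric is DistanceMetric.MANHATTAN:
        values = cdist(obs, obs, metric="cityblock")
    elif metric is DistanceMetric.MAHALANOBIS:
        if precision is None:
            precision = fit_shrinkage_gaussian(x).precision
        values = cdist(obs, obs, metric="mahalanobis", VI=precision)
    else:
        raise ValueError(f"{metric.value} is not a symmetric benchmark metric")
    np.fill_diagonal(values, 0.0)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(x.shape[1])]
    return SampleDistanceMatrix(values, list(sample_ids), metric)
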