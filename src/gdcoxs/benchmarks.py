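"""Comparator methods for the differential-interaction analysis.

Two families are provided:

* single-pair differential correlation — for one copy-number gene and one
  expression gene, the Pearson correlation is computed within each
  condition and the difference is tested with the two-sample Fisher-z
  statistic and a two-sided normal p-value;
* set-wise Mantel statistics — the correlation of upper-triangle entries
  of two symmetric sample-distance matrices (Euclidean, Manhattan or
  Mahalanobis with shrinkage covariance), plugged into the same
  label-permutation scaffold as the divergence-based method so power
  comparisons are paired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .divergence import (
    DistanceMetric,
    SampleDistanceMatrix,
    SYMMETRIC_METRICS,
    upper_triangle,
)
from .interaction import InteractionResult, interaction_score, permutation_test
from .io import ConditionLabels, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelationResult",
    "differential_correlation_pair",
    "mantel_interaction",
    "differential_mantel_test",
]


@dataclass
class PairCorrelationResult:
    """Differential correlation of one copy-number / expression gene pair."""

    r_a: float
    r_b: float
    z: float
    p_value: float
    group_a: str
    group_b: str

    @property
    def intractable(self) -> bool:
        return not np.isfinite(self.z)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if den == 0.0:
        return float("nan")
    return float(xc @ yc) / den


def differential_correlation_pair(
    cna_row: np.ndarray,
    ge_row: np.ndarray,
    labels: ConditionLabels,
    sample_ids: Sequence[str],
    reference_group: str | None = None,
) -> PairCorrelationResult:
    """Fisher-z test for a difference of two correlations.

    ``z = [atanh(r_a) - atanh(r_b)] / sqrt(1/(n_a - 3) + 1/(n_b - 3))``
    with a two-sided normal p-value. A zero-variance row within a group
    makes the pair intractable (NaN result, flagged).
    """
    cna_row = np.asarray(cna_row, dtype=float)
    ge_row = np.asarray(ge_row, dtype=float)
    labels.check_cover(sample_ids)
    groups = labels.groups
    ref = reference_group if reference_group is not None else groups[0]
    other = groups[1] if ref == groups[0] else groups[0]
    mask_a = labels.mask(sample_ids, ref)
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a < 4 or n_b < 4:
        raise ValueError("each group needs at least 4 samples")
    r_a = _pearson(cna_row[mask_a], ge_row[mask_a])
    r_b = _pearson(cna_row[~mask_a], ge_row[~mask_a])
    if not (np.isfinite(r_a) and np.isfinite(r_b)):
        return PairCorrelationResult(r_a, r_b, float("nan"), float("nan"), ref, other)
    clip = 1.0 - 1e-12
    za = math.atanh(max(-clip, min(clip, r_a)))
    zb = math.atanh(max(-clip, min(clip, r_b)))
    z = (za - zb) / math.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return PairCorrelationResult(r_a, r_b, z, p, ref, other)


def mantel_interaction(
    cna_dm: SampleDistanceMatrix, ge_dm: SampleDistanceMatrix
) -> float:
    """Mantel r: correlation of upper triangles of two distance matrices."""
    if cna_dm.sample_ids != ge_dm.sample_ids:
        raise ValueError("distance matrices must share the same sample order")
    if cna_dm.metric not in SYMMETRIC_METRICS or ge_dm.metric not in SYMMETRIC_METRICS:
        raise ValueError("the Mantel statistic requires symmetric distance metrics")
    return interaction_score(upper_triangle(cna_dm), upper_triangle(ge_dm))


def differential_mantel_test(
    cna: OmicsMatrix,
    ge: OmicsMatrix,
    labels: ConditionLabels,
    gene_set: Sequence[str],
    metric: DistanceMetric | str = DistanceMetric.EUCLIDEAN,
    n_permutations: int = 1000,
    seed: int = 0,
    set_name: str = "",
    alpha: float = 0.05,
    adjusted_alpha: float | None = None,
    reference_group: str | None = None,
) -> InteractionResult | None:
    """Differential Mantel test: the divergence-based permutation scaffold
    with a symmetric benchmark distance in place of the log-density ratio."""
    metric = DistanceMetric(metric)
    if metric not in SYMMETRIC_METRICS:
        raise ValueError(f"{metric.value} is not a symmetric benchmark metric")
    return permutation_test(
        cna,
        ge,
        labels,
        gene_set,
        n_permutations=n_permutations,
        seed=seed,
        set_name=set_name,
        alpha=alpha,
        adjusted_alpha=adjusted_alpha,
        method=f"mantel_{metric.value}",
        metric=metric,
        reference_group=reference_group,
    )
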