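"""Interaction scores, the differential statistic, and permutation testing.

The interaction score (IAS) of a gene set within one condition is the
Pearson correlation between the upper-triangle entries of two sample-wise
distance matrices — one computed from the set's copy-number sub-matrix and
one from its expression sub-matrix. A high IAS means the two data types
place the condition's samples at similar relative positions.

The differential statistic contrasts the IAS between two conditions on the
Fisher-z scale,

    diffIAS = [atanh(IAS_a) - atanh(IAS_b)] / sqrt(1/(m_a - 3) + 1/(m_b - 3))

with ``m = n (n - 1) / 2`` the number of sample pairs feeding each group's
correlation. Its significance comes from a label-permutation null — sample
to group assignments are shuffled with group sizes preserved and the
copy-number/expression pairing kept intact, and the densities, distance
matrices and IASs are recomputed within every permuted group — so the
statistic's scale does not affect the validity of the p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .density import (
    fit_shrinkage_gaussian,
    log_density_samples,
    product_kernel_log_density_samples,
)
from .divergence import DistanceMetric, benchmark_distance_matrix, upper_triangle
from .io import ConditionLabels, OmicsMatrix, subset_to_gene_set

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionResult",
    "interaction_score",
    "ias_from_log_densities",
    "diff_ias_statistic",
    "group_ias",
    "permutation_test",
    "bonferroni_threshold",
]

#: Correlations are clipped to +/- (1 - CLIP) before the Fisher transform.
_ATANH_CLIP = 1.0 - 1e-12


@dataclass
class InteractionResult:
    """Per-gene-set outcome of the differential interaction test.

    ``ias_group_a`` / ``ias_group_b`` are the interaction scores of the
    reference and the other condition; ``diff_ias`` contrasts them on the
    Fisher-z scale (negative when the interaction is stronger in group b).
    An intractable set — zero variance in a distance vector, the documented
    failure mode of the kernel baseline on copy-number data — carries NaN
    for the affected quantities and ``p_value`` NaN.
    """

    set_name: str
    n_cna: int
    n_exp: int
    ias_group_a: float
    ias_group_b: float
    diff_ias: float
    p_value: float
    adjusted_alpha: float
    significant: bool
    n_permutations: int
    seed: int
    group_a: str = ""
    group_b: str = ""
    method: str = "gdcoxs"

    @property
    def intractable(self) -> bool:
        return not np.isfinite(self.p_value)


def interaction_score(re_c: np.ndarray, re_g: np.ndarray) -> float:
    """Pearson correlation of two upper-triangle distance vectors.

    Returns NaN (the "intractable" flag) when either vector has zero
    variance, which happens when a group's sample-wise distances do not
    vary — e.g. all-neutral copy-number sub-matrices under the kernel
    baseline.
    """
    u = np.asarray(re_c, dtype=float)
    v = np.asarray(re_g, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("distance vectors must be 1-D and of equal length")
    if u.size < 2:
        raise ValueError("need at least 2 pairwise distances")
    uc = u - u.mean()
    vc = v - v.mean()
    den = math.sqrt(float(uc @ uc) * float(vc @ vc))
    if den == 0.0 or not math.isfinite(den):
        return float("nan")
    return float(uc @ vc) / den


def ias_from_log_densities(a: np.ndarray, b: np.ndarray) -> float:
    """Interaction score directly from two per-sample log-density vectors.

    The divergence matrices have entries ``a_i - a_j`` and ``b_i - b_j``,
    so every upper-triangle moment reduces to an O(n) expression in ``a``
    and ``b``; the result is identical to correlating the explicit upper
    triangles. Used in the permutation hot loop.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    if b.size != n or n < 2:
        raise ValueError("log-density vectors must share a length >= 2")
    a = a - a.mean()  # pair differences are shift invariant
    b = b - b.mean()
    m = n * (n - 1) / 2.0
    c = n - 1.0 - 2.0 * np.arange(n)
    su, sv = float(c @ a), float(c @ b)
    suv = n * float(a @ b)
    suu = n * float(a @ a)
    svv = n * float(b @ b)
    var_u = suu - su * su / m
    var_v = svv - sv * sv / m
    den = math.sqrt(max(var_u, 0.0) * max(var_v, 0.0))
    if den == 0.0 or not math.isfinite(den):
        return float("nan")
    return (suv - su * sv / m) / den


def diff_ias_statistic(ias_a: float, n_a: int, ias_b: float, n_b: int) -> float:
    """Fisher-z contrast of two interaction scores.

    ``n_a`` and ``n_b`` are the group sample counts; each group's
    correlation is based on ``m = n (n - 1) / 2`` sample pairs. Positive
    when the interaction is stronger in group a.
    """
    m_a = n_a * (n_a - 1) // 2
    m_b = n_b * (n_b - 1) // 2
    if m_a <= 3 or m_b <= 3:
        raise ValueError(
            f"need more than 3 sample pairs per group (got {m_a} and {m_b}); "
            "each group requires at least 4 samples"
        )
    if not (np.isfinite(ias_a) and np.isfinite(ias_b)):
        return float("nan")
    za = math.atanh(max(-_ATANH_CLIP, min(_ATANH_CLIP, ias_a)))
    zb = math.atanh(max(-_ATANH_CLIP, min(_ATANH_CLIP, ias_b)))
    se = math.sqrt(1.0 / (m_a - 3) + 1.0 / (m_b - 3))
    return (za - zb) / se


def group_ias(
    cna_x: np.ndarray,
    ge_x: np.ndarray,
    method: str = "gdcoxs",
    metric: DistanceMetric | str | None = None,
) -> float:
    """Interaction score of one condition from its two sub-matrices.

    ``method`` selects the distance construction: ``"gdcoxs"`` (shrinkage
    normal log-density ratios), ``"dcoxs_kernel"`` (product-kernel
    log-density ratios) or ``"mantel"`` (symmetric benchmark distances,
    requiring ``metric``).
    """
    if method == "gdcoxs":
        a = log_density_samples(fit_shrinkage_gaussian(cna_x), cna_x)
        b = log_density_samples(fit_shrinkage_gaussian(ge_x), ge_x)
        return ias_from_log_densities(a, b)
    if method == "dcoxs_kernel":
        a = product_kernel_log_density_samples(cna_x)
        b = product_kernel_log_density_samples(ge_x)
        return ias_from_log_densities(a, b)
    if method == "mantel":
        if metric is None:
            raise ValueError("the mantel method requires a distance metric")
        dc = benchmark_distance_matrix(cna_x, metric)
        dg = benchmark_distance_matrix(ge_x, metric)
        return interaction_score(upper_triangle(dc), upper_triangle(dg))
    raise ValueError(f"unknown method {method!r}")


def _diff_stat(
    cna_x: np.ndarray,
    ge_x: np.ndarray,
    mask_a: np.ndarray,
    ias_fn: Callable[[np.ndarray, np.ndarray], float],
) -> tuple[float, float, float]:
    """(diffIAS, ias_a, ias_b) for one assignment of samples to groups."""
    mask_b = ~mask_a
    ias_a = ias_fn(cna_x[:, mask_a], ge_x[:, mask_a])
    ias_b = ias_fn(cna_x[:, mask_b], ge_x[:, mask_b])
    stat = diff_ias_statistic(ias_a, int(mask_a.sum()), ias_b, int(mask_b.sum()))
    return stat, ias_a, ias_b


def permutation_diff_test(
    cna_x: np.ndarray,
    ge_x: np.ndarray,
    mask_a: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    ias_fn: Callable[[np.ndarray, np.ndarray], float],
) -> tuple[float, float, float, float]:
    """Shared permutation scaffold for all differential-interaction methods.

    Returns ``(diff_ias, ias_a, ias_b, p_value)``. The two-sided p-value
    uses the add-one estimator ``(#{|null| >= |observed|} + 1) / (B + 1)``;
    a permutation whose statistic is undefined counts toward the numerator
    (conservative). An undefined observed statistic yields ``p = NaN``.
    """
    obs, ias_a, ias_b = _diff_stat(cna_x, ge_x, mask_a, ias_fn)
    if not np.isfinite(obs):
        return obs, ias_a, ias_b, float("nan")
    assignment = mask_a.copy()
    n_exceed = 0
    abs_obs = abs(obs)
    # the observed fit has already warned about degenerate genes once;
    # the same warnings would otherwise repeat for every permutation
    density_logger = logging.getLogger("gdcoxs.density")
    old_level = density_logger.level
    density_logger.setLevel(logging.ERROR)
    try:
        for _ in range(n_permutations):
            perm = rng.permutation(assignment)
            null_stat, _, _ = _diff_stat(cna_x, ge_x, perm, ias_fn)
            if not np.isfinite(null_stat) or abs(null_stat) >= abs_obs:
                n_exceed += 1
    finally:
        density_logger.setLevel(old_level)
    p = (n_exceed + 1) / (n_permutations + 1)
    return obs, ias_a, ias_b, p


def _ias_fn_for(method: str, metric: DistanceMetric | str | None = None):
    if method in ("gdcoxs", "dcoxs_kernel"):
        return lambda c, g: group_ias(c, g, method)
    if method.startswith("mantel"):
        chosen = metric
        if chosen is None and "_" in method:
            chosen = method.split("_", 1)[1]
        return lambda c, g: group_ias(c, g, "mantel", chosen)
    raise ValueError(f"unknown method {method!r}")


def permutation_test(
    cna: OmicsMatrix,
    ge: OmicsMatrix,
    labels: ConditionLabels,
    gene_set: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    set_name: str = "",
    alpha: float = 0.05,
    adjusted_alpha: float | None = None,
    method: str = "gdcoxs",
    metric: DistanceMetric | str | None = None,
    reference_group: str | None = None,
) -> InteractionResult | None:
    """Differential-interaction permutation test for one gene set.

    The observed diffIAS comes from the real condition labels; the null
    distribution from ``n_permutations`` reshuffles of the sample-to-group
    assignment (group sizes preserved, the copy-number/expression pairing
    of every sample kept). Within each permutation the densities, distance
    matrices and interaction scores are recomputed per permuted group.

    Returns ``None`` when fewer than two member genes are present in
    either matrix (the set is skipped, with a logged reason).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    pair = subset_to_gene_set(cna, ge, gene_set)
    if pair is None:
        return None
    sub_cna, sub_ge = pair
    labels.check_cover(sub_cna.sample_ids)
    groups = labels.groups
    ref = reference_group if reference_group is not None else groups[0]
    if ref not in groups:
        raise ValueError(f"reference group {ref!r} is not one of {groups}")
    other = groups[1] if ref == groups[0] else groups[0]
    mask_a = labels.mask(sub_cna.sample_ids, ref)
    rng = np.random.default_rng(seed)
    ias_fn = _ias_fn_for(method, metric)
    obs, ias_a, ias_b, p = permutation_diff_test(
        sub_cna.values, sub_ge.values, mask_a, n_permutations, rng, ias_fn
    )
    if adjusted_alpha is None:
        adjusted_alpha = alpha
    return InteractionResult(
        set_name=set_name,
        n_cna=sub_cna.n_genes,
        n_exp=sub_ge.n_genes,
        ias_group_a=ias_a,
        ias_group_b=ias_b,
        diff_ias=obs,
        p_value=p,
        adjusted_alpha=adjusted_alpha,
        significant=bool(np.isfinite(p) and p < adjusted_alpha),
        n_permutations=n_permutations,
        seed=seed,
        group_a=ref,
        group_b=other,
        method=method,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold under Bonferroni correction."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests
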