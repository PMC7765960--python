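"""Per-sample log-density estimation for a gene set within one condition.

Two estimators are provided:

* a multivariate normal with a Schafer-Strimmer shrinkage covariance
  (the gdCoxS density) — sample correlations are shrunk toward the
  identity with an analytically estimated intensity, which keeps the
  covariance positive definite and invertible even when the number of
  samples is smaller than the number of genes in the set;
* a product-kernel density (the dCoxS baseline) — a multivariate kernel
  estimate formed as the product of univariate Gaussian kernels with
  per-gene bandwidths from Silverman's rule.

Both return natural-log densities; all arithmetic stays in log space so
large gene sets cannot underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianModel",
    "fit_shrinkage_gaussian",
    "shrinkage_covariance",
    "log_density",
    "log_density_samples",
    "silverman_bandwidths",
    "product_kernel_log_density",
    "product_kernel_log_density_samples",
]

#: Variance floor applied to genes that do not vary across the samples of a
#: condition (frequent for all-neutral copy-number rows in small groups).
VARIANCE_FLOOR = 1e-8

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class GaussianModel:
    """A fitted multivariate normal over the genes of one set.

    Attributes
    ----------
    mean : ndarray of shape (d,)
        Per-gene means over the condition's samples.
    covariance : ndarray of shape (d, d)
        Shrinkage covariance estimate (symmetric positive definite).
    precision : ndarray of shape (d, d)
        Inverse of ``covariance``.
    log_det : float
        Natural log of the determinant of ``covariance``.
    d : int
        Number of genes in the set.
    shrinkage_intensity : float
        Estimated shrinkage weight toward the identity correlation target,
        in [0, 1].
    """

    mean: np.ndarray
    covariance: np.ndarray
    precision: np.ndarray
    log_det: float
    d: int
    shrinkage_intensity: float


def _shrinkage_correlation_intensity(z: np.ndarray) -> float:
    """Analytic shrinkage intensity for correlations toward the identity.

    ``z`` holds standardized observations (n x d, centered, unit unbiased
    variance). The intensity is the ratio of the summed estimated variances
    of the off-diagonal sample correlations to their summed squares,
    clipped to [0, 1].
    """
    n = z.shape[0]
    r = (z.T @ z) / (n - 1)
    w_bar = (n - 1) / n * r
    sum_w2 = (z * z).T @ (z * z)
    var_r = n / (n - 1) ** 3 * (sum_w2 - n * w_bar**2)
    off = ~np.eye(z.shape[1], dtype=bool)
    denom = float((r[off] ** 2).sum())
    if denom <= 0.0:
        return 1.0
    lam = float(var_r[off].sum()) / denom
    return min(1.0, max(0.0, lam))


def shrinkage_covariance(
    x: np.ndarray,
    shrinkage_intensity: float | None = None,
    variance_floor: float = VARIANCE_FLOOR,
) -> tuple[np.ndarray, float]:
    """Shrinkage covariance of observations ``x`` (n samples x d genes).

    Sample correlations are shrunk toward the identity with intensity
    ``lambda*`` estimated analytically from the data (pass
    ``shrinkage_intensity`` to override), then rescaled by the unbiased
    sample variances. Variances are not shrunk. Returns the covariance and
    the intensity used.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if n < 2:
        raise ValueError("shrinkage covariance needs at least 2 samples")
    xc = x - x.mean(axis=0)
    var = (xc * xc).sum(axis=0) / (n - 1)
    floored = var < variance_floor
    if floored.any():
        logger.warning(
            "floored %d zero-variance gene(s) at %g", int(floored.sum()), variance_floor
        )
        var = np.where(floored, variance_floor, var)
    sd = np.sqrt(var)
    z = xc / sd
    if shrinkage_intensity is None:
        lam = _shrinkage_correlation_intensity(z)
    else:
        lam = float(shrinkage_intensity)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage_intensity must lie in [0, 1]")
    r = (z.T @ z) / (n - 1)
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    cov = r_shrunk * np.outer(sd, sd)
    return cov, lam


def fit_shrinkage_gaussian(
    x: np.ndarray,
    shrinkage_intensity: float | None = None,
    variance_floor: float = VARIANCE_FLOOR,
) -> GaussianModel:
    """Fit the set-wise shrinkage multivariate normal.

    Parameters
    ----------
    x : ndarray of shape (d, n) — genes x samples
        One condition's sub-matrix for a gene set (the values of an
        ``OmicsMatrix`` restricted to the condition's samples).
    shrinkage_intensity : float, optional
        Force the shrinkage weight instead of estimating it (used mainly
        for the diagonal limit ``1.0`` and the sample-covariance limit
        ``0.0`` in validation).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    d, n = x.shape
    if d < 1 or n < 2:
        raise ValueError(f"need >= 1 gene and >= 2 samples, got d={d}, n={n}")
    obs = x.T  # observations in rows
    cov, lam = shrinkage_covariance(obs, shrinkage_intensity, variance_floor)
    try:
        cho = linalg.cho_factor(cov, lower=True, check_finite=False)
    except linalg.LinAlgError:
        # lambda* estimated as 0 on a rank-deficient sample covariance;
        # a minimal intensity restores positive definiteness.
        cov, lam = shrinkage_covariance(obs, 1e-6, variance_floor)
        cho = linalg.cho_factor(cov, lower=True, check_finite=False)
    log_det = 2.0 * float(np.log(np.diag(cho[0])).sum())
    precision = linalg.cho_solve(cho, np.eye(d), check_finite=False)
    precision = 0.5 * (precision + precision.T)
    return GaussianModel(
        mean=x.mean(axis=1),
        covariance=cov,
        precision=precision,
        log_det=log_det,
        d=d,
        shrinkage_intensity=lam,
    )


def log_density(model: GaussianModel, x: np.ndarray) -> float:
    """Natural-log multivariate normal density of one sample vector.

    ``log f(x) = -(d/2) log(2 pi) - (1/2) log|Sigma|
    - (1/2) (x - mu)' Sigma^{-1} (x - mu)``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise ValueError(f"expected a vector of length {model.d}, got shape {x.shape}")
    diff = x - model.mean
    quad = float(diff @ model.precision @ diff)
    return -0.5 * (model.d * _LOG_2PI + model.log_det + quad)


def log_density_samples(model: GaussianModel, x: np.ndarray) -> np.ndarray:
    """Log densities of every column of a genes x samples matrix."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != model.d:
        raise ValueError(f"expected {model.d} genes (rows), got {x.shape[0]}")
    diff = x - model.mean[:, None]
    quad = np.einsum("in,in->n", diff, model.precision @ diff)
    return -0.5 * (model.d * _LOG_2PI + model.log_det + quad)


def silverman_bandwidths(x: np.ndarray, variance_floor: float = VARIANCE_FLOOR) -> np.ndarray:
    """Per-gene Silverman rule-of-thumb bandwidths.

    ``h_g = sd_g * (4 / (3 n)) ** (1/5)`` over the condition's samples,
    with the standard deviation floored so a constant gene never yields a
    zero bandwidth.
    """
    x = np.asarray(x, dtype=float)
    d, n = x.shape
    sd = x.std(axis=1, ddof=1)
    sd = np.maximum(sd, math.sqrt(variance_floor))
    return sd * (4.0 / (3.0 * n)) ** 0.2


def product_kernel_log_density_samples(
    x: np.ndarray, bandwidths: np.ndarray | None = None
) -> np.ndarray:
    """Product-kernel log densities of all samples (the dCoxS estimator).

    For sample ``i`` the leave-self-in estimate is

    ``f(S_i) = (1/n) sum_k prod_g phi((x_ig - x_kg) / h_g) / h_g``

    with Gaussian kernel ``phi`` and per-gene bandwidths ``h_g``
    (Silverman's rule by default). Returned in natural-log space via a
    log-sum-exp over samples.
    """
    x = np.asarray(x, dtype=float)
    d, n = x.shape
    if bandwidths is None:
        bandwidths = silverman_bandwidths(x)
    h = np.asarray(bandwidths, dtype=float)
    if h.shape != (d,):
        raise ValueError(f"expected {d} bandwidths, got shape {h.shape}")
    if (h <= 0).any():
        raise ValueError("bandwidths must be strictly positive")
    scaled = x / h[:, None]  # genes x samples
    sq = (scaled * scaled).sum(axis=0)
    # pairwise sum_g ((x_ig - x_kg)/h_g)^2 via the Gram expansion
    d2 = sq[:, None] + sq[None, :] - 2.0 * (scaled.T @ scaled)
    np.maximum(d2, 0.0, out=d2)
    # every exponent is <= 0 and the self term is exactly 0, so the plain
    # sum of exponentials lies in [1, n]: no rescaling needed
    kernel_sum = np.exp(-0.5 * d2).sum(axis=1)
    const = -0.5 * d * _LOG_2PI - float(np.log(h).sum()) - math.log(n)
    return np.log(kernel_sum) + const


def product_kernel_log_density(
    x: np.ndarray, sample_index: int, bandwidths: np.ndarray | None = None
) -> float:
    """Product-kernel log density of a single sample (column) of ``x``."""
    return float(product_kernel_log_density_samples(x, bandwidths)[sample_index])
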