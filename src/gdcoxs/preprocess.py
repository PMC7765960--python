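"""Expression normalization and gene-set size filtering.

The interaction analysis expects expression values on a roughly Gaussian
scale with comparable distributions across samples. Two standard steps
are provided: a log2(x + offset) transform of non-negative counts and
quantile normalization (every sample column is forced onto the common
reference distribution of rank-wise means, with ties within a column
receiving the mean of the reference values over their tied ranks — the
behaviour of the widely used ``normalize.quantiles`` reference
implementation). Gene sets are filtered by a strict minimum-size rule
before analysis.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import GeneSetCollection, MatrixKind, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = ["log_transform", "quantile_normalize", "filter_gene_sets"]


def log_transform(ge: OmicsMatrix, offset: float = 1.0) -> OmicsMatrix:
    """log2(value + offset) on every entry of an expression matrix.

    The default pseudo-count of 1 maps zero counts to zero. Negative
    input values are an error.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if (ge.values < 0).any():
        i, j = np.argwhere(ge.values < 0)[0]
        raise ValueError(
            f"negative expression value {ge.values[i, j]} at gene "
            f"{ge.gene_ids[i]!r}, sample {ge.sample_ids[j]!r}; log transform "
            "expects non-negative input"
        )
    return OmicsMatrix(
        np.log2(ge.values + offset), list(ge.gene_ids), list(ge.sample_ids), ge.kind
    )


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # ties within the column: mean of the reference values over the
        # run of tied ranks
        start = 0
        for end in range(1, n_genes + 1):
            if end == n_genes or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order[:, j], j] = assigned
    return out


def quantile_normalize(ge: OmicsMatrix) -> OmicsMatrix:
    """Force every sample column onto the common reference distribution.

    The reference is the vector of rank-wise means of the column-sorted
    values; after normalization every column has exactly the same sorted
    value distribution, and within-column rank order is preserved. A
    single-column matrix is returned unchanged (with a warning), since a
    reference over one sample is the sample itself.
    """
    if ge.n_samples < 2:
        logger.warning("quantile normalization of a single-column matrix is a no-op")
        return OmicsMatrix(
            ge.values.copy(), list(ge.gene_ids), list(ge.sample_ids), ge.kind
        )
    return OmicsMatrix(
        _quantile_normalize_values(ge.values),
        list(ge.gene_ids),
        list(ge.sample_ids),
        ge.kind,
    )


def filter_gene_sets(
    sets: GeneSetCollection,
    min_size: int = 10,
    cna: OmicsMatrix | None = None,
    ge: OmicsMatrix | None = None,
    count_mapped: bool = False,
) -> GeneSetCollection:
    """Keep gene sets with *more than* ``min_size`` member genes.

    The inequality is strict: a set of exactly ``min_size`` genes is
    removed. By default the raw membership count is used; with
    ``count_mapped=True`` only members present in both the copy-number and
    the expression matrix are counted.
    """
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    if count_mapped and (cna is None or ge is None):
        raise ValueError("count_mapped=True requires both matrices")
    kept: dict[str, tuple[str, list[str]]] = {}
    for name in sets:
        genes = sets.genes(name)
        if count_mapped:
            cna_genes = set(cna.gene_ids)
            ge_genes = set(ge.gene_ids)
            count = sum(1 for g in genes if g in cna_genes and g in ge_genes)
        else:
            count = len(genes)
        if count > min_size:
            kept[name] = sets.sets[name]
    n_removed = len(sets) - len(kept)
    if n_removed:
        logger.info(
            "removed %d gene set(s) with <= %d member gene(s)", n_removed, min_size
        )
    return GeneSetCollection(kept)
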