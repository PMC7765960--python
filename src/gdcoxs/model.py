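"""Model/results interface for the set-wise differential-interaction screen.

:class:`SetwiseDifferentialInteraction` is built from the aligned
copy-number and expression matrices, the two-group condition labels and a
gene-set collection; :meth:`~SetwiseDifferentialInteraction.fit` runs the
permutation screen over every analyzable set and returns a
:class:`SetwiseDifferentialInteractionResults` carrying the per-set
interaction scores, differential statistics, permutation p-values and the
Bonferroni-corrected significance calls, with a ``summary()`` table.

Per-set permutation streams are derived from the master seed and the set
name, so results do not depend on the order in which sets are processed.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from . import preprocess
from .divergence import DistanceMetric
from .interaction import InteractionResult, bonferroni_threshold, permutation_test
from .io import ConditionLabels, GeneSetCollection, MatrixKind, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SetwiseDifferentialInteraction",
    "SetwiseDifferentialInteractionResults",
    "derive_set_seed",
]


def derive_set_seed(master_seed: int, set_name: str) -> int:
    """Deterministic per-set seed from the master seed and the set name.

    Stable across processes and independent of the processing order, so a
    screen can be parallelized or re-run set by set without changing any
    p-value. The result is kept below 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(set_name.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


class SetwiseDifferentialInteraction:
    """Differential copy-number/expression interaction model for gene sets.

    Parameters
    ----------
    cna, ge : OmicsMatrix
        Copy-number (ternary) and expression matrices over the same
        samples; sample axes are aligned on construction and misalignment
        with no shared samples is an error.
    labels : ConditionLabels
        Two-group sample conditions (every sample must be labeled).
    gene_sets : GeneSetCollection
        Candidate sets; sets with ``min_set_size`` or fewer members are
        dropped (strict inequality), and sets with fewer than two member
        genes present in either matrix are skipped at fit time.
    method : str
        ``"gdcoxs"`` (shrinkage-normal divergence, default),
        ``"dcoxs_kernel"`` (product-kernel divergence) or
        ``"mantel_euclidean"`` / ``"mantel_manhattan"`` /
        ``"mantel_mahalanobis"``.
    reference_group : str, optional
        Group whose interaction score enters the differential statistic
        first; defaults to the alphabetically first label.
    """

    def __init__(
        self,
        cna: OmicsMatrix,
        ge: OmicsMatrix,
        labels: ConditionLabels,
        gene_sets: GeneSetCollection,
        method: str = "gdcoxs",
        min_set_size: int = 10,
        count_mapped: bool = False,
        reference_group: str | None = None,
    ) -> None:
        if cna.kind is not MatrixKind.CNA:
            raise ValueError("first matrix must be of kind CNA")
        if ge.kind is not MatrixKind.GE:
            raise ValueError("second matrix must be of kind GE")
        self.cna, self.ge = gio.align_samples(cna, ge)
        labels.check_cover(self.cna.sample_ids)
        self.labels = labels
        self.method = method
        self.min_set_size = min_set_size
        self.reference_group = (
            reference_group if reference_group is not None else labels.groups[0]
        )
        self.gene_sets = preprocess.filter_gene_sets(
            gene_sets,
            min_size=min_set_size,
            cna=self.cna,
            ge=self.ge,
            count_mapped=count_mapped,
        )
        if len(self.gene_sets) == 0:
            raise ValueError(
                f"no gene set has more than {min_set_size} member genes"
            )

    @classmethod
    def from_files(
        cls,
        cna_path,
        ge_path,
        labels_path,
        gmt_path,
        mapping_path=None,
        log_offset: float | None = None,
        quantile: bool = False,
        **kwargs,
    ) -> "SetwiseDifferentialInteraction":
        """Build the model from TSV/GMT files.

        ``log_offset`` (if given) applies a log2(x + offset) transform to
        the expression matrix and ``quantile=True`` quantile-normalizes it
        afterwards; the copy-number matrix is ingested with the five-level
        to ternary sign collapse.
        """
        cna = gio.read_matrix(cna_path, MatrixKind.CNA)
        ge = gio.read_matrix(ge_path, MatrixKind.GE)
        if mapping_path is not None:
            mapping = pd.read_csv(mapping_path, sep="\t", header=None, dtype=str)
            cna = gio.map_gene_ids(cna, mapping)
            ge = gio.map_gene_ids(ge, mapping)
        if log_offset is not None:
            ge = preprocess.log_transform(ge, log_offset)
        if quantile:
            ge = preprocess.quantile_normalize(ge)
        labels = gio.read_labels(labels_path)
        gene_sets = gio.read_gmt(gmt_path)
        return cls(cna, ge, labels, gene_sets, **kwargs)

    def fit(
        self,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> "SetwiseDifferentialInteractionResults":
        """Run the permutation screen over every analyzable gene set."""
        names = sorted(self.gene_sets)
        adj_alpha = bonferroni_threshold(alpha, len(names))
        results: list[InteractionResult] = []
        skipped: list[tuple[str, str]] = []
        for name in names:
            res = permutation_test(
                self.cna,
                self.ge,
                self.labels,
                self.gene_sets.genes(name),
                n_permutations=n_permutations,
                seed=derive_set_seed(seed, name),
                set_name=name,
                alpha=alpha,
                adjusted_alpha=adj_alpha,
                method=self.method,
                reference_group=self.reference_group,
            )
            if res is None:
                skipped.append((name, "fewer than 2 member genes in a matrix"))
                continue
            if res.intractable:
                skipped.append((name, "intractable (zero-variance distances)"))
            results.append(res)
        for name, reason in skipped:
            logger.info("gene set %s: %s", name, reason)
        return SetwiseDifferentialInteractionResults(
            self, results, skipped, alpha, adj_alpha, n_permutations, seed
        )


class SetwiseDifferentialInteractionResults:
    """Fitted screen: per-set estimates, p-values and significance calls."""

    def __init__(
        self,
        model: SetwiseDifferentialInteraction,
        results: list[InteractionResult],
        skipped: list[tuple[str, str]],
        alpha: float,
        adjusted_alpha: float,
        n_permutations: int,
        seed: int,
    ) -> None:
        self.model = model
        self.results = results
        self.skipped = skipped
        self.alpha = alpha
        self.adjusted_alpha = adjusted_alpha
        self.n_permutations = n_permutations
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        """Per-set results as a DataFrame (one row per analyzed set)."""
        frame = pd.DataFrame(
            {c: [getattr(r, c) for r in self.results] for c in gio.RESULT_COLUMNS}
        )
        frame["method"] = [r.method for r in self.results]
        return frame

    @property
    def n_tested(self) -> int:
        return len(self.results)

    @property
    def significant_sets(self) -> list[str]:
        return [r.set_name for r in self.results if r.significant]

    @property
    def n_significant(self) -> int:
        return len(self.significant_sets)

    @property
    def direction_split(self) -> tuple[int, int]:
        """(number significant with diffIAS > 0, with diffIAS < 0)."""
        pos = sum(1 for r in self.results if r.significant and r.diff_ias > 0)
        neg = sum(1 for r in self.results if r.significant and r.diff_ias < 0)
        return pos, neg

    def save_tsv(self, path) -> None:
        gio.write_results(
            self.results, path, extra_columns={"method": [r.method for r in self.results]}
        )

    def result_hash(self) -> str:
        """SHA-256 of the result table (determinism check across reruns)."""
        frame = self.frame
        return hashlib.sha256(
            frame.to_csv(sep="\t", index=False, float_format="%.12g").encode()
        ).hexdigest()

    def summary(self, top: int = 10) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        groups = self.model.labels.groups
        ref = self.model.reference_group
        other = groups[1] if ref == groups[0] else groups[0]
        pos, neg = self.direction_split
        lines = [
            "Set-wise differential interaction (CNA x GE)",
            "=" * 60,
            f"method:            {self.model.method}",
            f"groups:            {ref} (reference) vs {other}",
            f"samples:           {self.model.cna.n_samples}"
            f" ({ref}: {len(self.model.labels.group_samples(ref))},"
            f" {other}: {len(self.model.labels.group_samples(other))})",
            f"gene sets tested:  {self.n_tested}"
            + (f" ({len(self.skipped)} skipped/flagged)" if self.skipped else ""),
            f"permutations:      {self.n_permutations}   seed: {self.seed}",
            f"alpha:             {self.alpha}"
            f"   Bonferroni per-test threshold: {self.adjusted_alpha:.3g}",
            f"significant sets:  {self.n_significant}"
            f" (diffIAS > 0: {pos}, diffIAS < 0: {neg})",
            "-" * 60,
        ]
        frame = self.frame
        if len(frame):
            show = frame.sort_values("p_value").head(top)
            cols = [
                "set_name",
                "n_cna",
                "n_exp",
                "ias_group_a",
                "ias_group_b",
                "diff_ias",
                "p_value",
                "significant",
            ]
            lines.append(
                show[cols].to_string(
                    index=False,
                    float_format=lambda v: f"{v:.4g}",
                )
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SetwiseDifferentialInteractionResults: {self.n_tested} sets, "
            f"{self.n_significant} significant>"
        )
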