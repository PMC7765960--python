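"""Input/output of omics matrices, gene sets, condition labels and results.

The file formats are deliberately plain: tab-separated matrices with a
header row of sample identifiers and a first column of gene identifiers,
GMT gene-set collections (MSigDB dialect), and two-column TSV label files.
All ingestion enforces the invariants the interaction analysis relies on:
unique identifiers, no missing values, ternary copy-number calls, and an
identical sample ordering across the copy-number and expression matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixKind",
    "OmicsMatrix",
    "GeneSetCollection",
    "ConditionLabels",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "read_labels",
    "map_gene_ids",
    "subset_to_gene_set",
    "align_samples",
    "write_results",
    "RESULT_COLUMNS",
]


class MatrixKind(str, Enum):
    """Data type carried by an :class:`OmicsMatrix`.

    ``CNA`` holds gene-level copy-number calls restricted to loss (-1),
    neutral (0) and gain (+1); ``GE`` holds continuous expression values.
    """

    CNA = "CNA"
    GE = "GE"


@dataclass
class OmicsMatrix:
    """A genes x samples numeric matrix with identifiers on both axes.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Numeric matrix; rows are genes, columns are samples.
    gene_ids, sample_ids : sequence of str
        Unique identifiers for the rows and columns.
    kind : MatrixKind
        ``CNA`` (ternary calls) or ``GE`` (continuous).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    kind: MatrixKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.kind = MatrixKind(self.kind)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"row count {self.values.shape[0]} != number of gene ids "
                f"{len(self.gene_ids)}"
            )
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError(
                f"column count {self.values.shape[1]} != number of sample ids "
                f"{len(self.sample_ids)}"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if np.isnan(self.values).any():
            raise ValueError(
                f"{self.kind.value} matrix contains missing values; resolve "
                "missingness upstream"
            )
        if self.kind is MatrixKind.CNA:
            bad = ~np.isin(self.values, (-1.0, 0.0, 1.0))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"CNA matrix contains value {self.values[i, j]!r} at gene "
                    f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}; "
                    "expected ternary calls in {-1, 0, +1}"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_genes(self, gene_ids: Iterable[str]) -> "OmicsMatrix":
        """Return the sub-matrix of the listed genes, in matrix row order."""
        wanted = set(gene_ids)
        idx = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        return OmicsMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.kind,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Return the sub-matrix of the listed samples, in the given order."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present in matrix") from None
        return OmicsMatrix(
            self.values[:, idx], list(self.gene_ids), [str(s) for s in sample_ids], self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets, each with a free-text description.

    ``sets`` maps set name -> (description, ordered list of member genes).
    Duplicate members within a set are removed on construction, keeping the
    first occurrence.
    """

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, list[str]]] = {}
        for name, (desc, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "gene set %s: removed %d duplicate member(s)",
                    name,
                    len(genes) - len(unique),
                )
            cleaned[name] = (desc, unique)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})


@dataclass
class ConditionLabels:
    """Two-group sample labels (e.g. survival vs non-survival).

    ``labels`` maps sample id -> group label; exactly two distinct labels
    must be present and each group needs at least ``min_group_size``
    samples for the correlation of pairwise distances to be non-degenerate.
    """

    labels: dict[str, str]
    min_group_size: int = 4

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        groups = sorted(set(self.labels.values()))
        if len(groups) != 2:
            raise ValueError(
                f"expected exactly two group labels, found {len(groups)}: {groups}"
            )
        for g in groups:
            n = sum(1 for v in self.labels.values() if v == g)
            if n < self.min_group_size:
                raise ValueError(
                    f"group {g!r} has only {n} samples; at least "
                    f"{self.min_group_size} are required"
                )

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, sorted alphabetically."""
        return tuple(sorted(set(self.labels.values())))  # type: ignore[return-value]

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def check_cover(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise ValueError(
                f"{len(missing)} sample(s) have no condition label, e.g. "
                f"{missing[:3]}"
            )

    def mask(self, sample_ids: Sequence[str], group: str) -> np.ndarray:
        """Boolean mask over ``sample_ids`` of membership in ``group``."""
        return np.array([self.labels[s] == group for s in sample_ids], dtype=bool)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def read_matrix(path: str | Path, kind: MatrixKind | str) -> OmicsMatrix:
    """Read a genes x samples TSV matrix.

    The first row holds sample identifiers, the first column gene
    identifiers. For ``kind="CNA"`` five-level thresholded copy-number
    calls in {-2, -1, 0, 1, 2} are collapsed by sign to the ternary
    {-1, 0, +1} coding the interaction model uses; values outside that
    range are an error.
    """
    kind = MatrixKind(kind)
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    _check_unique([str(g) for g in frame.index], "gene id")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            # numpy's parser round-trips full double precision
            values[:, j] = frame[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            gene = bad.index[0]
            raise ValueError(
                f"non-numeric value {bad.iloc[0]!r} at gene {gene!r}, sample "
                f"{col!r} in {path}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at gene {frame.index[i]!r}, sample "
            f"{frame.columns[j]!r} in {path}"
        )
    if kind is MatrixKind.CNA:
        out_of_range = (values < -2) | (values > 2)
        if out_of_range.any():
            i, j = np.argwhere(out_of_range)[0]
            raise ValueError(
                f"CNA call {values[i, j]} outside [-2, 2] at gene "
                f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
            )
        collapsed = np.sign(values)
        n_collapsed = int((collapsed != values).sum())
        if n_collapsed:
            logger.info(
                "collapsed %d five-level copy-number call(s) to ternary by sign",
                n_collapsed,
            )
        values = collapsed
    return OmicsMatrix(values, list(frame.index), list(frame.columns), kind)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write an :class:`OmicsMatrix` as a TSV readable by :func:`read_matrix`."""
    # %.17g round-trips IEEE doubles exactly
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name TAB description TAB gene1 TAB ...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); a GMT "
                    "line needs a name, a description and at least one gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno} ({name!r}) lists no genes")
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def read_labels(path: str | Path, min_group_size: int = 4) -> ConditionLabels:
    """Read a two-column TSV of (sample id, group label)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: label file needs two columns (sample, group)")
    # tolerate an optional header line
    first = str(frame.iloc[0, 0]).lower()
    if first in {"sample", "sample_id", "id"}:
        frame = frame.iloc[1:]
    labels = dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))
    if len(labels) != len(frame):
        raise ValueError(f"{path}: duplicated sample ids in label file")
    return ConditionLabels(labels, min_group_size=min_group_size)


def map_gene_ids(m: OmicsMatrix, mapping: Mapping[str, str] | pd.DataFrame) -> OmicsMatrix:
    """Translate gene identifiers through a two-column mapping table.

    Genes with no mapping are dropped (counted in the log). When several
    source genes map to the same target, the first occurrence in matrix row
    order is kept. An empty intersection is an error.
    """
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise ValueError("mapping table needs two columns (source, target)")
        src = [str(x) for x in mapping.iloc[:, 0]]
        _check_unique(src, "mapping source id")
        table = dict(zip(src, (str(x) for x in mapping.iloc[:, 1])))
    else:
        table = {str(k): str(v) for k, v in mapping.items()}

    keep_idx: list[int] = []
    new_ids: list[str] = []
    seen: set[str] = set()
    n_unmapped = 0
    n_collided = 0
    for i, g in enumerate(m.gene_ids):
        target = table.get(g)
        if target is None:
            n_unmapped += 1
            continue
        if target in seen:
            n_collided += 1
            continue
        seen.add(target)
        keep_idx.append(i)
        new_ids.append(target)
    if not keep_idx:
        raise ValueError("no gene identifier of the matrix appears in the mapping")
    if n_unmapped:
        logger.info("dropped %d gene(s) with no identifier mapping", n_unmapped)
    if n_collided:
        logger.info(
            "dropped %d gene(s) whose mapped identifier was already taken "
            "(first occurrence kept)",
            n_collided,
        )
    return OmicsMatrix(m.values[keep_idx, :], new_ids, list(m.sample_ids), m.kind)


def align_samples(cna: OmicsMatrix, ge: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both matrices to their shared samples, in a common order.

    Raises if the shared set is empty. After this call
    ``cna.sample_ids == ge.sample_ids`` exactly.
    """
    shared = [s for s in cna.sample_ids if s in set(ge.sample_ids)]
    if not shared:
        raise ValueError("copy-number and expression matrices share no samples")
    dropped = (len(cna.sample_ids) - len(shared)) + (len(ge.sample_ids) - len(shared))
    if dropped:
        logger.info("dropped %d sample column(s) absent from the other matrix", dropped)
    return cna.select_samples(shared), ge.select_samples(shared)


def subset_to_gene_set(
    cna: OmicsMatrix,
    ge: OmicsMatrix,
    gene_set: Sequence[str],
    min_genes: int = 2,
) -> tuple[OmicsMatrix, OmicsMatrix] | None:
    """Extract the per-set sub-matrices used by the interaction analysis.

    Returns the rows of each matrix whose gene belongs to ``gene_set``.
    The two returned matrices may hold different gene counts (a pathway's
    genes need not all be measured on both platforms) but share the sample
    axis. Returns ``None``, with a logged reason, when fewer than
    ``min_genes`` members are present in either matrix.
    """
    if cna.sample_ids != ge.sample_ids:
        raise ValueError(
            "sample axes are not aligned; call align_samples() before "
            "extracting gene sets"
        )
    sub_cna = cna.select_genes(gene_set)
    sub_ge = ge.select_genes(gene_set)
    if sub_cna.n_genes < min_genes or sub_ge.n_genes < min_genes:
        logger.info(
            "gene set skipped: only %d CNA / %d GE member gene(s) present "
            "(need >= %d in both)",
            sub_cna.n_genes,
            sub_ge.n_genes,
            min_genes,
        )
        return None
    return sub_cna, sub_ge


#: Column layout of the per-set results table (mirrors the method's
#: standard report: set name, member counts, per-group interaction scores,
#: the differential statistic, the permutation p and the significance call).
RESULT_COLUMNS = [
    "set_name",
    "n_cna",
    "n_exp",
    "ias_group_a",
    "ias_group_b",
    "diff_ias",
    "p_value",
    "adjusted_alpha",
    "significant",
    "n_permutations",
    "seed",
]


def write_results(results: Sequence, path: str | Path, extra_columns: Mapping[str, Sequence] | None = None) -> None:
    """Write a list of per-set interaction results to a TSV file.

    ``results`` is a sequence of objects exposing the attributes named in
    :data:`RESULT_COLUMNS` (see ``interaction.InteractionResult``). An
    empty list yields a header-only file.
    """
    rows = {c: [getattr(r, c) for r in results] for c in RESULT_COLUMNS}
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if extra_columns:
        for name, col in extra_columns.items():
            frame[name] = list(col)
    frame.to_csv(path, sep="\t", index=False)
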