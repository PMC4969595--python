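"""Expression matrices, ratio tables and gene sets.

The pipeline's universal input is a genes x conditions TPM table read from
tab-separated text (first column gene identifiers, header row condition
identifiers).  Gene identifiers are opaque, case-sensitive strings; no
symbol/ID mapping is attempted.  All downstream analyses consume
pseudo-counted expression ratios between two named conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateIdentifierError,
    EmptyMatrixError,
    GeneMismatchError,
    GeneSetFormatError,
    InvalidValueError,
    UnknownConditionError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes x conditions abundance table (TPM).

    Wraps a float :class:`pandas.DataFrame` whose index holds gene ids and
    whose columns hold condition ids.  Construction enforces: unique gene
    and condition identifiers, finite non-negative values, and at least one
    gene and one condition.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise EmptyMatrixError(f"matrix must be at least 1x1, got shape {df.shape}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate condition identifiers: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise InvalidValueError("matrix body must be numeric")
        if not np.all(np.isfinite(values)):
            raise InvalidValueError("matrix contains non-finite values")
        if np.any(values < 0):
            raise InvalidValueError("TPM values must be non-negative")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def condition_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, condition: str) -> np.ndarray:
        if condition not in self.data.columns:
            raise UnknownConditionError(
                f"condition {condition!r} not in {self.condition_ids}"
            )
        return self.data[condition].to_numpy()

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise GeneMismatchError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def to_tsv(self, path: str | Path, gene_column: str = "gene_id") -> None:
        """Write the matrix as TSV with full round-trip precision."""
        df = self.data.copy()
        df.index.name = gene_column
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass(frozen=True)
class RatioTable:
    """Per-gene pseudo-counted expression ratios between two conditions.

    ``ratio`` is linear-scale and strictly positive; ``log2_ratio`` is its
    base-2 logarithm.  Gene order matches the source matrix.
    """

    gene_ids: tuple[str, ...]
    numerator_condition: str
    denominator_condition: str
    ratio: np.ndarray
    log2_ratio: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ratio = np.asarray(self.ratio, dtype=float)
        if ratio.shape != (len(self.gene_ids),):
            raise GeneMismatchError("ratio length does not match gene_ids")
        if np.any(~np.isfinite(ratio)) or np.any(ratio <= 0):
            raise InvalidValueError("ratios must be finite and strictly positive")
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "ratio", ratio)
        object.__setattr__(self, "log2_ratio", np.log2(ratio))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.ratio, index=list(self.gene_ids), name="ratio")

    def subset(self, gene_ids: Sequence[str]) -> "RatioTable":
        """Restrict to ``gene_ids`` (kept in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            pos = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise GeneMismatchError(f"gene {exc.args[0]!r} not in ratio table") from exc
        return RatioTable(
            gene_ids=tuple(gene_ids),
            numerator_condition=self.numerator_condition,
            denominator_condition=self.denominator_condition,
            ratio=self.ratio[pos],
        )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT line): name, free-text description, members."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise GeneSetFormatError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))

    def __len__(self) -> int:
        return len(self.members)


def load_expression_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a TPM matrix from tab-separated text.

    First column gene ids, header row condition ids, numeric body.
    Raises ``FileNotFoundError``, :class:`MatrixFormatError` (non-numeric
    cell), :class:`DuplicateIdentifierError`, or :class:`EmptyMatrixError`.
    """
    from .exceptions import MatrixFormatError

    if format != "tsv":
        raise ValueError(f"unsupported matrix format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix file not found: {path}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            encoding="utf-8",
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise EmptyMatrixError(f"empty matrix file: {path}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise EmptyMatrixError(f"matrix in {path} has shape {df.shape}")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise MatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def filter_detectable(
    m: ExpressionMatrix, min_tpm: float, min_conditions: int = 1
) -> ExpressionMatrix:
    """Retain genes with TPM >= ``min_tpm`` in at least ``min_conditions`` conditions.

    Condition set and gene order are preserved.  An empty result is returned
    (with a logged warning), not raised.
    """
    if min_conditions < 1 or min_conditions > m.shape[1]:
        raise ValueError(
            f"min_conditions must be in [1, {m.shape[1]}], got {min_conditions}"
        )
    keep = (m.data.to_numpy() >= min_tpm).sum(axis=1) >= min_conditions
    if not keep.any():
        logger.warning(
            "detectability filter (min_tpm=%s, min_conditions=%d) removed all %d genes",
            min_tpm,
            min_conditions,
            m.shape[0],
        )
        # bypass the >=1-gene invariant of the public constructor deliberately:
        # an empty survivor set is a legal, warned-about outcome of filtering
        empty = object.__new__(ExpressionMatrix)
        object.__setattr__(empty, "data", m.data.iloc[:0])
        return empty
    return ExpressionMatrix(m.data.loc[keep])


def compute_ratio(
    m: ExpressionMatrix,
    numerator: str,
    denominator: str,
    pseudocount: float = 1.0,
) -> RatioTable:
    """Per-gene (x_num + pc) / (x_den + pc) and its log2, in matrix gene order."""
    if pseudocount < 0:
        raise InvalidValueError(f"pseudocount must be non-negative, got {pseudocount}")
    num = m.column(numerator) + pseudocount
    den = m.column(denominator) + pseudocount
    if np.any(den == 0):
        raise InvalidValueError(
            "zero denominator with pseudocount 0; use a positive pseudocount"
        )
    return RatioTable(
        gene_ids=tuple(m.gene_ids),
        numerator_condition=numerator,
        denominator_condition=denominator,
        ratio=num / den,
    )


def average_columns(
    m: ExpressionMatrix, groups: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Collapse replicate columns by arithmetic mean.

    ``groups`` maps each output condition id to the input condition ids it
    averages.  Conditions not mentioned are dropped.
    """
    out = {}
    for name, cols in groups.items():
        for c in cols:
            if c not in m.data.columns:
                raise UnknownConditionError(f"condition {c!r} not in matrix")
        out[name] = m.data[list(cols)].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index))


def load_gene_sets(path: str | Path, format: str = "gmt") -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name TAB description TAB member...``.

    Duplicated member names within a line collapse to one; a line with fewer
    than 3 fields or an empty file raises :class:`GeneSetFormatError`.
    """
    if format != "gmt":
        raise ValueError(f"unsupported gene-set format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene-set file not found: {path}")
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetFormatError(
                    f"{path}:{lineno}: expected name, description and >=1 member, "
                    f"got {len(fields)} field(s)"
                )
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise GeneSetFormatError(f"{path}:{lineno}: set has no members")
            sets.append(GeneSet(name=fields[0], description=fields[1], members=members))
    if not sets:
        raise GeneSetFormatError(f"no gene sets found in {path}")
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT (members sorted for deterministic output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
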