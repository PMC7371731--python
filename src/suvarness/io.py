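"""Domain containers and readers/writers for the pipeline's external formats.

Every downstream stage consumes only the types defined here:

* :class:`ExpressionMatrix` — log-scale expression, genes x samples;
* sample annotation tables (plain :class:`pandas.DataFrame`, validated by
  :func:`validate_annotations`);
* :class:`GeneSet` collections read from GMT files;
* :class:`OrthologMap` — a deduplicated cross-species gene-ID relation.

Expression matrices are tab-delimited text with gene IDs in the first
column and sample IDs in the header (the usual GEO series-matrix
orientation); a ``transposed`` flag accepts samples-in-rows input.
Gene IDs are opaque strings — no symbol normalization is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "GeneSet",
    "OrthologMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
    "read_ortholog_map",
    "write_ortholog_map",
]

ANNOTATION_COLUMNS = ["outcome_group", "time", "event", "condition", "cohort"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ExpressionMatrix:
    """Log-scale expression values indexed by gene ID x sample ID.

    Thin immutable wrapper around a genes-x-samples :class:`pandas.DataFrame`
    that enforces the container invariants: unique gene and sample IDs and
    all-finite numeric values. All pipeline operations accept and return
    this type; ``.data`` exposes the underlying frame read-only.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        index = data.index.astype(str)
        columns = data.columns.astype(str)
        if index.duplicated().any():
            dupes = index[index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if columns.duplicated().any():
            dupes = columns[columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression values: {exc}") from exc
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {index[bad[0]]!r}, sample {columns[bad[1]]!r}"
            )
        self._data = pd.DataFrame(values, index=index, columns=columns)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self._data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data[list(samples)])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene IDs (GMT line semantics)."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersection(self, genes: Iterable[str]) -> frozenset[str]:
        return self.members & frozenset(genes)


class OrthologMap:
    """Deduplicated, possibly many-to-many (source, target) gene relation."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        cleaned = set()
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-pair {a!r} crosses no species boundary")
            cleaned.add((a, b))
        self.pairs: frozenset[tuple[str, str]] = frozenset(cleaned)
        self._fwd: dict[str, set[str]] = {}
        self._rev: dict[str, set[str]] = {}
        for a, b in self.pairs:
            self._fwd.setdefault(a, set()).add(b)
            self._rev.setdefault(b, set()).add(a)

    def partners(self, gene: str, direction: str = "forward") -> frozenset[str]:
        table = self._fwd if direction == "forward" else self._rev
        return frozenset(table.get(str(gene), set()))

    def image(self, genes: Iterable[str], direction: str = "forward") -> frozenset[str]:
        out: set[str] = set()
        for g in genes:
            out |= self.partners(g, direction)
        return frozenset(out)

    def source_genes(self) -> frozenset[str]:
        return frozenset(self._fwd)

    def target_genes(self) -> frozenset[str]:
        return frozenset(self._rev)

    def invert(self) -> "OrthologMap":
        return OrthologMap((b, a) for a, b in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.pairs))


def read_expression_matrix(
    path: str | Path,
    transposed: bool = False,
    collapse: str = "max_variance",
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (genes in rows by default).

    Duplicate gene rows — typically multiple probes per gene — are collapsed
    per ``collapse``: ``"max_variance"`` keeps the row with the highest
    sample variance, ``"mean"`` averages rows. Duplicate sample columns are
    an error.
    """
    path = Path(path)
    with open(path) as handle:
        header_line = handle.readline().rstrip("\n")
    if not header_line:
        raise ParseError(f"{path}: empty expression file")
    header = header_line.split("\t")[1:]
    if not transposed and len(set(header)) < len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"{path}: duplicate sample IDs {dupes[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty expression file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no expression values found")
    df.columns = header  # undo pandas' mangling of any duplicate names
    try:
        # object->float via float(), which round-trips repr exactly
        values = df.to_numpy(dtype=object).astype(float)
    except (TypeError, ValueError):
        for r in range(df.shape[0]):
            for c in range(df.shape[1]):
                try:
                    float(df.iat[r, c])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {df.iat[r, c]!r} at row "
                        f"{df.index[r]!r}, column {df.columns[c]!r}"
                    ) from None
        raise
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    numeric = pd.DataFrame(values, index=df.index, columns=df.columns)
    if transposed:
        numeric = numeric.T
        if numeric.columns.duplicated().any():
            dupes = numeric.columns[numeric.columns.duplicated()].unique().tolist()
            raise ParseError(f"{path}: duplicate sample IDs {dupes[:5]}")
    if numeric.index.duplicated().any():
        numeric = _collapse_duplicate_genes(numeric, collapse)
    return ExpressionMatrix(numeric)


def _collapse_duplicate_genes(df: pd.DataFrame, how: str) -> pd.DataFrame:
    dup_ids = df.index[df.index.duplicated()].unique().tolist()
    log.info("collapsing %d duplicated gene IDs (%s)", len(dup_ids), how)
    if how == "mean":
        collapsed = df.groupby(level=0, sort=False).mean()
        # groupby(sort=False) preserves first-appearance order
        return collapsed
    if how != "max_variance":
        raise ValueError(f"unknown collapse rule {how!r}")
    keep_pos: list[int] = []
    seen: dict[str, int] = {}
    variances = df.var(axis=1, ddof=1).to_numpy()
    for pos, gene in enumerate(df.index):
        if gene not in seen:
            seen[gene] = pos
            keep_pos.append(pos)
        elif variances[pos] > variances[seen[gene]]:
            keep_pos[keep_pos.index(seen[gene])] = pos
            seen[gene] = pos
    return df.iloc[keep_pos]


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT gene sets: name <TAB> description <TAB> member ... per line."""
    sets: list[GeneSet] = []
    seen_names: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                log.warning("%s: line %d has duplicate members, deduplicated", path, lineno)
            if name in seen_names:
                raise ParseError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
            seen_names.add(name)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            if not gs.members:
                log.warning("skipping empty gene set %r in GMT output", gs.name)
                continue
            fields = [gs.name, gs.description, *sorted(gs.members)]
            handle.write("\t".join(fields) + "\n")


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/complete a sample annotation table.

    Required columns: ``sample_id``, ``outcome_group``. Optional ``time``
    (days, >= 0), ``event`` (0/1), ``condition``, ``cohort`` are filled with
    nulls when absent. Returns a frame indexed by ``sample_id``.
    """
    df = df.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if "outcome_group" not in df.columns:
        raise ParseError("annotation table lacks required column 'outcome_group'")
    if df.index.duplicated().any():
        raise ParseError("duplicate sample_id in annotation table")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    time = pd.to_numeric(df["time"], errors="raise")
    if (time.dropna() < 0).any():
        bad = df.index[time < 0][0]
        raise ParseError(f"negative survival time for sample {bad!r}")
    df["time"] = time.astype(float)
    event = pd.to_numeric(df["event"], errors="raise")
    observed = event.dropna()
    if not observed.isin([0, 1]).all():
        raise ParseError("event flags must be 0 (censored) or 1 (observed)")
    df["event"] = event
    return df[ANNOTATION_COLUMNS]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: annotation CSV lacks required column 'sample_id'")
    return validate_annotations(df)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, index_label="sample_id")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column (source, target) TSV into a deduplicated relation."""
    pairs: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(f.strip() for f in fields):
                raise ParseError(
                    f"{path}: line {lineno} is not a two-column ortholog pair"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    return OrthologMap(pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as handle:
        for a, b in omap:
            handle.write(f"{a}\t{b}\n")
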