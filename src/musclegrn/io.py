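"""Data model and readers/writers for expression matrices, DEG tables and gene sets.

All tabular inputs are plain TSV.  Expression matrices are genes x samples
with a header row of sample (or tissue / stage) names and gene identifiers
in the first column.  Gene sets use the GMT v1 convention
(``name<TAB>description<TAB>member...``).  Differential-expression tables
require the columns ``gene_id``, ``fold_change`` and ``p_value``.

Gene identifiers are matched case-sensitively after stripping surrounding
whitespace; no silent symbol normalisation is performed.  Missing values are
encoded as an empty cell or ``NA`` on disk and as ``NaN`` internally — never
as zero.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALUE_KINDS",
    "ExpressionMatrix",
    "GeneSet",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "make_deg_table",
    "read_deg",
    "write_deg",
    "filter_deg",
    "counts_to_fpkm",
    "log2_plus1",
    "good_samples_genes",
]

#: Recognised expression value kinds.  ``counts``/``fpkm``/``nx`` must be
#: non-negative; ``log2fpkm1`` is log2(FPKM + 1) and hence also >= 0.
VALUE_KINDS = ("counts", "fpkm", "log2fpkm1", "nx")

_NONNEGATIVE_KINDS = frozenset(VALUE_KINDS)

DEG_COLUMNS = ("gene_id", "fold_change", "p_value", "direction")


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with a declared value kind.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  ``NaN``
        marks a missing measurement.
    kind
        One of :data:`VALUE_KINDS`.
    gene_lengths
        Optional per-gene transcript length in base pairs (needed for the
        counts -> FPKM conversion).
    """

    values: pd.DataFrame
    kind: str
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.kind!r}; expected one of {VALUE_KINDS}")
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite")
        if self.kind in _NONNEGATIVE_KINDS:
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals, initial=0.0) < 0:
                    raise ValueError(f"{self.kind} values must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = pd.Series(self.gene_lengths, dtype=float)
            _check_unique(self.gene_lengths.index, "gene id in gene_lengths")
            if (self.gene_lengths <= 0).any():
                bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
                raise ValueError(f"gene length must be positive (gene {bad!r})")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, kind: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, kind or self.kind, gene_lengths=self.gene_lengths)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers (GMT-compatible)."""

    name: str
    description: str = ""
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        _check_unique(self.members, "member")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def __iter__(self):
        return iter(self.members)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.members)


# ---------------------------------------------------------------------------
# Matrix TSV
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str, gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV matrix.

    Malformed input (ragged rows, non-numeric cells, duplicate ids, no data
    rows) is rejected with the offending row/column named — never silently
    coerced.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: no data rows") from None
        samples = [s.strip() for s in header[1:]]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {len(header)})"
                )
            genes.append(row[0].strip())
            parsed: list[float] = []
            for col, cell in zip(samples, row[1:]):
                cell = cell.strip()
                if cell in ("", "NA"):
                    parsed.append(math.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, column {col!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    dup = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated gene row {dup[0]!r}")
    values = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(values, kind, gene_lengths=gene_lengths)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips through :func:`read_matrix`."""
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, expected >= 3")
            name, desc = fields[0].strip(), fields[1].strip()
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                m = m.strip()
                if not m:
                    continue
                if m in seen:
                    warnings.warn(f"{path}: duplicate member {m!r} in set {name!r}; deduplicated")
                    continue
                seen.add(m)
                members.append(m)
            sets.append(GeneSet(name, desc, tuple(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file (blank lines ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if g:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def make_deg_table(gene_ids: Sequence[str], fold_changes: Sequence[float],
                   p_values: Sequence[float]) -> pd.DataFrame:
    """Assemble and validate a DEG table.

    Fold changes are signed, linear-scale folds (|fc| >= 1 means a fold of
    that magnitude; the sign encodes the direction).  The ``direction``
    column is derived from the sign.
    """
    df = pd.DataFrame({
        "gene_id": [g.strip() for g in gene_ids],
        "fold_change": np.asarray(fold_changes, dtype=float),
        "p_value": np.asarray(p_values, dtype=float),
    })
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in DEG table")
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise ValueError("p_value outside [0, 1]")
    if not np.isfinite(df["fold_change"]).all():
        raise ValueError("fold_change must be finite")
    df["direction"] = np.where(df["fold_change"] >= 0, "up", "down")
    return df


def read_deg(path: str | Path, fold_scale: str = "linear") -> pd.DataFrame:
    """Read a DEG TSV with columns gene_id, fold_change, p_value.

    ``fold_scale`` declares how the fold_change column is encoded:
    ``linear`` (signed linear fold) or ``log2`` (signed log2 fold, converted
    to a signed linear fold on load).  Microarray exports vary, so the caller
    must state the convention explicitly.
    """
    if fold_scale not in ("linear", "log2"):
        raise ValueError(f"fold_scale must be 'linear' or 'log2', got {fold_scale!r}")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in ("gene_id", "fold_change", "p_value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    fc = df["fold_change"].astype(float).to_numpy()
    if fold_scale == "log2":
        fc = np.sign(fc) * 2.0 ** np.abs(fc)
    return make_deg_table(df["gene_id"].tolist(), fc, df["p_value"].astype(float).to_numpy())


def write_deg(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def filter_deg(table: pd.DataFrame, p_max: float = 0.05, min_fold: float = 2.0) -> pd.DataFrame:
    """Keep significantly regulated rows: p < p_max (strict) and |fold| >= min_fold (inclusive).

    The output preserves row order and the up/down partition; it is a subset
    of the input and the operation is idempotent.
    """
    keep = (table["p_value"] < p_max) & (table["fold_change"].abs() >= min_fold)
    return table.loc[keep].reset_index(drop=True)


def deg_direction_sets(table: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Split a DEG table into (up, down) gene-id sets."""
    up = set(table.loc[table["direction"] == "up", "gene_id"])
    down = set(table.loc[table["direction"] == "down", "gene_id"])
    return up, down


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def counts_to_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to FPKM.

    ``fpkm[g, s] = counts[g, s] * 1e9 / (length[g] * libsize[s])`` where the
    library size is the column sum of counts over the genes present in the
    matrix (the standard convention).
    """
    if matrix.kind != "counts":
        raise ValueError(f"expected a counts matrix, got {matrix.kind!r}")
    if matrix.gene_lengths is None:
        raise ValueError("gene_lengths required for FPKM conversion")
    missing = [g for g in matrix.gene_ids if g not in matrix.gene_lengths.index]
    if missing:
        raise ValueError(f"missing gene length for gene {missing[0]!r}")
    lengths = matrix.gene_lengths.loc[matrix.gene_ids].to_numpy()
    counts = matrix.values.to_numpy(dtype=float)
    libsize = np.nansum(counts, axis=0)
    zero = np.flatnonzero(libsize <= 0)
    if len(zero):
        raise ValueError(f"zero library size in sample {matrix.sample_ids[zero[0]]!r}")
    fpkm = counts * 1e9 / (lengths[:, None] * libsize[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=matrix.gene_ids, columns=matrix.sample_ids),
        "fpkm", gene_lengths=matrix.gene_lengths,
    )


def log2_plus1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); maps FPKM onto the scale used for co-expression."""
    if matrix.kind != "fpkm":
        raise ValueError(f"expected an fpkm matrix, got {matrix.kind!r}")
    vals = matrix.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("log2_plus1 requires non-negative input")
    out = pd.DataFrame(np.log2(vals + 1.0), index=matrix.gene_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(out, "log2fpkm1", gene_lengths=matrix.gene_lengths)


def good_samples_genes(matrix: ExpressionMatrix, max_missing_frac: float = 0.5
                       ) -> tuple[ExpressionMatrix, list[dict]]:
    """Iteratively drop uninformative genes and samples until a fixed point.

    Each pass removes genes with zero variance (over their non-missing
    values) or with a missing fraction above ``max_missing_frac``, then
    samples with a missing fraction above the threshold; removals can make
    further rows/columns removable, hence the iteration.  Returns the
    filtered matrix and an ordered removal log.
    """
    df = matrix.values.copy()
    log: list[dict] = []
    iteration = 0
    while True:
        iteration += 1
        changed = False
        if df.shape[0]:
            miss = df.isna().mean(axis=1)
            var = df.var(axis=1, ddof=0)
            n_obs = df.notna().sum(axis=1)
            bad_genes = df.index[(miss > max_missing_frac) | (var.fillna(0) == 0) | (n_obs == 0)]
            for g in bad_genes:
                reason = "missing" if miss[g] > max_missing_frac or n_obs[g] == 0 else "zero variance"
                log.append({"kind": "gene", "id": g, "reason": reason, "iteration": iteration})
            if len(bad_genes):
                df = df.drop(index=bad_genes)
                changed = True
        if df.shape[0] == 0:
            raise ValueError("no informative genes")
        miss_s = df.isna().mean(axis=0)
        bad_samples = df.columns[miss_s > max_missing_frac]
        for s in bad_samples:
            log.append({"kind": "sample", "id": s, "reason": "missing", "iteration": iteration})
        if len(bad_samples):
            df = df.drop(columns=bad_samples)
            changed = True
        if not changed:
            break
    return matrix.with_values(df), log
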