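"""Expression-matrix, metadata and gene-set I/O.

Expression data are carried as a dense gene × sample grid of log2 values
(a :class:`pandas.DataFrame`) bundled with optional per-sample metadata.
Gene sets use the tab-delimited GMT dialect (name, description, members).
The module also provides the two transforms every downstream stage relies
on: a log2 shift and mean-reference quantile normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "log2_transform",
    "quantile_normalize",
    "read_gmt",
    "write_gmt",
]


@dataclass
class ExpressionMatrix:
    """Gene × sample grid of log2 expression with optional sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        Every value must be finite; ids must be unique.
    metadata
        Optional DataFrame indexed by sample id holding attributes such as
        genotype, treatment or clinical fields. Every row must refer to a
        sample present in ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value for gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        if self.metadata is not None:
            unknown = self.metadata.index.difference(cols)
            if len(unknown):
                raise ValueError(
                    f"metadata refers to unknown samples: {sorted(map(str, unknown))}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy carrying ``values`` but the same metadata."""
        meta = None if self.metadata is None else self.metadata.copy()
        return ExpressionMatrix(values, meta)


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene identifiers."""

    name: str
    members: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def require_nonempty(self) -> "GeneSet":
        """Validate the analysis-input invariant that members are non-empty."""
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        return self

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited gene × sample matrix.

    The first column carries gene ids, the header row sample ids.  Duplicate
    ids and non-numeric or empty cells are errors reported with their
    coordinates.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"duplicate sample id: {s!r} in {path}")
        seen.add(s)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r} in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if len(bad):
        g, s = bad[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} in {path}"
        )
    return ExpressionMatrix(numeric.astype(float))


def write_expression_tsv(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the format :func:`read_expression_tsv` reads."""
    df = mat.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata table keyed by its first column (sample_id)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def log2_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace every value v by log2(v + pseudocount).

    Raises if any shifted value is non-positive (the log is undefined).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    arr = mat.values.to_numpy(dtype=float)
    shifted = arr + pseudocount
    if (shifted <= 0).any():
        g, s = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"value {arr[g, s]} + pseudocount {pseudocount} is not positive "
            f"(gene {mat.genes[g]!r}, sample {mat.samples[s]!r})"
        )
    out = pd.DataFrame(np.log2(shifted), index=mat.values.index, columns=mat.values.columns)
    return mat.with_values(out)


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common mean-reference distribution.

    The reference is the per-rank mean across columns of the sorted values;
    each column is replaced by the reference in its own rank order.  Tied
    values within a column receive the mean of the reference values spanning
    their tied ranks, so the output is invariant to the within-tie order.
    """
    if mat.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    vals = mat.values.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        sorted_col = col[order]
        # average the reference over runs of tied values
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        counts = np.diff(np.r_[starts, len(sorted_col)])
        if (counts > 1).any():
            run_means = np.add.reduceat(ref, starts) / counts
            assigned[order] = np.repeat(run_means, counts)
        out[:, j] = assigned
    df = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return mat.with_values(df)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line as name, description, members."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno} in {path}: expected at least "
                    f"3 tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, members=frozenset(members), description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT; members are sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fields = [gs.name, gs.description, *gs.sorted_members()]
            fh.write("\t".join(fields) + "\n")
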