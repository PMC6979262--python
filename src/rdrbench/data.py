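"""Core data containers, matrix I/O, normalization and expression stratification.

The universal input of every differential-expression test in this package is a
:class:`CountMatrix`: an isoforms x cells table of non-negative expression
estimates (not necessarily integers -- quantifiers such as Cufflinks or Salmon
produce fractional estimates), together with per-cell group labels and library
sizes.  Matrices are read from tab-separated text or Matrix Market files with
sidecar id lists.

Normalization is counts-per-million (CPM).  Simulated data carry no transcript
lengths, so CPM stands in for TPM wherever an expression threshold is applied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as _spio
from scipy import sparse as _sparse


class ValidationError(ValueError):
    """Input violates a CountMatrix invariant (e.g. negative entries)."""


class ParseError(ValueError):
    """A file could not be parsed into a matrix or label table."""


@dataclasses.dataclass
class CountMatrix:
    """Isoform x cell expression matrix with labels and library sizes.

    Parameters
    ----------
    values : ndarray, shape (n_isoforms, n_cells)
        Non-negative expression estimates; may be non-integer.
    isoform_ids, cell_ids : sequence of str
        Unique row / column identifiers.
    group_labels : sequence of str, optional
        One of exactly two group identifiers per cell; required by the tests
        but optional for a bare matrix.
    library_sizes : ndarray, optional
        Strictly positive per-cell totals.  Defaults to the observed column
        sums; a simulator may override them with the generative truth.
    """

    values: np.ndarray
    isoform_ids: np.ndarray
    cell_ids: np.ndarray
    group_labels: np.ndarray | None = None
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.isoform_ids = np.asarray(self.isoform_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_iso, n_cells = self.values.shape
        if len(self.isoform_ids) != n_iso:
            raise ValidationError(
                f"{len(self.isoform_ids)} isoform ids for {n_iso} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(f"{len(self.cell_ids)} cell ids for {n_cells} columns")
        if len(set(self.isoform_ids)) != n_iso:
            raise ValidationError("isoform ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell ids are not unique")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix entries must be finite and non-negative")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels, dtype=object)
            if len(self.group_labels) != n_cells:
                raise ValidationError("one group label per cell required")
        if self.library_sizes is None:
            self.library_sizes = self.values.sum(axis=0)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
            if len(self.library_sizes) != n_cells:
                raise ValidationError("one library size per cell required")
        if np.any(self.library_sizes <= 0):
            raise ValidationError("library sizes must be strictly positive")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_isoforms(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def groups(self) -> tuple[str, str]:
        """The two distinct group labels, in sorted order."""
        if self.group_labels is None:
            raise ValidationError("matrix has no group labels")
        labels = sorted(set(self.group_labels))
        if len(labels) != 2:
            raise ValidationError(f"expected exactly 2 groups, found {len(labels)}")
        return labels[0], labels[1]

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        g1, g2 = self.groups()
        lab = np.asarray(self.group_labels)
        return lab == g1, lab == g2

    def with_groups(self, labels: Sequence[str] | pd.Series) -> "CountMatrix":
        """Attach group labels (a cell -> group mapping or aligned sequence)."""
        if isinstance(labels, pd.Series):
            missing = [c for c in self.cell_ids if c not in labels.index]
            if missing:
                raise ValidationError(f"no group label for cells: {missing[:5]}")
            labels = [labels[c] for c in self.cell_ids]
        return dataclasses.replace(self, group_labels=np.asarray(labels, dtype=object))

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:  # treat as cell-id list
            idx = {c: i for i, c in enumerate(self.cell_ids)}
            mask_idx = np.array([idx[c] for c in mask], dtype=int)
        else:
            mask_idx = np.flatnonzero(mask)
        return CountMatrix(
            values=self.values[:, mask_idx],
            isoform_ids=self.isoform_ids,
            cell_ids=self.cell_ids[mask_idx],
            group_labels=None
            if self.group_labels is None
            else self.group_labels[mask_idx],
            library_sizes=self.library_sizes[mask_idx],
        )

    def subset_isoforms(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = {g: i for i, g in enumerate(self.isoform_ids)}
            rows = np.array([idx[g] for g in mask], dtype=int)
        else:
            rows = np.flatnonzero(mask)
        return CountMatrix(
            values=self.values[rows],
            isoform_ids=self.isoform_ids[rows],
            cell_ids=self.cell_ids,
            group_labels=self.group_labels,
            library_sizes=self.library_sizes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.isoform_ids), columns=list(self.cell_ids)
        )


@dataclasses.dataclass(frozen=True)
class Stratum:
    """A named subset of isoforms; high/low strata partition the isoform set."""

    name: str
    member_ids: tuple

    def __len__(self) -> int:
        return len(self.member_ids)


# -- normalization ---------------------------------------------------------


def compute_cpm(m: CountMatrix) -> np.ndarray:
    """Counts per million: entry(i,j) = values(i,j) / library_size(j) * 1e6."""
    if np.any(m.library_sizes <= 0):
        raise ValidationError("zero or negative library size")
    return m.values / m.library_sizes[None, :] * 1e6


def log_cpm(m: CountMatrix) -> np.ndarray:
    """Entrywise log2(CPM + 1); zero expression maps to zero."""
    return np.log2(compute_cpm(m) + 1.0)


def stratify_by_expression(
    m: CountMatrix, threshold: float = 1.0, cell_fraction: float = 0.25
) -> tuple[Stratum, Stratum]:
    """Split isoforms into highly and lowly expressed strata.

    An isoform is *high* iff its normalized expression (CPM, the TPM surrogate
    for length-free data) exceeds ``threshold`` in strictly more than
    ``cell_fraction`` of the cells; all remaining isoforms are *low*.  The two
    strata always partition the isoform set.
    """
    cpm = compute_cpm(m)
    frac = (cpm > threshold).mean(axis=1)
    high_mask = frac > cell_fraction
    high = Stratum("high", tuple(m.isoform_ids[high_mask]))
    low = Stratum("low", tuple(m.isoform_ids[~high_mask]))
    return high, low


# -- file I/O --------------------------------------------------------------


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(path.suffix + ".rows"), path.with_suffix(
        path.suffix + ".cols"
    )


def read_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read an expression matrix from a tsv or Matrix Market (.mtx) file.

    tsv files carry cell ids in the header row and isoform ids in the first
    column.  mtx files are accompanied by ``<name>.mtx.rows`` /
    ``<name>.mtx.cols`` sidecar id lists (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        iso, cells = df.index.astype(str).to_numpy(), df.columns.astype(str).to_numpy()
    elif fmt == "mtx":
        rows_f, cols_f = _mtx_sidecars(path)
        for f in (rows_f, cols_f):
            if not f.exists():
                raise ParseError(f"missing sidecar id file {f}")
        try:
            values = np.asarray(_spio.mmread(path).todense(), dtype=float)
        except Exception as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        iso = np.array(rows_f.read_text().split(), dtype=object)
        cells = np.array(cols_f.read_text().split(), dtype=object)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative entry at row {bad[0] + 1}, column {bad[1] + 1} of {path}"
        )
    return CountMatrix(values=values, isoform_ids=iso, cell_ids=cells)


def write_matrix(m: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as tsv or Matrix Market with sidecar id files."""
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        m.to_frame().to_csv(path, sep="\t", index_label="isoform_id")
    elif fmt == "mtx":
        _spio.mmwrite(str(path), _sparse.csr_matrix(m.values))
        rows_f, cols_f = _mtx_sidecars(path)
        rows_f.write_text("\n".join(map(str, m.isoform_ids)) + "\n")
        cols_f.write_text("\n".join(map(str, m.cell_ids)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column tab-separated cell -> group label file."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse labels file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"labels file {path} needs two tab-separated columns")
    # tolerate an optional header line
    if list(df.iloc[0]) == ["cell_id", "group"]:
        df = df.iloc[1:]
    return pd.Series(df[1].to_numpy(), index=df[0].to_numpy(), name="group")


def write_labels(m: CountMatrix, path: str | Path) -> None:
    if m.group_labels is None:
        raise ValidationError("matrix has no group labels to write")
    pd.DataFrame({0: m.cell_ids, 1: m.group_labels}).to_csv(
        path, sep="\t", header=False, index=False
    )
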