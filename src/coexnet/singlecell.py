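"""Marker positivity from raw single-cell counts.

A cell is called positive for a marker when its raw transcript count
passes a detection floor (count > 0 by default).  Positive fractions are
reported per condition — e.g. biopsies taken before androgen-receptor
inhibitor treatment versus after resistance — as exact integer counts
plus the percentage rounded to one decimal, matching how such fractions
are reported in clinical single-cell studies.

No normalisation, clustering or doublet handling happens here: the input
is assumed to be the raw counts of cells already identified as tumor
cells upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class SingleCellCounts:
    """Cells x genes non-negative integer count matrix.

    ``matrix`` may be dense or scipy-sparse; ``conditions`` optionally
    labels each cell (e.g. ``"pre"`` / ``"post"``).
    """

    matrix: np.ndarray | sp.spmatrix
    cell_ids: Sequence[str]
    genes: Sequence[str]
    conditions: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix rows")
        if len(self.genes) != n_genes:
            raise ValueError("genes length does not match matrix columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell IDs must be unique")
        if len(set(self.genes)) != n_genes:
            raise ValueError("gene symbols must be unique")
        if self.conditions is not None and len(self.conditions) != n_cells:
            raise ValueError("conditions length does not match matrix rows")
        data = self.matrix.data if sp.issparse(self.matrix) else np.asarray(self.matrix)
        if data.size and (data < 0).any():
            raise ValueError("counts must be non-negative")
        if data.size and np.any(data != np.round(data)):
            raise ValueError("counts must be integers")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense count vector for one gene across all cells."""
        try:
            j = list(self.genes).index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in count matrix") from None
        col = self.matrix[:, j]
        if sp.issparse(col):
            return np.asarray(col.todense()).ravel()
        return np.asarray(col).ravel()

    # -- I/O ------------------------------------------------------------
    def to_mtx(self, directory: str | Path) -> None:
        """Write MTX triplet plus ``genes.tsv`` / ``barcodes.tsv`` sidecars."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        m = sp.coo_matrix(self.matrix)
        scipy.io.mmwrite(str(directory / "matrix.mtx"), m, field="integer")
        (directory / "genes.tsv").write_text("\n".join(self.genes) + "\n")
        (directory / "barcodes.tsv").write_text("\n".join(self.cell_ids) + "\n")
        if self.conditions is not None:
            lines = [f"{c}\t{cond}" for c, cond in zip(self.cell_ids, self.conditions)]
            (directory / "conditions.tsv").write_text("\n".join(lines) + "\n")

    @classmethod
    def from_mtx(
        cls,
        matrix_path: str | Path,
        genes_path: str | Path,
        barcodes_path: str | Path,
        conditions_path: str | Path | None = None,
    ) -> "SingleCellCounts":
        matrix = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
        genes = Path(genes_path).read_text().split()
        cells = Path(barcodes_path).read_text().split()
        conditions = None
        if conditions_path is not None:
            table = pd.read_csv(
                conditions_path, sep="\t", header=None, names=["cell", "condition"]
            )
            lookup = dict(zip(table["cell"].astype(str), table["condition"].astype(str)))
            conditions = [lookup[c] for c in cells]
        return cls(matrix=matrix, cell_ids=cells, genes=genes, conditions=conditions)

    @classmethod
    def from_dense_tsv(
        cls, path: str | Path, conditions_path: str | Path | None = None
    ) -> "SingleCellCounts":
        """Read a dense TSV with cells as rows and genes as columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        conditions = None
        if conditions_path is not None:
            table = pd.read_csv(
                conditions_path, sep="\t", header=None, names=["cell", "condition"]
            )
            lookup = dict(zip(table["cell"].astype(str), table["condition"].astype(str)))
            conditions = [lookup[c] for c in df.index]
        return cls(
            matrix=df.to_numpy(),
            cell_ids=[str(c) for c in df.index],
            genes=[str(g) for g in df.columns],
            conditions=conditions,
        )


@dataclass
class PositivityResult:
    """Positive-cell tally for one condition group."""

    condition: str
    n_cells: int
    n_positive: int

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_cells

    @property
    def percent_1dp(self) -> float:
        """Percentage of positive cells rounded to one decimal place."""
        return round(100.0 * self.fraction, 1)


def call_positive(
    counts: SingleCellCounts, gene: str, min_count: int = 1
) -> np.ndarray:
    """Boolean positivity per cell: count for ``gene`` >= ``min_count``.

    ``min_count=1`` is the detection rule (any transcript observed);
    higher floors are supported for sensitivity analyses.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return counts.gene_counts(gene) >= min_count


def positivity_fraction(
    counts: SingleCellCounts,
    gene: str,
    by_condition: bool = False,
    min_count: int = 1,
) -> list[PositivityResult]:
    """Positive-cell fraction overall or per condition group.

    Returns one :class:`PositivityResult` per group; counts are exact
    integers and the only floating step is the final division.
    """
    positive = call_positive(counts, gene, min_count=min_count)
    if not by_condition:
        return [
            PositivityResult(
                condition="all", n_cells=counts.n_cells, n_positive=int(positive.sum())
            )
        ]
    if counts.conditions is None:
        raise ValueError("by_condition requested but no condition labels present")
    conditions = np.asarray(counts.conditions)
    results = []
    for cond in dict.fromkeys(counts.conditions):  # first-appearance order
        mask = conditions == cond
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"condition group {cond!r} is empty")
        results.append(
            PositivityResult(
                condition=str(cond), n_cells=n, n_positive=int(positive[mask].sum())
            )
        )
    return results
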