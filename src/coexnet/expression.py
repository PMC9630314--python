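"""Expression-matrix containers shared across the pipeline.

An :class:`ExpressionMatrix` is a gene x sample table of non-negative
abundances with an explicit unit tag, because the cohorts this package
merges (clinical RNA-seq compendia, normal-tissue atlases) ship in
different units: FPKM, TPM, RSEM transcript fraction, raw counts.  The
unit tag is what lets :mod:`coexnet.normalize` decide which conversion
applies; it is never guessed from the values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

#: Recognised expression units.
UNITS = ("FPKM", "TPM", "RSEM_FRACTION", "PSEUDO_TPM", "COUNTS")


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression matrix with a unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample IDs as columns.
    unit
        One of ``FPKM``, ``TPM``, ``RSEM_FRACTION``, ``PSEUDO_TPM``,
        ``COUNTS``.
    cohort_id
        Label of the cohort the samples came from.
    """

    values: pd.DataFrame
    unit: str
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r} in cohort {self.cohort_id!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r} in cohort {self.cohort_id!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

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

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with a leading ``gene`` column."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(
            json.dumps({"unit": self.unit, "cohort_id": self.cohort_id}, indent=2)
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, unit: str | None = None, cohort_id: str | None = None
    ) -> "ExpressionMatrix":
        """Read a TSV matrix (first column ``gene``).

        Unit and cohort are taken from the JSON sidecar written by
        :meth:`to_tsv` unless given explicitly.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta: dict = {}
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        unit = unit if unit is not None else meta.get("unit")
        if unit is None:
            raise ValueError("unit not given and no sidecar metadata found")
        cohort_id = cohort_id if cohort_id is not None else meta.get("cohort_id", "cohort")
        return cls(values=df, unit=unit, cohort_id=cohort_id)


@dataclass
class MergedExpression:
    """Multi-cohort matrix on the common gene set, rescaled to pseudo-TPM.

    Every column sums to one million; ``sample_provenance`` maps each
    sample ID back to the cohort it came from.
    """

    values: pd.DataFrame
    sample_provenance: Mapping[str, str]
    n_common_genes: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_common_genes == 0:
            self.n_common_genes = self.values.shape[0]
        missing = set(self.values.columns) - set(self.sample_provenance)
        if missing:
            raise ValueError(f"samples without provenance: {sorted(missing)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def cohort_samples(self, cohort_id: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_provenance[s] == cohort_id]

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "unit": "PSEUDO_TPM",
                    "n_common_genes": self.n_common_genes,
                    "sample_provenance": dict(self.sample_provenance),
                },
                indent=2,
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MergedExpression":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            values=df,
            sample_provenance=meta["sample_provenance"],
            n_common_genes=meta["n_common_genes"],
        )
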