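"""Cross-cohort expression normalisation to pseudo-TPM.

Clinical RNA-seq compendia ship in heterogeneous units (FPKM, TPM, RSEM
transcript fraction).  The harmonisation here follows the standard
recipe: convert each cohort to TPM, intersect on shared gene symbols,
concatenate samples and rescale every sample so its total is one
million again ("pseudo-TPM" — the rescale is needed because dropping
non-shared genes removes mass).  Gene symbols are matched by exact,
case-sensitive string equality; no alias resolution is attempted, which
keeps the merge reproducible.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, MergedExpression

MILLION = 1_000_000.0


def _rescale_columns(values: pd.DataFrame, target: float) -> pd.DataFrame:
    sums = values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(
            f"sample {zero.index[0]!r} has all-zero expression; rescale undefined"
        )
    return values * (target / sums)


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM by rescaling each sample to a 1e6 total.

    Within-sample proportions are preserved exactly; this is the
    gene-length-free conversion valid because FPKM and TPM differ only
    by a per-sample constant.
    """
    if m.unit != "FPKM":
        raise ValueError(f"expected FPKM input, got {m.unit}")
    return ExpressionMatrix(
        values=_rescale_columns(m.values, MILLION), unit="TPM", cohort_id=m.cohort_id
    )


def rsem_fraction_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert RSEM estimated transcript fractions to TPM (x 1e6)."""
    if m.unit != "RSEM_FRACTION":
        raise ValueError(f"expected RSEM_FRACTION input, got {m.unit}")
    if (m.values.to_numpy() > 1.0).any():
        raise ValueError("values > 1 are not transcript fractions")
    return ExpressionMatrix(
        values=m.values * MILLION, unit="TPM", cohort_id=m.cohort_id
    )


def to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Dispatch on the unit tag; TPM passes through unchanged."""
    if m.unit == "TPM":
        return m
    if m.unit == "FPKM":
        return fpkm_to_tpm(m)
    if m.unit == "RSEM_FRACTION":
        return rsem_fraction_to_tpm(m)
    raise ValueError(f"no TPM conversion defined for unit {m.unit}")


def merge_cohorts(cohorts: Sequence[ExpressionMatrix]) -> MergedExpression:
    """Merge >= 2 TPM cohorts on their common gene symbols.

    Rows are restricted to the symbol intersection (sorted for
    determinism), columns concatenated, and every sample rescaled to a
    1e6 total.  Sample IDs colliding across cohorts are prefixed with
    their cohort label.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to merge")
    for m in cohorts:
        if m.unit != "TPM":
            raise ValueError(
                f"cohort {m.cohort_id!r} is in {m.unit}; convert to TPM first"
            )
    common: set[str] = set(cohorts[0].genes)
    for m in cohorts[1:]:
        common &= set(m.genes)
    if not common:
        raise ValueError("gene-symbol intersection across cohorts is empty")
    genes = sorted(common)

    seen: set[str] = set()
    blocks, provenance = [], {}
    for m in cohorts:
        block = m.values.loc[genes]
        rename = {
            s: (f"{m.cohort_id}:{s}" if s in seen else s) for s in block.columns
        }
        block = block.rename(columns=rename)
        seen.update(block.columns)
        provenance.update({s: m.cohort_id for s in block.columns})
        blocks.append(block)
    merged = pd.concat(blocks, axis=1)
    merged = _rescale_columns(merged, MILLION)
    return MergedExpression(
        values=merged, sample_provenance=provenance, n_common_genes=len(genes)
    )


@dataclass
class GeneSummary:
    """Per-cohort distribution summary for one gene."""

    gene: str
    cohort: str
    n: int
    median: float
    q1: float
    q3: float
    ci_low: float
    ci_high: float


def summarize_gene(
    merged: MergedExpression,
    gene: str,
    seed: int = 0,
    n_boot: int = 2000,
) -> list[GeneSummary]:
    """Median / quartiles / bootstrap 95% CI of a gene, per cohort.

    The CI of the median is a seeded percentile bootstrap with
    ``n_boot`` resamples.
    """
    if gene not in merged.values.index:
        near = difflib.get_close_matches(gene, merged.values.index, n=3)
        raise KeyError(f"gene {gene!r} not in merged matrix; nearest: {near}")
    rng = np.random.default_rng(seed)
    out = []
    for cohort in dict.fromkeys(merged.sample_provenance.values()):
        cols = merged.cohort_samples(cohort)
        x = merged.values.loc[gene, cols].to_numpy(float)
        boot = np.median(
            rng.choice(x, size=(n_boot, x.size), replace=True), axis=1
        )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        out.append(
            GeneSummary(
                gene=gene,
                cohort=cohort,
                n=x.size,
                median=float(np.median(x)),
                q1=float(np.percentile(x, 25)),
                q3=float(np.percentile(x, 75)),
                ci_low=float(lo),
                ci_high=float(hi),
            )
        )
    return out
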