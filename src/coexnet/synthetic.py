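"""Synthetic expression data with known planted structure.

Every downstream stage of the pipeline — normalisation, network
similarity, signature extraction, enrichment, single-cell positivity —
is exercised against data generated here, where the ground truth is
known by construction:

* **Planted modules.**  A co-expression module is induced by a shared
  latent factor on the log scale (a Gaussian copula): for each sample,
  module gene g gets ``z_g = sqrt(rho) * f + sqrt(1 - rho) * eps_g``
  with f and eps_g standard normal, so every within-module pair has
  correlation exactly ``rho`` on the log scale.  Exponentiating gives
  the heavy-tailed, right-skewed positive marginals typical of TPM
  data, with the target correlation controlled independently of the
  marginal shape.
* **Heterogeneous units.**  Cohorts are emitted in FPKM (arbitrary
  per-sample library scale), TPM (columns sum to 1e6) or RSEM transcript
  fraction (columns sum to 1), so the unit-conversion and merge code
  paths see realistic inputs.
* **Background genes** are mutually independent (correlation exactly 0),
  keeping planted-module recovery tests sharp.
* **Single-cell counts** are zero-inflated: a gene is detected in a cell
  with its configured detection fraction, and detected counts are
  ``1 + Poisson(mean - 1)`` so "detected" strictly means count > 0.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix
from .singlecell import SingleCellCounts

#: log-scale mean for background genes (~ exp(4) = 55 abundance units).
BACKGROUND_MEAN_LOG = 4.0
#: detection fraction for single-cell genes not configured explicitly.
DEFAULT_DETECTION = 0.05
#: log-SD of the per-sample library-size factor applied to FPKM cohorts.
FPKM_LIBRARY_SD = 0.3


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``within_correlation`` is the pairwise log-scale correlation among
    the module's genes; ``module_signal_sd`` the log-scale SD of each
    member; ``mean_log_expression`` the log-scale mean (natural log of
    abundance units).
    """

    module_id: str
    genes: tuple[str, ...]
    within_correlation: float
    mean_log_expression: float = BACKGROUND_MEAN_LOG
    module_signal_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.module_id!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.module_id!r} has duplicate gene symbols")
        if not (0.0 <= self.within_correlation <= 1.0):
            raise ValueError(
                f"module {self.module_id!r}: within_correlation "
                f"{self.within_correlation} outside [0, 1]"
            )
        if self.module_signal_sd <= 0:
            raise ValueError(f"module {self.module_id!r}: module_signal_sd must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """One simulated bulk cohort.

    ``noise_sd`` is the log-scale SD of the independent background
    genes; module genes' spread is set by their ModuleSpec so that the
    planted correlation is not diluted.
    """

    cohort_id: str
    n_samples: int
    unit: str = "TPM"
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.unit not in ("FPKM", "TPM", "RSEM_FRACTION"):
            raise ValueError(f"unsupported generator unit {self.unit!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SingleCellSpec:
    """Sparse single-cell counts with per-gene detection fractions."""

    n_cells: int
    n_genes: int
    detection_fraction: Mapping[str, float]
    mean_count_when_detected: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if len(self.detection_fraction) > self.n_genes:
            raise ValueError("more detection fractions than genes")
        for g, p in self.detection_fraction.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"detection fraction for {g!r} outside [0, 1]")
        if self.mean_count_when_detected < 1.0:
            raise ValueError("mean_count_when_detected must be >= 1")


def _check_gene_symbols(modules: Sequence[ModuleSpec], extra: Sequence[str]) -> None:
    seen: set[str] = set()
    for mod in modules:
        for g in mod.genes:
            if g in seen:
                raise ValueError(f"duplicate gene symbol {g!r} across modules")
            seen.add(g)
    for g in extra:
        if g in seen:
            raise ValueError(f"duplicate gene symbol {g!r} (module vs background)")
        seen.add(g)


def _apply_unit(values: np.ndarray, unit: str, rng: np.random.Generator) -> np.ndarray:
    if unit == "TPM":
        return values * (1e6 / values.sum(axis=0))
    if unit == "RSEM_FRACTION":
        return values / values.sum(axis=0)
    if unit == "FPKM":
        # FPKM columns carry an arbitrary per-sample depth factor; only
        # within-sample proportions are meaningful.
        factors = rng.lognormal(mean=0.0, sigma=FPKM_LIBRARY_SD, size=values.shape[1])
        return values * factors
    raise ValueError(f"unsupported unit {unit!r}")


def generate_cohort(
    cohort: CohortSpec,
    modules: Sequence[ModuleSpec] = (),
    n_background_genes: int = 0,
    background_genes: Sequence[str] | None = None,
    extra_gene_names: Sequence[str] = (),
) -> ExpressionMatrix:
    """Simulate one bulk cohort with planted modules plus background.

    Background genes default to ``BG0000, BG0001, ...``; explicit names
    can be given (used by :func:`generate_multicohort` to share or
    privatise genes across cohorts).  Reproducible bit-for-bit given the
    cohort seed.
    """
    if background_genes is None:
        background_genes = [f"BG{i:04d}" for i in range(n_background_genes)]
    background_genes = list(background_genes) + list(extra_gene_names)
    _check_gene_symbols(modules, background_genes)
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n_samples

    rows: list[np.ndarray] = []
    names: list[str] = []
    for mod in modules:
        rho = mod.within_correlation
        factor = rng.standard_normal(n)
        for g in mod.genes:
            z = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * rng.standard_normal(n)
            rows.append(mod.mean_log_expression + mod.module_signal_sd * z)
            names.append(g)
    for g in background_genes:
        rows.append(
            BACKGROUND_MEAN_LOG + cohort.noise_sd * rng.standard_normal(n)
        )
        names.append(g)
    if not rows:
        raise ValueError("cohort would contain no genes")

    base = np.exp(np.vstack(rows))
    values = _apply_unit(base, cohort.unit, rng)
    df = pd.DataFrame(
        values,
        index=names,
        columns=[f"{cohort.cohort_id}_S{j:04d}" for j in range(n)],
    )
    return ExpressionMatrix(values=df, unit=cohort.unit, cohort_id=cohort.cohort_id)


def generate_multicohort(
    cohorts: Sequence[CohortSpec],
    shared_modules: Sequence[ModuleSpec] = (),
    per_cohort_extra_genes: int = 0,
    n_background_genes: int = 50,
) -> list[ExpressionMatrix]:
    """Simulate several cohorts sharing modules and background genes.

    Every cohort contains the shared module and background genes; each
    additionally carries ``per_cohort_extra_genes`` private genes absent
    from the others, so the size of the gene-symbol intersection is
    known a priori (modules + background).
    """
    if len(cohorts) == 0:
        raise ValueError("need at least one cohort spec")
    if len(cohorts) < 2:
        raise ValueError("a multicohort simulation needs >= 2 cohorts")
    ids = [c.cohort_id for c in cohorts]
    if len(set(ids)) != len(ids):
        raise ValueError("cohort IDs must be unique")
    out = []
    for c in cohorts:
        private = [f"{c.cohort_id}_PRIV{i:03d}" for i in range(per_cohort_extra_genes)]
        out.append(
            generate_cohort(
                c,
                modules=shared_modules,
                n_background_genes=n_background_genes,
                extra_gene_names=private,
            )
        )
    return out


def generate_single_cell(spec: SingleCellSpec) -> SingleCellCounts:
    """Simulate zero-inflated single-cell counts.

    Per gene g, each cell is detected with probability
    ``detection_fraction[g]`` (genes not listed use
    ``DEFAULT_DETECTION``); detected cells draw
    ``1 + Poisson(mean_count_when_detected - 1)`` so every detected
    count is strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.detection_fraction)
    genes += [f"G{i:04d}" for i in range(spec.n_genes - len(genes))]
    fractions = [spec.detection_fraction.get(g, DEFAULT_DETECTION) for g in genes]
    counts = np.zeros((spec.n_cells, spec.n_genes), dtype=np.int64)
    lam = spec.mean_count_when_detected - 1.0
    for j, p in enumerate(fractions):
        detected = rng.random(spec.n_cells) < p
        counts[detected, j] = 1 + rng.poisson(lam, size=int(detected.sum()))
    return SingleCellCounts(
        matrix=counts,
        cell_ids=[f"CELL{i:05d}" for i in range(spec.n_cells)],
        genes=genes,
    )


def generate_gene_sets(
    modules: Sequence[ModuleSpec],
    n_random_sets: int,
    set_size: int,
    universe: Sequence[str],
    seed: int = 0,
) -> GeneSetCollection:
    """One exact gene set per planted module plus random decoy sets.

    Random sets are uniform without-replacement draws of ``set_size``
    genes from ``universe``; module sets are the modules' exact gene
    lists.  GMT-serialisable via :meth:`GeneSetCollection.to_gmt`.
    """
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError(
            f"set_size {set_size} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for mod in modules:
        sets[f"MODULE_{mod.module_id}"] = list(mod.genes)
    for i in range(n_random_sets):
        draw = rng.choice(len(universe), size=set_size, replace=False)
        sets[f"RANDOM_{i:03d}"] = [universe[j] for j in sorted(draw)]
    return GeneSetCollection(sets=sets, source="synthetic")


def write_spec_metadata(spec, path: str | Path) -> None:
    """Echo any generator spec to JSON alongside its output files."""
    from dataclasses import asdict, is_dataclass

    def _convert(obj):
        if is_dataclass(obj):
            return asdict(obj)
        if isinstance(obj, (list, tuple)):
            return [_convert(o) for o in obj]
        return obj

    Path(path).write_text(json.dumps(_convert(spec), indent=2, default=str))
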