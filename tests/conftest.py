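"""Shared fixtures: planted-module cohorts sized for fast, sharp tests."""

from __future__ import annotations

import numpy as np
import pytest

import coexnet as cx

MODULE_GENES = tuple(f"MOD{i}" for i in range(8))


def planted_module(rho: float = 0.9) -> cx.ModuleSpec:
    return cx.ModuleSpec("M1", MODULE_GENES, within_correlation=rho)


def planted_cohort(
    seed: int, rho: float = 0.9, n_samples: int = 500, n_background: int = 72
) -> cx.ExpressionMatrix:
    """One TPM cohort with an 8-gene module of correlation rho planted."""
    spec = cx.CohortSpec("SIM", n_samples=n_samples, unit="TPM", seed=seed)
    return cx.generate_cohort(
        spec, modules=[planted_module(rho)], n_background_genes=n_background
    )


@pytest.fixture(scope="session")
def module_genes() -> tuple[str, ...]:
    return MODULE_GENES


@pytest.fixture(scope="session")
def planted_similarity() -> cx.NetworkSimilarityMatrix:
    """Network-similarity matrix of one planted-module cohort (seed 0)."""
    cohort = planted_cohort(seed=0)
    return cx.network_similarity(cx.correlation_matrix(cohort))


@pytest.fixture(scope="session")
def random_expression() -> cx.ExpressionMatrix:
    """Structureless 20-gene x 30-sample cohort (background only)."""
    spec = cx.CohortSpec("RND", n_samples=30, unit="TPM", seed=123)
    return cx.generate_cohort(spec, modules=[], n_background_genes=20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230901)
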