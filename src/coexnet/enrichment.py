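"""Preranked gene-set enrichment analysis (GSEA) from first principles.

Given a profile of genes ranked by their signed association with a
query gene, the enrichment score (ES) of a gene set is the maximum
deviation of a weighted Kolmogorov-Smirnov running sum: walking down
the ranking, hitting a set member increments the sum by that gene's
|score|^p share of the set's total weight, and every miss decrements it
by 1/(N - Nh).  Significance comes from a gene-label permutation null
(random sets of the same size drawn from the universe), which yields a
sign-normalised NES, a nominal p per set and a collection-wide FDR q.

The association profile itself is built per cohort — the correlation of
the query gene with every other gene — and averaged across cohorts, so
several heterogeneous studies can contribute to one ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, MergedExpression
from .io import read_gmt, write_gmt
from .network import _apply_transform, _expression_frame

logger = logging.getLogger(__name__)


def _sorted_descending(scores: pd.Series) -> pd.Series:
    """Sort scores descending, ties broken by gene symbol."""
    frame = scores.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(frame["score"].to_numpy(), index=frame["gene"].to_numpy())


@dataclass
class RankedProfile:
    """Genes ordered by signed association with a query gene.

    ``scores`` is descending; the query itself is excluded.
    """

    query: str
    scores: pd.Series

    def __post_init__(self) -> None:
        if self.query in self.scores.index:
            raise ValueError("query gene must be excluded from its own profile")
        if not self.scores.index.is_unique:
            raise ValueError("profile genes must be unique")
        if (np.diff(self.scores.to_numpy()) > 0).any():
            raise ValueError("profile scores must be sorted descending")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)

    def to_rnk(self, path) -> None:
        self.scores.to_csv(path, sep="\t", header=False)

    @classmethod
    def from_rnk(cls, path, query: str) -> "RankedProfile":
        from .io import read_rnk

        return cls(query=query, scores=_sorted_descending(read_rnk(path)))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. oncogenic signature collections) read from GMT."""

    sets: dict[str, list[str]]
    source: str = "user"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path, source: str | None = None) -> "GeneSetCollection":
        return cls(sets=read_gmt(path), source=source or str(path))

    def to_gmt(self, path) -> None:
        write_gmt(self.sets, path)


def rank_profile(
    cohorts: Sequence["ExpressionMatrix | MergedExpression | pd.DataFrame"],
    query: str,
    method: str = "pearson",
    transform: str = "log2p1",
    profile_mode: str = "correlation",
) -> RankedProfile:
    """Rank all genes by association with ``query`` across cohorts.

    ``profile_mode="correlation"`` (default): per cohort, the
    correlation of the query gene with every other gene, then the
    per-gene arithmetic mean across cohorts.  ``"mean_expression"``
    ranks genes by their mean transformed expression instead (no query
    association; the query is still excluded from the ranking).
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    per_cohort: list[pd.Series] = []
    for i, cohort in enumerate(cohorts):
        frame = _expression_frame(cohort)
        label = getattr(cohort, "cohort_id", f"cohort_{i}")
        if query not in frame.index:
            raise KeyError(f"query gene {query!r} missing from cohort {label!r}")
        X = _apply_transform(frame.to_numpy(float), transform)
        if method == "spearman":
            from scipy.stats import rankdata

            X = rankdata(X, axis=1)
        elif method != "pearson":
            raise ValueError(f"unknown correlation method {method!r}")
        if profile_mode == "mean_expression":
            per_cohort.append(pd.Series(X.mean(axis=1), index=frame.index))
            continue
        if profile_mode != "correlation":
            raise ValueError(f"unknown profile_mode {profile_mode!r}")
        qi = list(frame.index).index(query)
        q = X[qi]
        if q.std() == 0:
            raise ValueError(f"query gene {query!r} is constant in cohort {label!r}")
        Xc = X - X.mean(axis=1, keepdims=True)
        qc = q - q.mean()
        norms = np.sqrt((Xc**2).sum(axis=1)) * np.sqrt((qc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ qc) / norms
        per_cohort.append(pd.Series(np.clip(r, -1, 1), index=frame.index))

    combined = pd.concat(per_cohort, axis=1, join="inner").mean(axis=1)
    combined = combined.drop(index=query, errors="ignore").dropna()
    return RankedProfile(query=query, scores=_sorted_descending(combined))


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]


def enrichment_score(
    profile: RankedProfile,
    gene_set: Sequence[str],
    weight_p: float = 1.0,
) -> EnrichmentScore:
    """Weighted KS enrichment score of one gene set on a ranked profile.

    Hits are weighted by |score|^weight_p normalised to the set's total
    weight; misses are penalised 1/(N - Nh).  ES is the running sum's
    maximum-magnitude deviation from zero; the leading edge is the set
    members at or before (after, for negative ES) the extremum.
    """
    genes = np.asarray(profile.genes)
    scores = profile.scores.to_numpy(float)
    n = genes.size
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no overlap with the ranked profile")
    if nh == n:
        raise ValueError("gene set covers the entire universe; miss penalty undefined")

    weights = np.abs(scores) ** weight_p * hit
    total = weights.sum()
    if total == 0:  # all hit scores are exactly 0: fall back to equal weights
        weights = hit.astype(float)
        total = float(nh)
    p_hit = np.cumsum(weights) / total
    p_miss = np.cumsum(~hit) / (n - nh)
    running = p_hit - p_miss
    hi, lo = float(running.max()), float(running.min())
    # Tie-break convention: when the positive and negative extrema tie in
    # magnitude (within 1e-12), report the positive deviation.
    if hi >= -lo - 1e-12:
        es = hi
        peak = int(np.argmax(running))
    else:
        es = lo
        peak = int(np.argmin(running))
    if es >= 0:
        leading = genes[: peak + 1][hit[: peak + 1]]
    else:
        leading = genes[peak:][hit[peak:]]
    return EnrichmentScore(es=es, running_sum=running, leading_edge=list(leading))


def _es_from_positions(
    abs_weight: np.ndarray, positions: np.ndarray, n: int
) -> float:
    """Fast ES using only the hit positions (0-based, sorted ascending).

    The running sum attains its extrema only immediately before or
    after a hit, so O(k) candidates suffice; used for permutation nulls.
    """
    k = positions.size
    w = abs_weight[positions]
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    cum_after = np.cumsum(w) / total
    miss_before = (positions - np.arange(k)) / (n - k)
    r_after = cum_after - miss_before
    r_before = (cum_after - w / total) - miss_before
    hi = float(r_after.max())
    lo = float(r_before.min())
    return hi if hi >= -lo - 1e-12 else lo  # same tie-break as enrichment_score


def _null_es_batch(
    abs_weight: np.ndarray, k: int, n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES for ``n_perm`` random size-k sets, fully vectorised.

    Same O(k)-candidate logic as :func:`_es_from_positions`, applied to
    a (n_perm, k) matrix of sorted hit positions at once.
    """
    pos = np.sort(rng.random((n_perm, n)).argsort(axis=1)[:, :k], axis=1)
    w = abs_weight[pos]
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        total[zero] = float(k)
    cum_after = np.cumsum(w, axis=1) / total
    miss_before = (pos - np.arange(k)) / (n - k)
    r_after = cum_after - miss_before
    r_before = (cum_after - w / total) - miss_before
    hi = r_after.max(axis=1)
    lo = r_before.min(axis=1)
    return np.where(hi >= -lo - 1e-12, hi, lo)


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_hits_in_universe: int
    leading_edge: list[str] = field(default_factory=list)


def nes_and_fdr(
    profile: RankedProfile,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
) -> list[EnrichmentResult]:
    """ES, NES, nominal p and FDR q for every set in a collection.

    The null is a gene-label permutation: for every set, random
    same-size subsets of the profile universe, drawn independently per
    set so that the p-values of different sets do not share null draws.
    NES divides each ES by the mean magnitude of its set's same-sign
    null ES; nominal p is the same-sign null tail fraction; FDR q
    follows the GSEA convention, the ratio of the pooled null NES tail
    fraction to the observed NES tail fraction, clipped to [0, 1].
    Fully deterministic given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    genes = np.asarray(profile.genes)
    index = {g: i for i, g in enumerate(genes)}
    n = genes.size
    abs_weight = np.abs(profile.scores.to_numpy(float)) ** weight_p

    observed: list[tuple[str, EnrichmentScore, int]] = []
    for name, members in collection.sets.items():
        k = len(set(members) & set(genes))
        if k == 0:
            logger.warning("gene set %r has no overlap with the profile; skipped", name)
            continue
        observed.append((name, enrichment_score(profile, members, weight_p), k))
    if not observed:
        raise ValueError("no gene set overlaps the ranked profile")

    def _norms(draws: np.ndarray) -> tuple[float, float]:
        pos = draws[draws > 0]
        neg = -draws[draws < 0]
        fallback = np.abs(draws).mean() or 1.0
        return (
            float(pos.mean()) if pos.size else float(fallback),
            float(neg.mean()) if neg.size else float(fallback),
        )

    null_es: list[np.ndarray] = [
        _null_es_batch(abs_weight, k, n, n_permutations, rng)
        for _, _, k in observed
    ]
    null_nes: list[np.ndarray] = []
    results: list[EnrichmentResult] = []
    obs_nes = []
    for (name, score, k), draws in zip(observed, null_es):
        pos_mean, neg_mean = _norms(draws)
        null_nes.append(np.where(draws >= 0, draws / pos_mean, draws / neg_mean))
        nes = score.es / pos_mean if score.es >= 0 else score.es / neg_mean
        if score.es >= 0:
            same = draws[draws > 0]
        else:
            same = -draws[draws < 0]
        p = float((same >= abs(score.es)).mean()) if same.size else 0.0
        obs_nes.append(nes)
        results.append(
            EnrichmentResult(
                name=name,
                es=score.es,
                nes=float(nes),
                nominal_p=p,
                fdr_q=np.nan,  # filled below
                n_hits_in_universe=k,
                leading_edge=score.leading_edge,
            )
        )

    pooled_null = np.concatenate(null_nes)
    obs_arr = np.asarray(obs_nes)
    pos_null = pooled_null[pooled_null >= 0]
    neg_null = pooled_null[pooled_null < 0]
    pos_obs = obs_arr[obs_arr >= 0]
    neg_obs = obs_arr[obs_arr < 0]
    for res in results:
        if res.nes >= 0:
            num = (pos_null >= res.nes).mean() if pos_null.size else 0.0
            den = (pos_obs >= res.nes).mean()
        else:
            num = (neg_null <= res.nes).mean() if neg_null.size else 0.0
            den = (neg_obs <= res.nes).mean()
        res.fdr_q = float(np.clip(num / den, 0.0, 1.0)) if den > 0 else 0.0

    results.sort(key=lambda r: (-r.nes, r.name))
    return results


def filter_results(
    results: Sequence[EnrichmentResult],
    nes_cutoff: float = 1.4,
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Keep results with |NES| >= cutoff and FDR q <= cutoff.

    The 1.4 default is the NES threshold commonly used when tabulating
    significant oncogenic-signature enrichments.
    """
    kept = [r for r in results if abs(r.nes) >= nes_cutoff and r.fdr_q <= fdr_cutoff]
    return sorted(kept, key=lambda r: -abs(r.nes))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per set) for TSV export."""
    return pd.DataFrame(
        {
            "set": [r.name for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "n_hits": [r.n_hits_in_universe for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
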