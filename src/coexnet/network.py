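"""Gene-network construction by second-order correlation.

A gene's "network" is its vector of co-expression correlations to every
other gene.  Two genes' networks are compared by correlating those
vectors — a correlation of correlation profiles — yielding a similarity
score in [-1, 1]: 1 for genes embedded in the same co-expression
neighbourhood, -1 for discordant neighbourhoods.  Downstream, a query
gene's "network signature" is the set of genes whose similarity to it
meets a threshold (0.7 by default), and the full gene x gene similarity
matrix can be embedded in 2-D with UMAP so that distance on the plane
reflects network similarity.

Two numerical details matter and are handled explicitly:

* the first-order correlation is computed, by default, on
  log2(expression + 1) — TPM-scale data are strongly right-skewed and a
  handful of extreme samples would otherwise dominate every profile;
* before correlating two profiles, the entries at both genes' own
  positions are removed from both vectors.  The structural 1 on the
  diagonal (and the pair's mutual correlation) would otherwise inflate
  the similarity of every pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, MergedExpression

logger = logging.getLogger(__name__)

DEFAULT_SIGNATURE_THRESHOLD = 0.7


def _expression_frame(
    m: "ExpressionMatrix | MergedExpression | pd.DataFrame",
) -> pd.DataFrame:
    if isinstance(m, pd.DataFrame):
        return m
    return m.values


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(values + 1.0)
    if transform == "none":
        return values
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class CorrelationMatrix:
    """First-order gene x gene correlation over samples.

    Zero-variance genes have undefined correlations; their rows/columns
    are NaN and listed in ``dropped_genes``.
    """

    values: pd.DataFrame
    method: str
    transform: str
    n_samples: int
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def correlation_matrix(
    m: "ExpressionMatrix | MergedExpression | pd.DataFrame",
    method: str = "pearson",
    transform: str = "log2p1",
) -> CorrelationMatrix:
    """All-pairs gene correlation across samples.

    ``method`` is ``pearson`` or ``spearman``; ``transform`` is applied
    to the expression values first (``log2p1`` or ``none``).  Genes with
    zero variance after the transform get NaN entries and are reported
    in ``dropped_genes`` (downstream stages exclude them).
    """
    frame = _expression_frame(m)
    if frame.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate genes")
    X = _apply_transform(frame.to_numpy(float), transform)
    if method == "spearman":
        from scipy.stats import rankdata

        X = rankdata(X, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    constant = X.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    dropped = [g for g, flag in zip(frame.index, constant) if flag]
    if dropped:
        logger.info(
            "correlation_matrix: %d zero-variance gene(s) flagged: %s",
            len(dropped),
            dropped[:10],
        )
    return CorrelationMatrix(
        values=pd.DataFrame(corr, index=frame.index, columns=frame.index),
        method=method,
        transform=transform,
        n_samples=frame.shape[1],
        dropped_genes=dropped,
    )


@dataclass
class NetworkSimilarityMatrix:
    """Symmetric gene x gene matrix of network-similarity scores.

    Entries lie in [-1, 1] with a unit diagonal.  Genes whose
    first-order correlations were undefined are excluded entirely
    (``excluded_genes``).
    """

    values: pd.DataFrame
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "NetworkSimilarityMatrix":
        return cls(values=pd.read_csv(path, sep="\t", index_col=0))


def network_similarity(c: CorrelationMatrix) -> NetworkSimilarityMatrix:
    """Second-order similarity: correlate every pair of correlation profiles.

    ``S[i, j]`` is the Pearson correlation between gene i's and gene j's
    rows of the first-order matrix, computed over all other genes — the
    entries at positions i and j are removed from both profiles before
    correlating.  The result is symmetric with a unit diagonal.

    The pairwise exclusion is computed in closed form from row sums, row
    sums of squares and the Gram matrix, so the whole matrix costs one
    matrix product rather than an explicit double loop.
    """
    valid = [g for g in c.genes if g not in set(c.dropped_genes)]
    if len(valid) < 4:
        raise ValueError("need at least 4 genes with defined correlations")
    if c.dropped_genes:
        logger.info(
            "network_similarity: excluding %d gene(s) with undefined correlations",
            len(c.dropped_genes),
        )
    C = c.values.loc[valid, valid].to_numpy(float)
    G = C.shape[0]
    n = G - 2  # profile length after removing both self positions

    row_sum = C.sum(axis=1)
    row_sq = (C**2).sum(axis=1)
    gram = C @ C  # C is symmetric

    # For pair (i, j), profile i drops C[i,i]=1 and C[i,j]; profile j
    # drops C[j,j]=1 and C[j,i].  All reduced sums follow from the full
    # row statistics.
    sx = row_sum[:, None] - 1.0 - C
    sy = sx.T
    sxx = row_sq[:, None] - 1.0 - C**2
    syy = sxx.T
    sxy = gram - 2.0 * C  # subtract C[i,i]*C[j,i] + C[i,j]*C[j,j]

    cov = sxy - sx * sy / n
    var_x = sxx - sx**2 / n
    var_y = syy - sy**2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        S = cov / np.sqrt(var_x * var_y)
    degenerate = (var_x <= 0) | (var_y <= 0)
    if degenerate.any():
        n_bad = int(degenerate.sum() - np.trace(degenerate))
        if n_bad:
            logger.info(
                "network_similarity: %d pair(s) with zero-variance profiles "
                "recorded as missing",
                n_bad,
            )
        S[degenerate] = np.nan
    S = np.clip(S, -1.0, 1.0)
    S = (S + S.T) / 2.0  # enforce exact symmetry against rounding
    np.fill_diagonal(S, 1.0)
    return NetworkSimilarityMatrix(
        values=pd.DataFrame(S, index=valid, columns=valid),
        excluded_genes=list(c.dropped_genes),
    )


@dataclass
class NetworkSignature:
    """Genes whose network similarity to a query meets a threshold.

    Members are (gene, score) pairs sorted by score descending, ties
    broken by gene symbol; the query itself is a member (self-similarity
    is 1).
    """

    query: str
    threshold: float
    members: list[tuple[str, float]]

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.members, columns=["gene", "score"]).to_csv(
            path, sep="\t", index=False
        )


def extract_signature(
    s: NetworkSimilarityMatrix,
    query: str,
    threshold: float = DEFAULT_SIGNATURE_THRESHOLD,
) -> NetworkSignature:
    """All genes with similarity >= ``threshold`` to the query gene."""
    if query not in s.values.index:
        raise KeyError(f"query gene {query!r} not in similarity matrix")
    scores = s.values.loc[query]
    hits = scores[scores >= threshold].dropna()
    members = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    return NetworkSignature(
        query=query,
        threshold=threshold,
        members=[(str(g), float(v)) for g, v in members],
    )


@dataclass
class SignatureDistribution:
    """Similarities from one test gene to every member of a signature.

    This is the per-gene distribution drawn as a violin when comparing
    candidate genes against a reference network signature.
    """

    test_gene: str
    reference_query: str
    scores: np.ndarray

    @property
    def summary(self) -> dict[str, float]:
        return {
            "median": float(np.median(self.scores)),
            "q1": float(np.percentile(self.scores, 25)),
            "q3": float(np.percentile(self.scores, 75)),
            "min": float(np.min(self.scores)),
            "max": float(np.max(self.scores)),
        }


def signature_distribution(
    s: NetworkSimilarityMatrix, sig: NetworkSignature, test_gene: str
) -> SignatureDistribution:
    """Similarity of ``test_gene`` to each member of a reference signature.

    With ``test_gene == sig.query`` this returns the signature's own
    scores (all at or above the threshold by construction).
    """
    if test_gene not in s.values.index:
        raise KeyError(f"test gene {test_gene!r} not in similarity matrix")
    scores = s.values.loc[test_gene, sig.genes].to_numpy(float)
    return SignatureDistribution(
        test_gene=test_gene, reference_query=sig.query, scores=scores
    )


def signature_overlap(a: NetworkSignature, b: NetworkSignature) -> dict[str, float]:
    """Jaccard index and overlap coefficient of two signatures' gene sets."""
    sa, sb = set(a.genes), set(b.genes)
    inter = len(sa & sb)
    union = len(sa | sb)
    return {
        "jaccard": inter / union if union else 0.0,
        "overlap_coefficient": inter / min(len(sa), len(sb)) if sa and sb else 0.0,
        "n_intersection": float(inter),
        "n_a": float(len(sa)),
        "n_b": float(len(sb)),
    }


@dataclass
class EmbeddingCoordinates:
    """2-D embedding of gene networks; one (x, y) per gene."""

    coordinates: pd.DataFrame  # columns: x, y
    n_neighbors: int
    min_dist: float
    metric: str
    seed: int

    def to_tsv(self, path) -> None:
        out = self.coordinates.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def embed_networks(
    s: NetworkSimilarityMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
    metric: str = "euclidean",
) -> EmbeddingCoordinates:
    """UMAP embedding of the similarity matrix rows into 2-D.

    Each gene's feature vector is its full similarity profile, so genes
    with similar networks land close together on the plane.  The seed
    and all parameters are recorded in the result; a fixed seed makes
    the layout reproducible.
    """
    import umap  # deferred: slow import, only needed for embedding

    G = len(s.genes)
    if G < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} genes, got {G}"
        )
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        n_components=2,
        random_state=seed,
    )
    coords = reducer.fit_transform(s.values.to_numpy(float))
    return EmbeddingCoordinates(
        coordinates=pd.DataFrame(coords, index=s.genes, columns=["x", "y"]),
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        seed=seed,
    )
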