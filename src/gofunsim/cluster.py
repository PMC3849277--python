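"""Protein clustering by functional similarity: pairwise similarity
matrices, agglomerative clustering with Newick export, and spectral
k-means.  Distances are d = 1 - similarity."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .annotations import AnnotationCorpus
from .errors import MissingAnnotationError, ParameterError
from .ic import ICTable
from .ontology import OntologyGraph
from .protsim import MeasureConfig, protein_sim

log = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single")


@dataclass
class SimilarityMatrix:
    proteins: list[str]
    values: np.ndarray  # symmetric, unit diagonal, NaN for missing pairs
    measure: MeasureConfig | None

    def has_na(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage form over d = 1 - similarity."""

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str

    def to_newick(self) -> str:
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"


def similarity_matrix(
    proteins,
    measure: MeasureConfig,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    ic: ICTable | None,
    namespace: str,
) -> SimilarityMatrix:
    """All-pairs protein similarity; unannotated proteins are dropped with a
    logged warning.  Fewer than two annotated survivors is an error."""
    resolved = [corpus.resolve(p) for p in proteins]
    kept: list[str] = []
    for p in resolved:
        if corpus.direct(p, namespace):
            if p not in kept:
                kept.append(p)
        else:
            log.warning("dropping %s: no annotation in %s", p, namespace)
    if len(kept) < 2:
        raise ParameterError(
            f"need at least 2 annotated proteins, have {len(kept)}"
        )
    n = len(kept)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = protein_sim(
                    measure, corpus, graph, ic, kept[i], kept[j], namespace
                ).score
            except MissingAnnotationError:
                s = np.nan
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(kept, values, measure)


def drop_na(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Repeatedly drop the protein with the most NA pairs until complete."""
    values = matrix.values.copy()
    keep = list(range(len(matrix.proteins)))
    while True:
        sub = values[np.ix_(keep, keep)]
        na_counts = np.isnan(sub).sum(axis=1)
        if na_counts.sum() == 0:
            break
        worst = int(np.argmax(na_counts))
        keep.pop(worst)
        if len(keep) < 2:
            raise ParameterError("fewer than 2 proteins remain after NA removal")
    return SimilarityMatrix(
        [matrix.proteins[i] for i in keep], values[np.ix_(keep, keep)],
        matrix.measure,
    )


def hierarchical(matrix: SimilarityMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering on d = 1 - similarity."""
    if method not in LINKAGES:
        raise ParameterError(f"unknown linkage {method!r}; use one of {LINKAGES}")
    if matrix.has_na():
        raise ParameterError("similarity matrix contains NA entries")
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    z = linkage(condensed, method=method)
    return Dendrogram(z, list(matrix.proteins), method)


def spectral_kmeans(
    matrix: SimilarityMatrix, k: int, seed: int = 0
) -> dict[str, int]:
    """Normalized-Laplacian embedding of the similarity graph followed by
    k-means (k-means++ init, deterministic for a fixed seed)."""
    n = len(matrix.proteins)
    if not 2 <= k < n:
        raise ParameterError(f"cluster count k={k} outside [2, {n - 1}]")
    if matrix.has_na():
        raise ParameterError("similarity matrix contains NA entries")
    s = (matrix.values + matrix.values.T) / 2.0
    deg = s.sum(axis=1)
    if np.any(deg <= 0):
        raise ParameterError("similarity graph has an isolated protein")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * s * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(lap)
    embed = eigvecs[:, :k]
    norms = np.linalg.norm(embed, axis=1)
    norms[norms == 0] = 1.0
    embed = embed / norms[:, None]
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(embed)
    return {p: int(c) for p, c in zip(matrix.proteins, labels)}
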