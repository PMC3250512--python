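"""Probabilistic presence/absence similarity and agglomerative clustering.

The pairwise score is the classic hypergeometric null: given the total
species pool S and two sites holding a and b species, the probability of
sharing at least the observed number s by drawing the two species sets at
random is the tail

    p = sum_{i=s}^{min(a,b)} C(b, i) C(S-b, a-i) / C(S, a)

and similarity is 1 - p.  An occurrence-frequency-weighted null (species
drawn proportionally to how often they occur) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ClusterNode, linkage, to_tree
from scipy.spatial.distance import squareform

from .community import CommunityMatrix

__all__ = [
    "RaupCrickMatrix",
    "Dendrogram",
    "raup_crick_pair",
    "raup_crick",
    "agglomerate",
]


@dataclass
class RaupCrickMatrix:
    site_ids: list[str]
    values: np.ndarray  # similarity in [0, 1], symmetric, unit diagonal
    convention: str = "similarity"  # 1 - P(X >= s_obs)
    null_model: str = "equiprobable"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


def raup_crick_pair(a: int, b: int, s: int, pool: int) -> float:
    """Tail probability P(shared >= s) for richnesses a, b in a pool of S.

    Exchangeable in a and b.  Computed as an exact rational sum of
    binomial terms, then converted to float.
    """
    if not 0 <= a <= pool or not 0 <= b <= pool:
        raise ValueError("richness exceeds species pool")
    if s > min(a, b):
        raise ValueError("shared count exceeds the smaller richness")
    num = sum(comb(b, i) * comb(pool - b, a - i) for i in range(s, min(a, b) + 1))
    return num / comb(pool, a)


def _weighted_null_p(
    occ: np.ndarray, a: int, b: int, s: int, rng: np.random.Generator, draws: int
) -> float:
    # Monte-Carlo null with species sampled proportionally to occurrence frequency
    freq = occ.sum(axis=0)
    w = freq / freq.sum()
    n_species = occ.shape[1]
    hits = 0
    for _ in range(draws):
        sa = rng.choice(n_species, size=a, replace=False, p=w)
        sb = rng.choice(n_species, size=b, replace=False, p=w)
        if len(np.intersect1d(sa, sb, assume_unique=True)) >= s:
            hits += 1
    return hits / draws


def raup_crick(
    matrix: CommunityMatrix,
    null_model: str = "equiprobable",
    seed: int = 0,
    draws: int = 1000,
) -> RaupCrickMatrix:
    """All-pairs Raup-Crick similarity for a binary community matrix.

    The diagonal is set to 1 by convention.  ``null_model='weighted'``
    switches to an occurrence-frequency-weighted Monte-Carlo null.
    """
    if not matrix.binary:
        raise ValueError("Raup-Crick requires a presence/absence matrix")
    occ = matrix.occurrences.astype(int)
    n = matrix.n_sites
    pool = matrix.n_species
    richness = occ.sum(axis=1)
    shared = occ @ occ.T
    sim = np.ones((n, n))
    rng = np.random.default_rng(seed)
    for i in range(n):
        for j in range(i + 1, n):
            if null_model == "equiprobable":
                p = raup_crick_pair(
                    int(richness[i]), int(richness[j]), int(shared[i, j]), pool
                )
            elif null_model == "weighted":
                p = _weighted_null_p(
                    occ, int(richness[i]), int(richness[j]), int(shared[i, j]),
                    rng, draws,
                )
            else:
                raise ValueError(f"unknown null model {null_model!r}")
            sim[i, j] = sim[j, i] = 1.0 - p
    return RaupCrickMatrix(
        site_ids=list(matrix.site_ids), values=sim, null_model=null_model
    )


@dataclass
class Dendrogram:
    site_ids: list[str]
    merge: np.ndarray  # scipy linkage matrix on dissimilarity = 1 - similarity
    linkage_method: str

    def cut(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.merge, t=n_clusters, criterion="maxclust")
        return {s: int(c) for s, c in zip(self.site_ids, labels)}

    def heights(self) -> np.ndarray:
        return self.merge[:, 2]

    def to_newick(self) -> str:
        tree = to_tree(self.merge)
        return _newick(tree, self.site_ids) + ";"


def _newick(node: ClusterNode, labels: list[str]) -> str:
    # branch length = parent height - child height (ultrametric heights)
    def rec(n: ClusterNode, parent_height: float) -> str:
        length = parent_height - n.dist
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.10g}"
        inner = ",".join(rec(c, n.dist) for c in (n.left, n.right))
        return f"({inner}):{length:.10g}"

    if node.is_leaf():
        return labels[node.id]
    inner = ",".join(rec(c, node.dist) for c in (node.left, node.right))
    return f"({inner})"


def agglomerate(similarity: RaupCrickMatrix, method: str = "average") -> Dendrogram:
    """Hierarchical agglomerative clustering on 1 - similarity."""
    n = len(similarity.site_ids)
    if n < 2:
        raise ValueError("need at least 2 sites to cluster")
    d = similarity.dissimilarity().copy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
    merge = linkage(squareform(d, checks=False), method=method)
    return Dendrogram(
        site_ids=list(similarity.site_ids), merge=merge, linkage_method=method
    )
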