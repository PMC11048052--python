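"""Anchor-based alignment of pseudo-spots and real spots in a shared PCA space.

Both expression matrices are restricted to the selected marker genes,
standardized with pooled per-gene statistics, and projected onto the top
principal axes of the concatenated data. Mutual nearest cross-batch
neighbors under cosine similarity become anchors; each real spot is then
shifted by a locally kernel-weighted average of the anchor displacement
vectors. The pseudo batch — which carries the ground-truth proportions used
for training — is the fixed reference frame and is never moved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .io import ExpressionMatrix


@dataclass
class IntegrationResult:
    embedding: np.ndarray            # (n_pseudo + n_real) × d, pseudo rows first
    anchors: list[tuple[int, int, float]]  # (pseudo_row, real_row, score in [0,1])
    d: int
    batch: np.ndarray                # 0 = pseudo, 1 = real, per row

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError("integrated embedding contains non-finite values")

    @property
    def pseudo_embedding(self) -> np.ndarray:
        return self.embedding[self.batch == 0]

    @property
    def real_embedding(self) -> np.ndarray:
        return self.embedding[self.batch == 1]


def embed(
    pseudo: ExpressionMatrix,
    real: ExpressionMatrix,
    markers: Sequence[str],
    d: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint PCA embedding of both batches on shared marker genes.

    Returns (embedding, batch labels). Genes are standardized with pooled
    mean/std so neither batch dominates the axes; ``d`` is capped at the data
    rank bound min(n_rows, n_shared_markers).
    """
    shared = [g for g in markers if g in set(pseudo.gene_ids) and g in set(real.gene_ids)]
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} marker genes shared between batches; >= 10 required"
        )
    X = np.vstack([pseudo.subset_genes(shared).values, real.subset_genes(shared).values])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    d_eff = min(d, X.shape[0], X.shape[1])
    pca = PCA(n_components=d_eff, svd_solver="full")
    emb = pca.fit_transform(X)
    batch = np.concatenate([np.zeros(pseudo.n_rows, int), np.ones(real.n_rows, int)])
    return emb, batch


def _cosine_normalize(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def find_anchors(
    embedding: np.ndarray, batch: np.ndarray, n_neighbors: int = 15
) -> list[tuple[int, int, float]]:
    """Mutual nearest cross-batch neighbor pairs under cosine similarity.

    (i, j) is an anchor iff j is among pseudo-row i's ``n_neighbors`` most
    similar real rows and vice versa. The anchor score is the overlap fraction
    of the two endpoints' neighbor sets in the full embedding — 1 when the
    endpoints see the same neighborhood, near 0 for a spurious pairing.
    """
    p_idx = np.flatnonzero(batch == 0)
    r_idx = np.flatnonzero(batch == 1)
    if p_idx.size == 0 or r_idx.size == 0:
        raise ValueError("both batches must be nonempty")
    Xn = _cosine_normalize(embedding)
    sim = Xn[p_idx] @ Xn[r_idx].T  # n_pseudo × n_real
    kp = min(n_neighbors, r_idx.size)
    kr = min(n_neighbors, p_idx.size)
    # top-k real neighbors of each pseudo row, and vice versa
    nn_of_p = np.argpartition(-sim, kth=kp - 1, axis=1)[:, :kp]
    nn_of_r = np.argpartition(-sim.T, kth=kr - 1, axis=1)[:, :kr]
    r_nbr_sets = [set(row) for row in nn_of_r]

    # neighborhoods in the full embedding for scoring
    k_all = min(n_neighbors, embedding.shape[0] - 1)
    full_sim = Xn @ Xn.T
    np.fill_diagonal(full_sim, -np.inf)
    full_nn = np.argpartition(-full_sim, kth=k_all - 1, axis=1)[:, :k_all]
    full_sets = [set(row) for row in full_nn]

    anchors: list[tuple[int, int, float]] = []
    for pi, row in enumerate(nn_of_p):
        for rj in row:
            if pi in r_nbr_sets[rj]:
                gi, gj = int(p_idx[pi]), int(r_idx[rj])
                score = len(full_sets[gi] & full_sets[gj]) / k_all
                anchors.append((gi, gj, float(score)))
    if not anchors:
        warnings.warn("no mutual nearest neighbor anchors found between batches", stacklevel=2)
    return anchors


def integrate(
    embedding: np.ndarray,
    batch: np.ndarray,
    anchors: list[tuple[int, int, float]],
) -> IntegrationResult:
    """Shift real rows by kernel-weighted anchor displacements; pseudo rows fixed.

    Anchors are first reduced to the highest-scoring pair per real endpoint:
    mutual-neighbor lists contain many merely-similar pairs whose displacement
    is systematically biased along the batch shift, and the best match per
    spot is the least biased estimate of the local correction. Each real row x
    then receives sum_a w_a (pseudo_a − real_a) / sum_a w_a with weights
    w_a = score_a · exp(−dist(x, real_a)² / (2σ_x²)); the bandwidth σ_x is the
    median distance from x to the anchors' real endpoints, so the correction
    is local where anchors are dense and global where they are not. With no
    anchors the embedding is passed through unchanged with a warning.
    """
    embedding = np.asarray(embedding, dtype=float)
    out = embedding.copy()
    d = embedding.shape[1]
    if not anchors:
        warnings.warn("integrate called with no anchors; returning input unchanged", stacklevel=2)
        return IntegrationResult(out, [], d, np.asarray(batch))
    best: dict[int, tuple[int, int, float]] = {}
    for a in anchors:
        if a[1] not in best or a[2] > best[a[1]][2]:
            best[a[1]] = a
    kept = sorted(best.values(), key=lambda a: a[1])
    a_p = np.array([a[0] for a in kept])
    a_r = np.array([a[1] for a in kept])
    scores = np.array([a[2] for a in kept])
    disp = embedding[a_p] - embedding[a_r]          # pseudo − real
    real_rows = np.flatnonzero(batch == 1)
    X = embedding[real_rows]
    D = np.linalg.norm(X[:, None, :] - embedding[a_r][None, :, :], axis=2)  # n_real × n_anchors
    sigma = np.median(D, axis=1)
    sigma = np.maximum(sigma, 1e-8)
    W = np.exp(-(D ** 2) / (2 * sigma[:, None] ** 2)) * scores[None, :]
    W_sum = W.sum(axis=1, keepdims=True)
    W_sum[W_sum == 0] = 1.0
    out[real_rows] = X + (W @ disp) / W_sum
    return IntegrationResult(out, list(anchors), d, np.asarray(batch))


def integrate_datasets(
    pseudo: ExpressionMatrix,
    real: ExpressionMatrix,
    markers: Sequence[str],
    d: int = 30,
    n_neighbors: int = 15,
) -> IntegrationResult:
    """Convenience wrapper: embed → find_anchors → integrate."""
    emb, batch = embed(pseudo, real, markers, d=d)
    anchors = find_anchors(emb, batch, n_neighbors=n_neighbors)
    return integrate(emb, batch, anchors)
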