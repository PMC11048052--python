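"""Marker-gene selection: rate thresholding, dispersion ranking, silhouette re-ranking.

The selection proceeds in stages. From the cells × genes matrix we summarize
each cell type by its per-gene detection rate (matrix ``O``) and mean
expression (matrix ``P``). A Tukey-fence threshold on each type's rate vector
keeps highly detected genes; a top-l cut on the mean keeps strongly expressed
ones; a dispersion score ranks genes by type specificity; finally, for each
type the candidate genes are re-ranked by the silhouette coefficient of the
cell-type clustering along that single gene's expression axis, and the top t
per type form the marker set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import CellTypeLabels, ExpressionMatrix

Stage = Literal["full", "threshold_filtered", "top_mean_filtered"]

_EPS = 1e-6


@dataclass
class TypeSummaryMatrices:
    """Per-type detection-rate (O) and mean-expression (P) matrices, k × m."""

    O: np.ndarray
    P: np.ndarray
    types: list[str]
    gene_ids: list[str]
    stage: Stage = "full"

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        k, m = self.O.shape
        if self.P.shape != (k, m):
            raise ValueError("O and P shapes differ")
        if len(self.types) != k or len(self.gene_ids) != m:
            raise ValueError("type/gene id lengths do not match matrix shape")
        if m and (self.O.min() < 0 or self.O.max() > 1):
            raise ValueError("expression rates must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, cols: Sequence[int], stage: Stage) -> "TypeSummaryMatrices":
        cols = list(cols)
        return TypeSummaryMatrices(
            self.O[:, cols], self.P[:, cols], list(self.types),
            [self.gene_ids[j] for j in cols], stage,
        )


@dataclass
class ThresholdParams:
    Q3: float
    IQR: float
    threshold: float


@dataclass
class MarkerGeneSet:
    """Per-type silhouette-ranked marker genes plus their deduplicated union."""

    per_type: dict[str, list[tuple[str, float]]]
    t: int
    union: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.union:
            seen: list[str] = []
            for genes in self.per_type.values():
                for g, _ in genes:
                    if g not in seen:
                        seen.append(g)
            self.union = seen

    def to_records(self) -> list[tuple[str, str, float]]:
        return [(ct, g, s) for ct, genes in self.per_type.items() for g, s in genes]


def summarize_by_type(Q: ExpressionMatrix, labels: CellTypeLabels) -> TypeSummaryMatrices:
    """Compute O (detection rate) and P (mean expression) per cell type."""
    codes = labels.vector(Q.row_ids)
    k = labels.k
    O = np.zeros((k, Q.n_genes))
    P = np.zeros((k, Q.n_genes))
    for t in range(k):
        mask = codes == t
        if mask.sum() < 2:
            raise ValueError(
                f"cell type {labels.types[t]!r} has fewer than 2 cells"
            )
        O[t] = (Q.values[mask] > 0).mean(axis=0)
        P[t] = Q.values[mask].mean(axis=0)
    return TypeSummaryMatrices(O, P, list(labels.types), list(Q.gene_ids), "full")


def quartile_threshold(
    rates: np.ndarray, precedence: Literal["tukey", "half"] = "tukey"
) -> ThresholdParams:
    """Upper-fence threshold over one type's detection rates.

    ``tukey`` (default) reads the fence as Q3 + 1.5·IQR; ``half`` is the
    alternative grouping 0.5·(2·Q3 + 1.5·IQR). Quartiles use linear
    interpolation.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate vector")
    q1, q3 = np.percentile(rates, [25, 75])
    iqr = q3 - q1
    if precedence == "tukey":
        thr = q3 + 1.5 * iqr
    elif precedence == "half":
        thr = 0.5 * (2 * q3 + 1.5 * iqr)
    else:
        raise ValueError(f"unknown precedence {precedence!r}")
    return ThresholdParams(Q3=float(q3), IQR=float(iqr), threshold=float(thr))


def threshold_filter(
    S: TypeSummaryMatrices,
    min_genes: int = 200,
    precedence: Literal["tukey", "half"] = "tukey",
) -> TypeSummaryMatrices:
    """Keep the union over types of genes whose rate exceeds that type's fence.

    On rate data bounded by 1 the fence can exclude everything; if fewer than
    ``min_genes`` genes pass, fall back to the top ``min_genes`` genes by
    maximum rate across types (ties broken by gene id).
    """
    if S.stage != "full":
        raise ValueError("threshold_filter expects a stage-'full' summary")
    keep = np.zeros(S.n_genes, dtype=bool)
    for t in range(len(S.types)):
        thr = quartile_threshold(S.O[t], precedence).threshold
        keep |= S.O[t] > thr
    if keep.sum() < min(min_genes, S.n_genes):
        max_rate = S.O.max(axis=0)
        order = sorted(range(S.n_genes), key=lambda j: (-max_rate[j], S.gene_ids[j]))
        cols = sorted(order[: min(min_genes, S.n_genes)])
    else:
        cols = list(np.flatnonzero(keep))
    return S.subset(cols, "threshold_filtered")


def top_mean_filter(S: TypeSummaryMatrices, l: int) -> TypeSummaryMatrices:
    """Keep the l genes with the largest max-over-types mean expression."""
    if S.stage != "threshold_filtered":
        raise ValueError("top_mean_filter expects a threshold_filtered summary")
    if l > S.n_genes:
        raise ValueError(f"l={l} exceeds available genes s={S.n_genes}")
    max_mean = S.P.max(axis=0)
    order = sorted(range(S.n_genes), key=lambda j: (-max_mean[j], S.gene_ids[j]))
    cols = sorted(order[:l])
    return S.subset(cols, "top_mean_filtered")


def dispersion_score(
    a: float, b: float, c: float, d: float, e: float = 1.0,
    formula: Literal["ratio", "product"] = "ratio",
) -> float:
    """Type-specificity score of one gene for one target type.

    ``a``: mean expression in the target type; ``b``: max mean in the other
    types; ``c``: detection rate in the target type; ``d``: mean detection
    rate in the other types; ``e`` weights the rate term. The default form is
    (a − b) · (c / (d + ε))^e — positive mean contrast amplified when the gene
    is detected often in the target type and rarely elsewhere. ``product`` is
    the alternative reading (a − b) · c · e / (d + ε).
    """
    if e <= 0:
        raise ValueError("e must be positive")
    if formula == "ratio":
        return float((a - b) * (c / (d + _EPS)) ** e)
    if formula == "product":
        return float((a - b) * c * e / (d + _EPS))
    raise ValueError(f"unknown formula {formula!r}")


def _dispersion_matrix(S: TypeSummaryMatrices, e: float, formula: str) -> np.ndarray:
    """k × m matrix of dispersion scores, vectorized over genes."""
    k, m = S.O.shape
    disp = np.empty((k, m))
    for t in range(k):
        others = [u for u in range(k) if u != t]
        a = S.P[t]
        b = S.P[others].max(axis=0)
        c = S.O[t]
        d = S.O[others].mean(axis=0)
        if formula == "ratio":
            disp[t] = (a - b) * (c / (d + _EPS)) ** e
        else:
            disp[t] = (a - b) * c * e / (d + _EPS)
    return disp


def candidate_markers(
    S: TypeSummaryMatrices,
    per_type_candidates: int,
    e: float = 1.0,
    formula: Literal["ratio", "product"] = "ratio",
) -> dict[str, list[str]]:
    """Top genes per type by descending dispersion score (ties by gene id).

    Only genes with strictly positive dispersion qualify: a candidate marker
    must be over-expressed in its type relative to the best other type, so a
    gene expressed only in type A can never enter another type's candidate
    list (where its mean contrast a − b is negative). A type may therefore
    receive fewer than ``per_type_candidates`` genes.
    """
    if per_type_candidates < 1:
        raise ValueError("per_type_candidates must be >= 1")
    if S.stage != "top_mean_filtered":
        raise ValueError("candidate_markers expects a top_mean_filtered summary")
    disp = _dispersion_matrix(S, e, formula)
    out: dict[str, list[str]] = {}
    for t, name in enumerate(S.types):
        positive = [j for j in range(S.n_genes) if disp[t, j] > 0]
        order = sorted(positive, key=lambda j: (-disp[t, j], S.gene_ids[j]))
        out[name] = [S.gene_ids[j] for j in order[:per_type_candidates]]
    return out


def gene_silhouette(
    expr: np.ndarray,
    labels: CellTypeLabels,
    cell_ids: Sequence[str],
    target_type: str,
    max_cells_per_type: int = 500,
    seed: int = 0,
) -> float:
    """Mean silhouette of the target type's cells along one gene's 1-D axis.

    Cells are points on the expression axis of a single gene; clusters are the
    cell types. Distances are |x − y|. Each type is subsampled to at most
    ``max_cells_per_type`` cells with a fixed seed so the O(n²) computation
    stays tractable. Silhouette of a cell i is (b−a)/max(a,b) with a the mean
    intra-type distance and b the smallest mean distance to another type;
    cells in singleton clusters and cells with a=b=0 score 0.
    """
    if target_type not in labels.types:
        raise ValueError(f"unknown target type {target_type!r}")
    expr = np.asarray(expr, dtype=float).ravel()
    codes = labels.vector(cell_ids)
    rng = np.random.default_rng(seed)
    sub_idx: list[np.ndarray] = []
    for t in range(labels.k):
        idx = np.flatnonzero(codes == t)
        if idx.size > max_cells_per_type:
            idx = np.sort(rng.choice(idx, size=max_cells_per_type, replace=False))
        sub_idx.append(idx)
    x = [expr[idx] for idx in sub_idx]
    ti = labels.types.index(target_type)
    xt = x[ti]
    if xt.size == 0:
        raise ValueError(f"target type {target_type!r} has no cells")
    nt = xt.size
    # mean distance from each target cell to every cluster, vectorized
    scores = np.zeros(nt)
    # a(i): intra-cluster mean over the other n-1 members
    if nt > 1:
        d_intra = np.abs(xt[:, None] - xt[None, :]).sum(axis=1) / (nt - 1)
    else:
        d_intra = None  # singleton: convention s = 0
    d_other = np.full((labels.k, nt), np.inf)
    for t in range(labels.k):
        if t == ti or x[t].size == 0:
            continue
        d_other[t] = np.abs(xt[:, None] - x[t][None, :]).mean(axis=1)
    b = d_other.min(axis=0)
    if d_intra is None or not np.isfinite(b).any():
        return 0.0
    denom = np.maximum(d_intra, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - d_intra) / denom, 0.0)
    scores = np.where(np.isfinite(s), s, 0.0)
    return float(scores.mean())


def select_markers(
    candidates: dict[str, list[str]],
    Q: ExpressionMatrix,
    labels: CellTypeLabels,
    t: int = 20,
    max_cells_per_type: int = 500,
    seed: int = 0,
) -> MarkerGeneSet:
    """Re-rank each type's candidates by silhouette; keep the top t per type."""
    if t < 1:
        raise ValueError("t must be >= 1")
    gene_index = {g: j for j, g in enumerate(Q.gene_ids)}
    per_type: dict[str, list[tuple[str, float]]] = {}
    for ct, genes in candidates.items():
        scored = []
        for g in genes:
            s = gene_silhouette(
                Q.values[:, gene_index[g]], labels, Q.row_ids, ct,
                max_cells_per_type=max_cells_per_type, seed=seed,
            )
            scored.append((g, s))
        scored.sort(key=lambda gs: (-gs[1], gs[0]))
        per_type[ct] = scored[:t]
    return MarkerGeneSet(per_type=per_type, t=t)


def select_feature_genes(
    Q: ExpressionMatrix,
    labels: CellTypeLabels,
    t: int = 20,
    l: int | None = None,
    e: float = 1.0,
    per_type_candidates: int | None = None,
    min_genes: int = 200,
    max_cells_per_type: int = 500,
    seed: int = 0,
) -> MarkerGeneSet:
    """Full selection pipeline on a (normalized) reference matrix.

    ``l`` defaults to min(s, 1000) after the rate-threshold stage;
    ``per_type_candidates`` defaults to 3·t.
    """
    S = summarize_by_type(Q, labels)
    S1 = threshold_filter(S, min_genes=min_genes)
    l_eff = min(S1.n_genes, 1000) if l is None else l
    S2 = top_mean_filter(S1, l_eff)
    cand = candidate_markers(S2, per_type_candidates or 3 * t, e=e)
    sub = Q.subset_genes(S2.gene_ids)
    return select_markers(cand, sub, labels, t=t, max_cells_per_type=max_cells_per_type, seed=seed)
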