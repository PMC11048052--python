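"""Pseudo-spot synthesis: sum the expression of 2–8 randomly drawn cells.

Each synthetic spot mimics a spatial capture location that aggregates the
transcripts of the handful of cells it covers. Because the member cells are
known, every spot carries an exact ground-truth cell-type proportion vector —
the supervision signal for the deconvolution model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .io import CellTypeLabels, ExpressionMatrix, ProportionMatrix


@dataclass
class PseudoSpotSet:
    """Synthesized spots, their ground-truth proportions, and member cells."""

    expression: ExpressionMatrix
    truth: ProportionMatrix
    members: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        if len(self.members) != self.expression.n_rows:
            raise ValueError("members list does not match number of spots")

    def export(self, directory: str | Path, prefix: str = "pseudo") -> None:
        from . import io as _io

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        _io.write_expression(self.expression, directory / f"{prefix}_expression.csv")
        _io.write_proportions(self.truth, directory / f"{prefix}_truth.csv")
        (directory / f"{prefix}_members.json").write_text(
            json.dumps({"seed": self.seed, "members": dict(zip(self.expression.row_ids, self.members))})
        )


def make_spot(
    cell_rows: np.ndarray, cell_types: Sequence[str], types: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Sum 2–8 cell expression rows; proportions are member-type fractions."""
    cell_rows = np.atleast_2d(np.asarray(cell_rows, dtype=float))
    n = cell_rows.shape[0]
    if not 2 <= n <= 8:
        raise ValueError(f"a spot must mix 2-8 cells, got {n}")
    if len(cell_types) != n:
        raise ValueError("one type per cell row required")
    expr = cell_rows.sum(axis=0)
    prop = np.array([sum(ct == t for ct in cell_types) / n for t in types])
    return expr, prop


def generate(
    Q: ExpressionMatrix,
    labels: CellTypeLabels,
    n_spots: int,
    min_cells: int = 2,
    max_cells: int = 8,
    seed: int = 0,
    cell_indices: Sequence[int] | None = None,
    balanced_types: bool = False,
    spot_prefix: str = "pseudo",
) -> PseudoSpotSet:
    """Draw ``n_spots`` mixtures of ``min_cells``–``max_cells`` cells.

    Member counts are uniform on [min_cells, max_cells]; cells are drawn
    uniformly with replacement from ``cell_indices`` (default: all cells).
    With ``balanced_types`` a type is drawn uniformly first, then a cell of
    that type, equalizing type exposure. Fully reproducible given ``seed``.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if not (1 <= min_cells <= max_cells):
        raise ValueError("need 1 <= min_cells <= max_cells")
    rng = np.random.default_rng(seed)
    pool = np.arange(Q.n_rows) if cell_indices is None else np.asarray(list(cell_indices), dtype=int)
    if pool.size == 0:
        raise ValueError("empty cell pool")
    codes = labels.vector(Q.row_ids)
    by_type = [pool[codes[pool] == t] for t in range(labels.k)]

    expr = np.zeros((n_spots, Q.n_genes))
    prop = np.zeros((n_spots, labels.k))
    members: list[list[str]] = []
    counts = rng.integers(min_cells, max_cells + 1, size=n_spots)
    for i in range(n_spots):
        if balanced_types:
            chosen = []
            for _ in range(counts[i]):
                t = rng.integers(labels.k)
                while by_type[t].size == 0:
                    t = rng.integers(labels.k)
                chosen.append(rng.choice(by_type[t]))
            chosen = np.array(chosen)
        else:
            chosen = rng.choice(pool, size=counts[i], replace=True)
        expr[i] = Q.values[chosen].sum(axis=0)
        tc = np.bincount(codes[chosen], minlength=labels.k)
        prop[i] = tc / counts[i]
        members.append([Q.row_ids[j] for j in chosen])

    spot_ids = [f"{spot_prefix}_{i:05d}" for i in range(n_spots)]
    return PseudoSpotSet(
        expression=ExpressionMatrix(expr, spot_ids, list(Q.gene_ids)),
        truth=ProportionMatrix(prop, spot_ids, list(labels.types)),
        members=members,
        seed=seed,
    )


def split_cells(n_cells: int, holdout_fraction: float = 0.5, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Partition cell indices into (training, held-out) disjoint pools.

    Benchmark spots drawn from the held-out pool share no cells with training
    pseudo-spots, preventing leakage from exact cell reuse.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    n_hold = int(round(n_cells * holdout_fraction))
    return np.sort(perm[n_hold:]), np.sort(perm[:n_hold])
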