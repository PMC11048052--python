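"""Scoring predicted proportions: Jensen–Shannon distance and rank-sum tests.

The Jensen–Shannon distance between two probability vectors is the square
root of the Jensen–Shannon divergence with base-2 logarithms, which bounds it
exactly in [0, 1]: 0 for identical distributions, 1 for disjoint supports.
Method variants are compared on their per-spot JSD samples with the
two-sided Wilcoxon rank-sum (Mann–Whitney U) test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import ProportionMatrix

_SIMPLEX_TOL = 1e-6


def _check_simplex(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0 or p.min() < -_SIMPLEX_TOL or abs(p.sum() - 1.0) > 1e-4:
        raise ValueError(f"{name} is not a valid probability vector (sum={p.sum()!r})")
    return np.clip(p, 0.0, None)


def jsd(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen–Shannon distance (base-2) between two probability vectors."""
    p = _check_simplex(p, "p")
    q = _check_simplex(q, "q")
    if p.size != q.size:
        raise ValueError(f"length mismatch: {p.size} vs {q.size}")
    m = 0.5 * (p + q)
    # KL(x ‖ m) with the 0·log0 ≡ 0 convention; m=0 implies x=0 there
    def kl(x: np.ndarray) -> float:
        nz = x > 0
        return float(np.sum(x[nz] * np.log2(x[nz] / m[nz])))

    div = 0.5 * kl(p) + 0.5 * kl(q)
    return float(np.sqrt(max(div, 0.0)))


@dataclass
class EvaluationReport:
    per_spot: pd.Series          # index: spot_id, values: JSD
    mean_jsd: float
    median_jsd: float
    comparisons: dict[str, tuple[float, float]]  # name -> (statistic, p)

    def to_tidy(self, method: str = "gtadc") -> pd.DataFrame:
        return pd.DataFrame(
            {"method": method, "spot": self.per_spot.index, "jsd": self.per_spot.values}
        )

    def export(self, path: str | Path, method: str = "gtadc") -> None:
        path = Path(path)
        self.to_tidy(method).to_csv(path.with_suffix(".csv"), index=False)
        path.with_suffix(".json").write_text(json.dumps({
            "method": method,
            "mean_jsd": self.mean_jsd,
            "median_jsd": self.median_jsd,
            "n_spots": int(self.per_spot.size),
            "comparisons": {k: list(v) for k, v in self.comparisons.items()},
        }, indent=2))


def evaluate(pred: ProportionMatrix, truth: ProportionMatrix) -> EvaluationReport:
    """Per-spot JSD of prediction vs truth, aligned by spot id and type name."""
    missing = sorted(set(truth.spot_ids) ^ set(pred.spot_ids))
    if missing:
        raise ValueError(f"unmatched spot ids between pred and truth: {missing[:10]}")
    if set(pred.types) != set(truth.types):
        raise ValueError("pred and truth disagree on the cell-type set")
    pred_df = pred.to_dataframe().loc[truth.spot_ids, truth.types]
    vals = np.array([
        jsd(pred_df.iloc[i].to_numpy(), truth.values[i]) for i in range(len(truth.spot_ids))
    ])
    per_spot = pd.Series(vals, index=truth.spot_ids, name="jsd")
    return EvaluationReport(
        per_spot=per_spot,
        mean_jsd=float(vals.mean()),
        median_jsd=float(np.median(vals)),
        comparisons={},
    )


def ranksum_compare(jsd_a: Sequence[float], jsd_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two JSD samples.

    Exact enumeration when both samples have n ≤ 10 and no cross-sample ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(list(jsd_a), dtype=float)
    b = np.asarray(list(jsd_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def uniform_baseline(truth: ProportionMatrix) -> EvaluationReport:
    """JSD of the uninformative uniform prediction (1/k per type) per spot."""
    k = len(truth.types)
    u = np.full(k, 1.0 / k)
    vals = np.array([jsd(u, row) for row in truth.values])
    per_spot = pd.Series(vals, index=truth.spot_ids, name="jsd")
    return EvaluationReport(per_spot, float(vals.mean()), float(np.median(vals)), {})
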