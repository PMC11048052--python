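"""End-to-end orchestration: markers → pseudo-spots → integrate → graph → GAT.

``deconvolve`` is the in-memory pipeline; ``run_pipeline`` wraps it with file
IO and a run manifest; ``demo`` runs the whole method on the bundled synthetic
scenario with a benchmark whose ground truth is known, and reports JSD.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluation, feature_selection, gat, graph, integration, io, pseudospots, simulate
from .config import RunConfig

logger = logging.getLogger("gtadc")


def _subseeds(seed: int, n: int) -> list[int]:
    # independent child seeds below 2**31, reproducibly derived from the master
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    markers: feature_selection.MarkerGeneSet
    pseudo: pseudospots.PseudoSpotSet
    integration: integration.IntegrationResult
    adjacency: graph.WeightedAdjacency
    train: gat.TrainResult
    proportions: io.ProportionMatrix       # real spots × types
    report: evaluation.EvaluationReport | None = None
    baseline: evaluation.EvaluationReport | None = None
    timings: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)


def _corrected_expression_features(
    pseudo_norm: io.ExpressionMatrix,
    real_norm: io.ExpressionMatrix,
    markers: Sequence[str],
    result: integration.IntegrationResult,
) -> np.ndarray:
    """Marker-expression node features with the anchor correction applied in gene space."""
    shared = [g for g in markers if g in set(pseudo_norm.gene_ids) and g in set(real_norm.gene_ids)]
    Xp = pseudo_norm.subset_genes(shared).values
    Xr = real_norm.subset_genes(shared).values
    X = np.vstack([Xp, Xr])
    if result.anchors:
        emb = result.embedding
        best: dict[int, tuple[int, int, float]] = {}
        for a in result.anchors:
            if a[1] not in best or a[2] > best[a[1]][2]:
                best[a[1]] = a
        kept = sorted(best.values(), key=lambda a: a[1])
        a_p = np.array([a[0] for a in kept])
        a_r = np.array([a[1] for a in kept])
        scores = np.array([a[2] for a in kept])
        disp = X[a_p] - X[a_r]
        real_rows = np.flatnonzero(result.batch == 1)
        D = np.linalg.norm(emb[real_rows][:, None, :] - emb[a_r][None, :, :], axis=2)
        sigma = np.maximum(np.median(D, axis=1), 1e-8)
        W = np.exp(-(D ** 2) / (2 * sigma[:, None] ** 2)) * scores[None, :]
        X[real_rows] += (W @ disp) / np.maximum(W.sum(axis=1, keepdims=True), 1e-12)
    return X


def deconvolve(
    sc: io.ExpressionMatrix,
    labels: io.CellTypeLabels,
    st: io.ExpressionMatrix,
    config: RunConfig | None = None,
    cell_indices: Sequence[int] | None = None,
    st_truth: io.ProportionMatrix | None = None,
) -> PipelineResult:
    """Infer per-spot cell-type proportions for ``st`` from the ``sc`` reference.

    ``cell_indices`` optionally restricts the cell pool used to synthesize
    training pseudo-spots (e.g. the non-held-out half in benchmarks). When
    ``st_truth`` is given the result carries a JSD report and the uniform
    baseline.
    """
    cfg = config or RunConfig()
    seeds = _subseeds(cfg.seed, 4)
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}

    t0 = time.time()
    sc_qc = io.qc_filter_genes(sc, labels, min_rate=cfg.min_rate)
    sc_norm = io.normalize(sc_qc, target_sum=cfg.target_sum, log1p=cfg.log1p)
    logger.info("QC kept %d/%d genes", sc_qc.n_genes, sc.n_genes)

    markers = feature_selection.select_feature_genes(
        sc_norm, labels, t=cfg.t, l=cfg.l, e=cfg.e,
        per_type_candidates=cfg.per_type_candidates, min_genes=cfg.min_genes,
        max_cells_per_type=cfg.max_cells_per_type, seed=seeds[0],
    )
    timings["markers"] = time.time() - t0
    logger.info("selected %d marker genes (%d per type)", len(markers.union), cfg.t)

    t0 = time.time()
    n_pseudo = cfg.n_pseudo_spots or 5 * st.n_rows
    pseudo = pseudospots.generate(
        sc_qc, labels, n_pseudo, min_cells=cfg.min_cells, max_cells=cfg.max_cells,
        seed=seeds[1], cell_indices=cell_indices,
    )
    pseudo_norm = io.normalize(pseudo.expression, cfg.target_sum, cfg.log1p)
    st_norm = io.normalize(st, cfg.target_sum, cfg.log1p)
    timings["pseudo"] = time.time() - t0
    checksums["pseudo_expression"] = _checksum(pseudo.expression.values)

    t0 = time.time()
    emb, batch = integration.embed(pseudo_norm, st_norm, markers.union, d=cfg.d)
    if cfg.use_integration:
        anchors = integration.find_anchors(emb, batch, n_neighbors=cfg.n_neighbors)
        integ = integration.integrate(emb, batch, anchors)
    else:
        integ = integration.IntegrationResult(emb, [], emb.shape[1], batch)
    if cfg.feature_space == "expression":
        features = _corrected_expression_features(pseudo_norm, st_norm, markers.union, integ)
    else:
        features = integ.embedding
    timings["integration"] = time.time() - t0
    checksums["features"] = _checksum(features)
    logger.info("integration: %d anchors, feature dim %d", len(integ.anchors), features.shape[1])

    t0 = time.time()
    adjacency = graph.forest_adjacency(
        features, T=cfg.n_trees, leaf_size=cfg.leaf_size, seed=seeds[2]
    )
    timings["graph"] = time.time() - t0

    t0 = time.time()
    node_ids = list(pseudo.expression.row_ids) + list(st.row_ids)
    gat_cfg = gat.GATConfig(**{**cfg.gat.__dict__, "seed": seeds[3]})
    trained = gat.train(features, adjacency, pseudo.truth, node_ids, labels.types, gat_cfg)
    timings["train"] = time.time() - t0
    logger.info("training: final loss %.4f", trained.history[-1])

    result = PipelineResult(
        markers=markers, pseudo=pseudo, integration=integ, adjacency=adjacency,
        train=trained, proportions=trained.real_proportions,
        timings=timings, checksums=checksums,
    )
    if st_truth is not None:
        result.report = evaluation.evaluate(trained.real_proportions, st_truth)
        result.baseline = evaluation.uniform_baseline(st_truth)
    return result


def run_pipeline(
    config_path: str | Path | None,
    sc_path: str | Path,
    sc_meta_path: str | Path,
    st_path: str | Path,
    out_dir: str | Path,
    st_truth_path: str | Path | None = None,
    sc_format: str = "csv",
    st_format: str = "csv",
) -> PipelineResult:
    """File-based pipeline: read inputs, deconvolve, write outputs + manifest."""
    for p, name in ((sc_path, "scRNA-seq matrix"), (sc_meta_path, "cell metadata"), (st_path, "ST matrix")):
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} not found: {p}")
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    sc = io.read_expression(sc_path, format=sc_format)
    labels = io.read_cell_metadata(sc_meta_path)
    st = io.read_expression(st_path, format=st_format)
    truth = io.read_proportions(st_truth_path) if st_truth_path else None

    result = deconvolve(sc, labels, st, cfg, st_truth=truth)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_proportions(result.proportions, out / "proportions.csv")
    import pandas as pd
    pd.DataFrame(result.markers.to_records(), columns=["cell_type", "gene_id", "silhouette"]).to_csv(
        out / "markers.csv", index=False
    )
    result.adjacency.export(out / "adjacency.mtx")
    pd.DataFrame({"epoch": range(len(result.train.history)), "loss": result.train.history}).to_csv(
        out / "training_log.csv", index=False
    )
    if result.report is not None:
        result.report.export(out / "evaluation")
    manifest = {
        "config": cfg.to_dict(),
        "inputs": {"sc": str(sc_path), "sc_meta": str(sc_meta_path), "st": str(st_path)},
        "timings": result.timings,
        "checksums": result.checksums,
        "n_markers": len(result.markers.union),
        "n_anchors": len(result.integration.anchors),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


@dataclass
class DemoResult:
    mean_jsd: float
    median_jsd: float
    baseline_mean_jsd: float
    marker_recovery: float
    n_markers: int
    pipeline: PipelineResult
    truth: io.ProportionMatrix


def marker_recovery_rate(
    markers: feature_selection.MarkerGeneSet, marker_map: dict[str, list[str]]
) -> float:
    """Fraction of planted marker genes present in the selected union."""
    planted = {g for genes in marker_map.values() for g in genes}
    return len(planted & set(markers.union)) / len(planted)


def demo(
    seed: int = 0,
    config: RunConfig | None = None,
    sim: simulate.SimulationConfig | None = None,
    n_benchmark_spots: int = 100,
    n_pseudo_spots: int = 400,
) -> DemoResult:
    """Simulate the default 4-type scenario and run the full method against truth."""
    sim = sim or simulate.SimulationConfig(seed=seed)
    cfg = config or RunConfig()
    cfg.seed = seed
    cfg.n_pseudo_spots = n_pseudo_spots
    ref, labels, marker_map = simulate.simulate_reference(sim)
    seeds = _subseeds(seed + 101, 2)
    train_pool, holdout = pseudospots.split_cells(ref.n_rows, 0.5, seed=seeds[0])
    st, truth = simulate.simulate_benchmark_st(
        ref, labels, n_benchmark_spots, batch_shift=sim.batch_shift,
        seed=seeds[1], cell_indices=holdout,
    )
    result = deconvolve(ref, labels, st, cfg, cell_indices=train_pool, st_truth=truth)
    return DemoResult(
        mean_jsd=result.report.mean_jsd,
        median_jsd=result.report.median_jsd,
        baseline_mean_jsd=result.baseline.mean_jsd,
        marker_recovery=marker_recovery_rate(result.markers, marker_map),
        n_markers=len(result.markers.union),
        pipeline=result,
        truth=truth,
    )
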