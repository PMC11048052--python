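import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gtadc.feature_selection import (
    MarkerGeneSet,
    candidate_markers,
    dispersion_score,
    gene_silhouette,
    quartile_threshold,
    select_feature_genes,
    select_markers,
    summarize_by_type,
    threshold_filter,
    top_mean_filter,
)
from gtadc.io import CellTypeLabels, ExpressionMatrix


def brute_force_silhouette(x, codes, target_code):
    """O(n²) reference: mean silhouette of target-cluster points on a 1-D axis."""
    x = np.asarray(x, float)
    scores = []
    for i in np.flatnonzero(codes == target_code):
        same = np.flatnonzero(codes == target_code)
        same = same[same != i]
        if same.size == 0:
            scores.append(0.0)
            continue
        a = np.mean([abs(x[i] - x[j]) for j in same])
        bs = []
        for c in set(codes) - {target_code}:
            other = np.flatnonzero(codes == c)
            if other.size:
                bs.append(np.mean([abs(x[i] - x[j]) for j in other]))
        b = min(bs)
        denom = max(a, b)
        scores.append((b - a) / denom if denom > 0 else 0.0)
    return float(np.mean(scores))


def _labels_from_codes(codes):
    names = [f"t{c}" for c in sorted(set(codes))]
    cells = [f"c{i}" for i in range(len(codes))]
    return cells, CellTypeLabels({c: f"t{k}" for c, k in zip(cells, codes)}, names)


class TestSummaries:
    def test_rate_and_mean_hand_example(self):
        # type A cells with values [0, 2] -> rate 0.5, mean 1.0
        Q = ExpressionMatrix(np.array([[0.0], [2.0], [1.0], [1.0]]),
                             ["c1", "c2", "c3", "c4"], ["g"])
        labels = CellTypeLabels({"c1": "A", "c2": "A", "c3": "B", "c4": "B"})
        S = summarize_by_type(Q, labels)
        assert S.O[0, 0] == 0.5 and S.P[0, 0] == 1.0
        assert S.O[1, 0] == 1.0 and S.P[1, 0] == 1.0

    def test_all_zero_and_constant_genes(self, tiny_matrix):
        Q, labels = tiny_matrix
        S = summarize_by_type(Q, labels)
        # g3 is constant 1 in all cells
        assert np.all(S.O[:, 2] == 1.0) and np.all(S.P[:, 2] == 1.0)

    def test_type_with_one_cell_rejected(self):
        Q = ExpressionMatrix(np.ones((3, 1)), ["a", "b", "c"], ["g"])
        labels = CellTypeLabels({"a": "A", "b": "A", "c": "B"})
        with pytest.raises(ValueError, match="'B'"):
            summarize_by_type(Q, labels)


class TestQuartileThreshold:
    def test_degenerate_all_equal(self):
        p = quartile_threshold(np.full(10, 0.4))
        assert p.Q3 == pytest.approx(0.4) and p.IQR == 0.0
        assert p.threshold == pytest.approx(0.4)

    def test_hand_quartiles_linear_interpolation(self):
        p = quartile_threshold(np.array([0, 0.25, 0.5, 0.75, 1.0]))
        assert p.Q3 == pytest.approx(0.75)
        assert p.IQR == pytest.approx(0.5)
        assert p.threshold == pytest.approx(1.5)

    def test_against_independent_quantile_oracle(self):
        rates = np.array([0.1, 0.1, 0.1, 0.9])
        # linear-interpolation quantile computed from first principles:
        # position h = (n-1)*q; value = x[floor(h)] + frac*(x[floor(h)+1]-x[floor(h)])
        xs = np.sort(rates)
        def quantile(q):
            h = (len(xs) - 1) * q
            lo = int(np.floor(h))
            return xs[lo] + (h - lo) * (xs[min(lo + 1, len(xs) - 1)] - xs[lo])
        q3, q1 = quantile(0.75), quantile(0.25)
        p = quartile_threshold(rates)
        assert p.threshold == pytest.approx(q3 + 1.5 * (q3 - q1), abs=1e-12)

    def test_alternative_precedence(self):
        p = quartile_threshold(np.array([0, 0.25, 0.5, 0.75, 1.0]), precedence="half")
        assert p.threshold == pytest.approx(0.5 * (2 * 0.75 + 1.5 * 0.5))


class TestThresholdAndTopMean:
    def _summary(self, O, P=None):
        O = np.asarray(O, float)
        P = O.copy() if P is None else np.asarray(P, float)
        k, m = O.shape
        from gtadc.feature_selection import TypeSummaryMatrices
        return TypeSummaryMatrices(O, P, [f"t{i}" for i in range(k)],
                                   [f"g{j}" for j in range(m)], "full")

    def test_gene_above_fence_kept(self):
        # type 0 rates mostly 0.2, one gene at 1.0 -> exceeds the fence
        O = np.array([[0.2] * 9 + [1.0], [0.2] * 10])
        S1 = threshold_filter(self._summary(O), min_genes=1)
        assert "g9" in S1.gene_ids

    def test_identical_rates_engage_fallback(self):
        O = np.full((2, 30), 0.5)
        S1 = threshold_filter(self._summary(O), min_genes=10)
        assert S1.n_genes == 10  # nothing strictly exceeds; fallback by max rate

    def test_top_mean_identity_when_l_equals_s(self):
        O = np.array([[0.2] * 4 + [1.0], [0.2] * 5])
        S1 = threshold_filter(self._summary(O), min_genes=3)
        assert top_mean_filter(S1, S1.n_genes).gene_ids == S1.gene_ids

    def test_top_mean_ranks_and_tie_break(self):
        from gtadc.feature_selection import TypeSummaryMatrices
        S1 = TypeSummaryMatrices(
            np.full((1, 3), 0.5), np.array([[5.0, 3.0, 3.0]]),
            ["t0"], ["gb", "ga", "gc"], "threshold_filtered",
        )
        S2 = top_mean_filter(S1, 2)
        # mean-5 gene kept; tie at 3.0 resolved to lexicographically smaller id
        assert set(S2.gene_ids) == {"gb", "ga"}
        with pytest.raises(ValueError):
            top_mean_filter(S1, 5)


class TestDispersion:
    def test_zero_when_no_mean_contrast(self):
        assert dispersion_score(a=3, b=3, c=0.9, d=0.1) == 0.0

    def test_ratio_near_one_when_rates_equal(self):
        assert dispersion_score(a=3, b=1, c=0.5, d=0.5) == pytest.approx(2.0, rel=1e-4)

    def test_hand_computation(self):
        assert dispersion_score(a=2, b=1, c=0.8, d=0.2) == pytest.approx(4.0, rel=1e-4)

    @given(
        a=st.floats(1.01, 10), b=st.floats(0, 1), c=st.floats(0.01, 1),
        d=st.floats(0.01, 1), delta=st.floats(0.01, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, a, b, c, d, delta):
        base = dispersion_score(a, b, c, d)
        assert dispersion_score(a + delta, b, c, d) > base
        assert dispersion_score(a, b + delta, c, d) < base
        assert dispersion_score(a, b, min(c + delta, 1.0), d) >= base
        assert dispersion_score(a, b, c, d + delta) < base


class TestGeneSilhouette:
    def test_identical_expression_scores_zero(self):
        cells, labels = _labels_from_codes([0, 0, 1, 1])
        assert gene_silhouette(np.full(4, 5.0), labels, cells, "t0") == 0.0

    def test_perfect_separation_scores_one(self):
        codes = [0, 0, 0, 1, 1, 1]
        cells, labels = _labels_from_codes(codes)
        x = np.array([10.0, 10, 10, 0, 0, 0])
        s = gene_silhouette(x, labels, cells, "t0")
        assert s == pytest.approx(brute_force_silhouette(x, np.array(codes), 0))
        assert s == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = rng.integers(9, 60)
            codes = rng.integers(0, 3, size=n)
            while len(set(codes)) < 3:
                codes = rng.integers(0, 3, size=n)
            x = rng.gamma(2.0, 2.0, size=n) * rng.integers(0, 2, size=n)
            cells, labels = _labels_from_codes(codes)
            for target in range(3):
                ours = gene_silhouette(x, labels, cells, f"t{target}")
                assert ours == pytest.approx(
                    brute_force_silhouette(x, codes, target), abs=1e-9
                )

    def test_matches_sklearn_silhouette_samples(self):
        from sklearn.metrics import silhouette_samples
        rng = np.random.default_rng(3)
        codes = np.repeat([0, 1, 2], 15)
        x = rng.normal(loc=codes * 2.0, scale=1.0)
        cells, labels = _labels_from_codes(codes)
        sk = silhouette_samples(x.reshape(-1, 1), codes, metric="euclidean")
        for target in range(3):
            assert gene_silhouette(x, labels, cells, f"t{target}") == pytest.approx(
                sk[codes == target].mean(), abs=1e-9
            )

    def test_null_gene_scores_near_zero_across_seeds(self):
        cells = [f"c{i}" for i in range(60)]
        labels = CellTypeLabels(
            {c: f"t{i % 3}" for i, c in enumerate(cells)}, ["t0", "t1", "t2"]
        )
        codes = np.array([i % 3 for i in range(60)])
        scores = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=60)
            scores.append(gene_silhouette(x, labels, cells, "t0"))
        assert abs(np.mean(scores)) < 0.15

    def test_unknown_target_type_rejected(self):
        cells, labels = _labels_from_codes([0, 0, 1, 1])
        with pytest.raises(ValueError, match="unknown target"):
            gene_silhouette(np.ones(4), labels, cells, "nope")

    def test_subsampling_is_deterministic(self):
        rng = np.random.default_rng(5)
        codes = np.repeat([0, 1], 400)
        x = rng.normal(loc=codes, size=800)
        cells, labels = _labels_from_codes(codes)
        s1 = gene_silhouette(x, labels, cells, "t0", max_cells_per_type=100, seed=9)
        s2 = gene_silhouette(x, labels, cells, "t0", max_cells_per_type=100, seed=9)
        assert s1 == s2


class TestMarkerSelection:
    def test_exclusive_gene_only_candidate_for_its_type(self, small_sim):
        ref, labels, marker_map = small_sim
        from gtadc.io import normalize, qc_filter_genes
        norm = normalize(qc_filter_genes(ref, labels))
        S2 = top_mean_filter(threshold_filter(summarize_by_type(norm, labels)), 150)
        cand = candidate_markers(S2, 30)
        for t, genes in marker_map.items():
            for other, lst in cand.items():
                if other != t:
                    assert not (set(genes) & set(lst))

    def test_select_markers_dedup_and_bound(self, tiny_matrix):
        Q, labels = tiny_matrix
        ms = select_markers({"A": ["g2", "g3"], "B": ["g1", "g3"]}, Q, labels, t=2)
        assert len(ms.union) <= 2 * 2
        assert len(ms.union) == len(set(ms.union))

    def test_top_exclusive_marker_selected_with_t1(self, small_sim):
        ref, labels, marker_map = small_sim
        from gtadc.io import normalize, qc_filter_genes
        norm = normalize(qc_filter_genes(ref, labels))
        ms = select_feature_genes(norm, labels, t=1)
        for t, (top,) in ((t, lst) for t, lst in ms.per_type.items()):
            assert top[0] in marker_map[t]

    def test_stages_only_remove_genes(self, small_sim):
        ref, labels, _ = small_sim
        from gtadc.io import normalize, qc_filter_genes
        norm = normalize(qc_filter_genes(ref, labels))
        S = summarize_by_type(norm, labels)
        S1 = threshold_filter(S)
        S2 = top_mean_filter(S1, min(S1.n_genes, 100))
        assert set(S1.gene_ids) <= set(S.gene_ids)
        assert set(S2.gene_ids) <= set(S1.gene_ids)
        assert S1.n_genes >= S2.n_genes
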