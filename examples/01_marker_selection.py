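"""Select cell-type marker genes from a scRNA-seq reference.

Builds a small synthetic reference with planted markers, runs the selection
pipeline (detection-rate fence -> top-mean cut -> dispersion ranking ->
silhouette re-ranking) and reports how many planted markers were recovered.
"""

from gtadc import normalize, qc_filter_genes, select_feature_genes
from gtadc.pipeline import marker_recovery_rate
from gtadc.simulate import SimulationConfig, simulate_reference

sim = SimulationConfig(k=3, cells_per_type=60, n_genes=500, markers_per_type=12, seed=0)
reference, labels, planted = simulate_reference(sim)

counts_qc = qc_filter_genes(reference, labels, min_rate=0.20)
log_norm = normalize(counts_qc, target_sum=1e4, log1p=True)
markers = select_feature_genes(log_norm, labels, t=12, seed=0)

print(f"reference: {reference.n_rows} cells x {reference.n_genes} genes, "
      f"{labels.k} cell types")
for cell_type, ranked in markers.per_type.items():
    top, score = ranked[0]
    print(f"  {cell_type}: top marker {top} (silhouette {score:.3f})")
print(f"marker union size: {len(markers.union)}")
print(f"planted-marker recovery: {marker_recovery_rate(markers, planted):.0%}")
# The silhouette scores near 1 say each marker's expression axis separates its
# type cleanly; recovery is the fraction of planted markers the method found.
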