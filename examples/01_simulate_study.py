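"""Generate a synthetic three-group study with planted ground truth.

Builds the default design — 15 young healthy (YH), 8 young patients (YP)
and 37 older patients (OP), 10,000 genes of which 150 carry primary-aging
effects and 1,000 carry shared pathology effects — and prints what was
planted where.
"""

from agesplit import synthetic

design = synthetic.StudyDesign(n_genes=10_000, seed=1)
counts, truth = synthetic.simulate_counts(design)
proteins = synthetic.simulate_proteome(design, counts, truth)

print(f"count matrix: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
print(f"protein matrix: {proteins.intensities.shape[0]} proteins "
      f"({design.protein_fraction:.0%} of genes quantified)")
print("\nplanted effect classes:")
print(truth["effect_class"].value_counts().to_string())
print("\nprotein regulation modes among quantified genes:")
print(truth.loc[truth["detected_as_protein"], "protein_mode"]
      .value_counts().to_string())

# pathology effects shift both patient groups; primary effects only OP
g = truth[truth["effect_class"] == "pathology_up"].index[0]
print(f"\nexample pathology_up gene {g}: "
      f"true lfc YP-vs-YH = {truth.loc[g, 'lfc_YP_vs_YH']:+.0f}, "
      f"OP-vs-YP = {truth.loc[g, 'lfc_OP_vs_YP']:+.0f}")
g = truth[truth["effect_class"] == "primary_up"].index[0]
print(f"example primary_up gene {g}:   "
      f"true lfc YP-vs-YH = {truth.loc[g, 'lfc_YP_vs_YH']:+.0f}, "
      f"OP-vs-YP = {truth.loc[g, 'lfc_OP_vs_YP']:+.0f}")
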