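"""Select primary-aging genes and check recovery against planted truth.

A gene counts as primary-aging when it changes in the same direction in
both OP-vs-YP and OP-vs-YH — at the protein level where quantified, at the
mRNA level otherwise (mRNAs whose quantified protein did not change are
excluded). Pathology genes shift YP and OP equally, so they cancel in
OP-vs-YP and stay out of the set.
"""

from agesplit import integrate, proteome, rnaseq, synthetic

design = synthetic.StudyDesign(n_genes=10_000, seed=1)
cm, truth = synthetic.simulate_counts(design)
pm = synthetic.simulate_proteome(design, cm, truth)

sf = rnaseq.size_factors(cm.counts)
disp = rnaseq.estimate_dispersion(cm.counts, sf, cm.groups)
tpm = rnaseq.compute_tpm(cm.counts, cm.gene_lengths)
de = {
    pair: rnaseq.call_degs(
        rnaseq.wald_test(cm.counts, sf, disp, cm.groups, pair),
        tpm, cm.groups, pair,
    )
    for pair in (("OP", "YP"), ("OP", "YH"))
}
prot = proteome.anova_tukey(
    proteome.filter_proteins(proteome.batch_normalize(pm)),
    tukey_scope="candidates",
)
selected = integrate.select_primary_aging(
    de[("OP", "YP")], de[("OP", "YH")],
    proteome.pairwise_status(prot, ("OP", "YP")),
    proteome.pairwise_status(prot, ("OP", "YH")),
    detected_proteins=pm.intensities.index,
)

print(f"selected primary-aging genes: {len(selected)} "
      f"({(selected['direction'] == 'up').sum()} up, "
      f"{(selected['direction'] == 'down').sum()} down)")
print(selected["evidence"].value_counts().to_string())

planted = set(truth.index[truth["effect_class"].isin(["primary_up", "primary_down"])])
got = set(selected.index)
print(f"\nplanted primary genes: {len(planted)}")
print(f"sensitivity: {len(planted & got) / len(planted):.2f}  "
      f"precision: {len(planted & got) / len(got):.2f}")
pathology = set(truth.index[truth["effect_class"].str.startswith("pathology")])
print(f"pathology genes leaking in: {len(pathology & got)} of {len(pathology)}")
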