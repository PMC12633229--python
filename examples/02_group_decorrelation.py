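"""Within-group correlation shifts and Mahalanobis separation in disease.

For module genes coupled at r = 0.6 in Control but 0.3 in AD, the analysis
reports the per-group r, classifies the change (stable / decorrelated /
over_correlated within a +/-0.02 band), and quantifies centroid separation
of the anchor's (RNA, protein) cloud with the pooled-covariance
Mahalanobis distance D (little < 0.60 <= moderate < 0.90 <= strong).
"""

import anchoromics as am

cfg = am.SimConfig(seed=7)
cfg.n_per_group = {"Control": 60, "MCI": 0, "AD": 60, "Other": 0}
data = am.simulate_dataset(cfg)
groups = data.metadata["group"]
anchor = data.rna.feature("NPTX2")

print("gene            r_Control  r_AD   class")
module = [g for g in data.rna.feature_ids if g.startswith("PLASTICITY")][:5]
for gene in module:
    wr = am.within_group_r(data.rna.feature(gene), anchor, groups,
                           keep=["Control", "AD"])
    cls = am.classify_decorrelation(wr["Control"].r, wr["AD"].r)
    print(f"{gene:15s} {wr['Control'].r:8.3f} {wr['AD'].r:6.3f}   {cls}")

protein = am.rollup_peptides(data.peptides)
res = am.group_shift_analysis(
    anchor.loc[protein.sample_ids], protein.feature("NPTX2"), groups,
    gene_id="NPTX2", layer="rna_protein",
)
print(f"\nanchor RNA vs anchor protein: D = {res.D:.2f} "
      f"({res.separation_class} separation)")
# The planted AD protein downshift (1 pooled SD) moves the AD centroid down
# the protein axis, so D lands in the 'strong' band even though the
# within-group correlation itself barely changes.
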