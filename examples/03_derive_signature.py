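"""Derive a gene signature by backwards feature selection.

Starting from the MFA candidates, a Gaussian-kernel SVM is cross-validated
leave-one-out; each round drops the gene whose exclusion lowers the CV
misclassification the most, and the best visited subset (over a small
C x sigma grid) becomes the signature.
"""

import pandas as pd

import platinsig as ps

panel = ps.generate_panel(ps.PanelSpec(seed=1))
x = ps.zscore_normalize(panel.expression)
d = panel.dose_response
y = ps.label_by_threshold(d, d.median())

blocks = [("GE", x.to_frame()),
          ("GI50", pd.DataFrame([d.gi50], index=["GI50"], columns=d.sample_ids))]
cand = ps.select_correlated_genes(ps.run_mfa(blocks, 2, align_to="GI50"), "GI50")
print(f"start set: {len(cand.genes)} MFA-qualified genes")

sigs = ps.derive_signature(x, y, cand.genes, C_grid=[10, 1000], sigma_grid=[10, 100])
sig = sigs[0]
print(f"{len(sigs)} co-optimal signature(s)")
print(f"signature: {sig.genes} (C={sig.hyperparams.C:g}; sigma={sig.hyperparams.sigma:g})")
print(f"LOOCV misclassification: {sig.objective_value:.3f}")
print("removal trace (round, removed gene, CV value):")
for row in sig.provenance:
    if row.get("removed"):
        print(f"  {row['round']:2d}  {row['removed']:6s} -> {row['value']:.3f}")
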