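"""Simulate a cell-line panel with planted drug-response genes.

Generates a 40-line x 30-gene expression panel in which 3 genes linearly
drive a continuous GI50 (mapped into the 4.0-5.6 -log10 molar range), then
derives binary sensitive/resistant labels at the median GI50.
"""

import platinsig as ps

panel = ps.generate_panel(ps.PanelSpec(seed=1))
d = panel.dose_response

print(f"panel: {panel.expression.n_genes} genes x {panel.expression.n_samples} cell lines")
print(f"planted genes: {panel.truth['informative_genes']} (signs {panel.truth['signs']})")
print(f"GI50 range: {d.gi50.min():.2f}-{d.gi50.max():.2f}, median {d.median():.3f}")

y = ps.label_by_threshold(d, d.median())
print(f"labels at the median threshold: {y.n_sensitive} sensitive / {y.n_resistant} resistant")
# sensitive means GI50 above the cutoff: the line is growth-inhibited at a
# lower drug concentration
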