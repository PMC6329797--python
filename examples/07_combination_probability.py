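"""Combine per-drug sensitivity probabilities for combination chemotherapy.

Under independence the probability of sensitivity to at least one drug of
a combination is 1 - prod(1 - d_i); a pooled pair estimate d_ij replaces
two terms when their errors are suspected to be dependent.
"""

import platinsig as ps

p_s, p_r = ps.combine_drug_probabilities([0.9, 0.05], mode="independent")
print(f"drugs at 90% and 5% sensitivity -> combination: "
      f"{100 * p_s:.1f}% sensitive / {100 * p_r:.1f}% resistant")

combo = ps.DrugCombination({"cisplatin": 0.9, "gemcitabine": 0.05, "paclitaxel": 0.5},
                           pairs={("cisplatin", "gemcitabine"): 0.8})
p_s2, p_r2 = ps.combine_drug_probabilities(combo, mode="paired")
print(f"with a pooled cisplatin+gemcitabine estimate of 0.8: "
      f"{100 * p_s2:.1f}% sensitive / {100 * p_r2:.1f}% resistant")
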