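"""TE content of simulated genes and the length~TE correlation.

Simulates 30 taxa whose intron growth is exclusively TE insertion at rates
varying across branches, profiles each gene's TE composition, and tests the
Pearson correlation between gene length and TE fraction.
"""

from intronarch import pearson_correlation, te_profile
from intronarch.models import TEAnnotation
from intronarch.simulate import SimConfig, simulate_family

cfg = SimConfig(seed=42, n_leaves=30, gain_rate=0, loss_rate=0, subst_rate=0,
                te_rate_max=4.0)
models, truth = simulate_family(cfg)

lengths, fractions = [], []
for m in models:
    annos = [
        TEAnnotation(m.gene_id, r["start"], r["end"], r["te_class"], r["superfamily"])
        for r in truth.te_registry[m.taxon]
    ]
    prof = te_profile(m, annos)
    lengths.append(m.gene_length)
    fractions.append(prof.te_fraction)

print(f"gene lengths: {min(lengths):,} - {max(lengths):,} nt")
print(f"TE fractions: {min(fractions):.2f} - {max(fractions):.2f} % of gene length")
r, p = pearson_correlation(lengths, fractions)
print(f"Pearson r(gene length, TE fraction) = {r:.3f}  (p = {p:.2e})")
print("(length expansion driven purely by TE insertion yields a strong")
print(" positive correlation between gene length and TE proportion)")
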