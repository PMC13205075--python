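"""Gene-ratio-ranked term enrichment of up-regulated genes.

Simulates an experiment whose term catalogue contains one planted
"lipid storage" set enriched for up-regulated mRNAs, runs the
hypergeometric over-representation test and ranks by gene ratio (overlap
divided by selected-set size) — the convention for reporting top GO terms
and pathways.
"""

from cernascreen import enrichment, synthetic
from cernascreen.types import SimulationConfig

config = SimulationConfig(
    n_mrna=400, n_lncrna=10, n_mirna=10, n_circrna=10,
    n_de_per_class={"mRNA": 40, "lncRNA": 0, "miRNA": 0, "circRNA": 0},
    n_triads=0, n_terms=16, seed=2,
)
matrix, _, _, terms, truth = synthetic.simulate_experiment(config, with_sequences=False)

up = {f for f, (d, _) in truth.de_status.items()
      if d == "up" and matrix.rna_class.loc[f] == "mRNA"}
universe = set(matrix.features_in_class("mRNA"))
records = enrichment.enrich(up, terms, universe, direction_label="up")
top = enrichment.top_terms(records)

print(f"universe: {len(universe)} mRNAs; selected (up): {len(up)}")
print("top terms by gene ratio (k/n = selected genes in term / selected genes):")
for r in top[:6]:
    marker = "  <- planted" if r.term_id == truth.enriched_term_id else ""
    print(f"  {r.namespace:7s} {r.term_id:16s} gene_ratio={r.gene_ratio:.3f} "
          f"k={r.k:2d} K={r.K:3d} p={r.p:.3g} p_adj={r.p_adj:.3g}{marker}")
print("the planted lipid-storage analogue should rank first in BP with the")
print("smallest p: most of its members were drawn from the up-regulated set")
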