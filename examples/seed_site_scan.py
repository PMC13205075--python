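"""Classify canonical miRNA seed sites on a target sequence.

Builds a target carrying one site of each canonical class for a single
miRNA and scans it. Site classes (8mer > 7mer-m8 > 7mer-A1 > 6mer) differ
in whether the match extends to miRNA position 8 and whether an A faces
miRNA position 1 on the target.
"""

from cernascreen.targeting import reverse_complement, seed_sites

mirna = "UGGAAUGUAAAGAAGUAUGUAU"
core = reverse_complement(mirna[1:7])     # pairs miRNA positions 2-7
m8 = reverse_complement(mirna[7])          # complement of miRNA position 8

spacer = "GGGG"
target = spacer.join([
    "CC" + core + "C",        # 6mer: bare core
    "CC" + core + "A",        # 7mer-A1: core + A opposite position 1
    m8 + core + "C",          # 7mer-m8: m8 match + core
    m8 + core + "A",          # 8mer: both
]) + "CC"

print(f"miRNA 5'->3': {mirna}")
print(f"seed core on target: {core} (reverse complement of positions 2-7)")
for site in seed_sites("miR-x", mirna, "target-1", target):
    print(f"  position {site.position:3d}: {site.site_type}")
print("stronger site classes predict stronger repression; the screen can be")
print("restricted to >= 7mer evidence (its default) to suppress chance 6mers")
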