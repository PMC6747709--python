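"""Enumerate the single-mutant library at a six-site panel and combine
kept singles into higher-order variants.

Each site is mutated to the 17 allowed residues (C and P are never
introduced; cysteine positions are never touched), giving 6 x 17 = 102
single-point mutants.
"""

from nbmature import (MutagenesisPolicy, SiteSet, combine_variants,
                      enumerate_single_mutants, parse_variant)

wt = {55: "S", 58: "V", 107: "G", 108: "T", 109: "S", 110: "F"}
sites = SiteSet(residues=frozenset(wt), provenance="overlap")
singles = enumerate_single_mutants(wt, MutagenesisPolicy(sites=sites))
print(f"single mutants at {len(wt)} sites: {len(singles)}")

round1 = [parse_variant(s) for s in
          ("S55Q", "G107I", "G107W", "T108H", "S109E", "S109V", "F110A")]
doubles = combine_variants(round1, 2)
print(f"double mutants from {len(round1)} kept singles: {len(doubles)}")
print("first five:", ", ".join(v.label for v in doubles[:5]))
# 7 singles give C(7,2)=21 pairs; the two same-position pairs (G107, S109)
# are dropped, leaving 19 position-distinct doubles.
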