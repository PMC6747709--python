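"""Rank mutants by robust consensus Z-score over three simulated scorers.

Raw scores (lower = better) are standardised per scorer by median/MAD,
averaged, and the negative-Z shortlist is taken.  Four truly beneficial
singles are planted; they should float to the top.
"""

from nbmature import (MutagenesisPolicy, PlantedScenario, SiteSet,
                      consensus_z, enumerate_single_mutants, gen_score_table,
                      select_top)

scenario = PlantedScenario.default_campaign(seed=0)
wt = dict(PlantedScenario.CAMPAIGN_SITES)
sites = SiteSet(residues=frozenset(wt), provenance="overlap")
singles = enumerate_single_mutants(wt, MutagenesisPolicy(sites=sites))
table = gen_score_table(singles, scenario)

result = consensus_z(table)
top = select_top(result, n=10, max_z=0.0)
print("top 10 by consensus Z (most negative = predicted best):")
for lab in top:
    marker = " <- planted" if lab in scenario.planted_effects else ""
    print(f"  {lab:8s} Z = {result.consensus[lab]:+.2f}{marker}")
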