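"""Nominate mutation sites: hotspot motifs on the coding DNA intersected
with the 5 A antibody-antigen interface.

Builds a synthetic coding sequence with AGY/RGYW motifs planted at chosen
residues and a toy complex whose contact footprint is known exactly, then
runs both criteria and intersects them.
"""

from nbmature import (gen_coding_dna, gen_toy_complex, hotspot_residues,
                      interface_residues, rmhdp_overlap, scan_hotspot_motifs)

protein = "M" + "A" * 40 + "S" + "AA" + "V" + "A" * 20  # S at 42, V at 45
cs, manifest = gen_coding_dna(protein, [42], seed=0)
hits = scan_hotspot_motifs(cs)
hot = hotspot_residues(hits, cs)
print(f"hotspot residues (AGY/RGYW coverage): {hot.sorted()}")

complex_ = gen_toy_complex(len(protein), [30, 42, 43], seed=0)
iface = interface_residues(complex_, "A", "B", cutoff=5.0)
print(f"interface residues (<= 5 A of partner): {iface.sorted()}")

panel = rmhdp_overlap(iface, hot)
print(f"nominated mutation panel (overlap):     {panel.sorted()}")
# The overlap keeps only residues supported by BOTH criteria - these are
# the positions worth spending mutagenesis and scoring effort on.
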