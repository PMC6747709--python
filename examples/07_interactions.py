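"""Classify the noncovalent contacts across an interface by distance
criteria: salt bridge, H-bond, cation-pi, aromatic-aromatic, hydrophobic.

Coordinates are constructed analytically so each expected contact type and
distance is known in advance.
"""

import numpy as np

from nbmature import ResidueSelection, detect_interactions
from nbmature.structio import Atom, Chain, Residue, Structure


def residue(number, name, atoms):
    return Residue(author_number=number, name=name,
                   atoms=[Atom(name=n, element=e, xyz=np.array(x, float))
                          for n, e, x in atoms])


def phe(number, center):
    cx, cy, cz = center
    atoms = [("CA", "C", (cx, cy, cz + 4.0))]
    for i, n in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
        a = np.pi * i / 3
        atoms.append((n, "C", (cx + 1.39 * np.cos(a), cy + 1.39 * np.sin(a), cz)))
    return residue(number, "PHE", atoms)


antibody = Chain(id="A", residues=[
    residue(108, "HIS", [("CA", "C", (0, 0, 5)), ("ND1", "N", (0, 0, 0)),
                         ("CG", "C", (-1, 0, 0)), ("CD2", "C", (-1, 1, 0)),
                         ("CE1", "C", (0.5, 1, 0)), ("NE2", "N", (-0.2, 1.8, 0))]),
    phe(107, (10, 0, 0)),
])
antigen = Chain(id="B", residues=[
    residue(51, "ASP", [("CA", "C", (3.5, 0, 5)), ("OD1", "O", (3.2, 0, 0))]),
    phe(37, (10, 0, 4.65)),
])
s = Structure(chains=[antibody, antigen])

records = detect_interactions(s, ResidueSelection("A"), ResidueSelection("B"))
for r in records:
    print(f"{r.type:18s} {r.name_a}{r.residue_a} -- {r.name_b}{r.residue_b}"
          f"  {r.distance:.2f} A  ({r.detail})")
# With histidine uncharged (default) the H108-D51 pair is an H-bond, not a
# salt bridge; the stacked rings at 4.65 A are an aromatic-aromatic contact.
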