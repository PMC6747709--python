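"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation paths they check:
the motif oracle enumerates concrete k-mers by substring comparison, the
interface oracle is an all-pairs O(n^2) distance loop, and the codon oracle
is a hard-coded translation table.
"""

from __future__ import annotations

import numpy as np
import pytest

from nbmature.fixtures import load_reference_tables
from nbmature.structio import Atom, Chain, Residue, Structure

# expansions written out by hand: R=A/G, Y=C/T, W=A/T
AGY_KMERS = ("AGC", "AGT")
RGYW_KMERS = ("AGCA", "AGCT", "AGTA", "AGTT", "GGCA", "GGCT", "GGTA", "GGTT")


def oracle_motif_hits(seq: str) -> set[tuple[str, int]]:
    """Every (motif name, start) occurrence by naive substring comparison."""
    hits = set()
    for name, kmers in (("AGY", AGY_KMERS), ("RGYW", RGYW_KMERS)):
        k = len(kmers[0])
        for i in range(len(seq) - k + 1):
            if seq[i:i + k] in kmers:
                hits.add((name, i))
    return hits


def oracle_interface(structure: Structure, query: str, partner: str,
                     cutoff: float) -> set[int]:
    """All-pairs heavy-atom distance loop."""
    q = structure.chain(query)
    p = structure.chain(partner)
    partner_atoms = [a.xyz for r in p.residues for a in r.atoms if a.is_heavy]
    out = set()
    for res in q.residues:
        for a in res.atoms:
            if not a.is_heavy:
                continue
            for b in partner_atoms:
                if float(np.linalg.norm(a.xyz - b)) <= cutoff:
                    out.add(res.author_number)
                    break
            else:
                continue
            break
    return out


# hard-coded standard genetic code (independent of any library table)
ORACLE_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def make_residue(number: int, name: str, atom_specs) -> Residue:
    """Residue from [(atom name, element, (x, y, z)), ...]."""
    return Residue(author_number=number, name=name,
                   atoms=[Atom(name=n, element=e, xyz=np.array(xyz, dtype=float))
                          for n, e, xyz in atom_specs])


def two_residue_structure(res_a: Residue, res_b: Residue) -> Structure:
    return Structure(chains=[Chain(id="A", residues=[res_a]),
                             Chain(id="B", residues=[res_b])])


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def six_site_overlap(reference_tables):
    from nbmature.rmhdp import rmhdp_overlap

    return rmhdp_overlap(reference_tables.interface, reference_tables.hotspot)
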