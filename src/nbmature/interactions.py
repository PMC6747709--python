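"""Distance-based classification of noncovalent contacts across an interface.

Five classes, each with a configurable distance cutoff and the standard
atom sets from the structural-biology literature:

- salt bridge: charged side-chain N of {Lys, Arg} (His optional) to
  carboxylate O of {Asp, Glu}, <= 4.0 A
- hydrogen bond: any N/O donor-acceptor pair, <= 3.5 A (distance-only; an
  angular criterion is a documented extension, off by default because the
  input structures are models with unreliable hydrogens)
- cation-pi: charged-group atom of {Lys, Arg} to aromatic ring centroid of
  {Phe, Tyr, Trp, His}, <= 6.0 A
- aromatic-aromatic: ring centroid to ring centroid, <= 7.0 A
- hydrophobic: side-chain carbon pairs of apolar residues, <= 4.5 A

Histidine counts as aromatic for the pi terms but is not charged by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structio import Residue, Structure

__all__ = ["InteractionCutoffs", "InteractionRecord", "detect_interactions",
           "ResidueSelection"]

log = logging.getLogger(__name__)

POSITIVE_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_POSITIVE_ATOMS = {"HIS": ("ND1", "NE2")}
NEGATIVE_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class InteractionCutoffs:
    salt_bridge: float = 4.0
    hbond: float = 3.5
    cation_pi: float = 6.0
    aromatic_aromatic: float = 7.0
    hydrophobic: float = 4.5
    histidine_charged: bool = False


@dataclass(frozen=True)
class InteractionRecord:
    type: str
    chain_a: str
    residue_a: int
    name_a: str
    chain_b: str
    residue_b: int
    name_b: str
    distance: float  # Angstrom, per-type metric
    detail: str = ""  # atoms or centroids used


@dataclass
class ResidueSelection:
    """Residues of one chain, optionally restricted to author numbers."""

    chain_id: str
    residue_numbers: frozenset[int] | None = None

    def pick(self, s: Structure) -> list[tuple[str, Residue]]:
        ch = s.chain(self.chain_id)
        out = []
        for r in ch.residues:
            if self.residue_numbers is None or r.author_number in self.residue_numbers:
                out.append((ch.id, r))
        if not out:
            raise ValueError(f"selection on chain {self.chain_id!r} is empty")
        return out


def _atoms(res: Residue, names: tuple[str, ...]) -> list:
    return [a for a in res.atoms if a.name in names]


def _ring_centroid(res: Residue) -> np.ndarray | None:
    names = AROMATIC_RINGS.get(res.name)
    if names is None:
        return None
    atoms = _atoms(res, names)
    if len(atoms) < len(names):
        log.warning("residue %s%d: incomplete aromatic ring, skipped",
                    res.name, res.author_number)
        return None
    return np.mean([a.xyz for a in atoms], axis=0)


def _positive_atoms(res: Residue, cutoffs: InteractionCutoffs):
    table = dict(POSITIVE_ATOMS)
    if cutoffs.histidine_charged:
        table.update(HIS_POSITIVE_ATOMS)
    return _atoms(res, table.get(res.name, ()))


def _no_atoms(res: Residue) -> list:
    return [a for a in res.atoms if a.element.upper() in ("N", "O")]


def _sidechain_carbons(res: Residue) -> list:
    return [a for a in res.atoms
            if a.element.upper() == "C" and a.name not in BACKBONE_ATOMS]


def _min_pair(atoms_a, atoms_b):
    best = None
    for a in atoms_a:
        for b in atoms_b:
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if best is None or d < best[0]:
                best = (d, a, b)
    return best


def detect_interactions(
    s: Structure,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    cutoffs: InteractionCutoffs | None = None,
) -> list[InteractionRecord]:
    """Classify pairwise contacts between two residue selections.

    The output is symmetric: swapping the selections yields the same residue
    pairs (A/B roles exchanged).  One record per (pair, type), carrying the
    minimal per-type distance and the atoms or centroids that realised it.
    """
    cutoffs = cutoffs or InteractionCutoffs()
    records: list[InteractionRecord] = []
    for chain_a, res_a in selection_a.pick(s):
        for chain_b, res_b in selection_b.pick(s):
            if chain_a == chain_b and res_a.key == res_b.key:
                continue
            records.extend(_classify_pair(chain_a, res_a, chain_b, res_b, cutoffs))
    records.sort(key=lambda r: (r.type, r.chain_a, r.residue_a,
                                r.chain_b, r.residue_b))
    return records


def _classify_pair(chain_a, res_a, chain_b, res_b,
                   cutoffs: InteractionCutoffs) -> list[InteractionRecord]:
    found: list[InteractionRecord] = []

    def record(kind, dist, detail):
        found.append(InteractionRecord(
            type=kind, chain_a=chain_a, residue_a=res_a.author_number,
            name_a=res_a.name, chain_b=chain_b, residue_b=res_b.author_number,
            name_b=res_b.name, distance=round(dist, 3), detail=detail))

    # salt bridge (either orientation)
    for pos, neg, flip in ((res_a, res_b, False), (res_b, res_a, True)):
        pa = _positive_atoms(pos, cutoffs)
        na = _atoms(neg, NEGATIVE_ATOMS.get(neg.name, ()))
        if pa and na:
            best = _min_pair(pa, na)
            if best and best[0] <= cutoffs.salt_bridge:
                detail = (f"{best[2].name}-{best[1].name}" if flip
                          else f"{best[1].name}-{best[2].name}")
                record("salt_bridge", best[0], detail)
                break

    # hydrogen bond: any N/O vs N/O
    best = _min_pair(_no_atoms(res_a), _no_atoms(res_b))
    if best and best[0] <= cutoffs.hbond:
        record("hbond", best[0], f"{best[1].name}-{best[2].name}")

    # cation-pi (either orientation)
    for cat, aro, flip in ((res_a, res_b, False), (res_b, res_a, True)):
        ca = _positive_atoms(cat, cutoffs)
        centroid = _ring_centroid(aro)
        if ca and centroid is not None:
            d = min(float(np.linalg.norm(a.xyz - centroid)) for a in ca)
            if d <= cutoffs.cation_pi:
                record("cation_pi", d, "charged-group/ring-centroid")
                break

    # aromatic-aromatic
    cen_a, cen_b = _ring_centroid(res_a), _ring_centroid(res_b)
    if cen_a is not None and cen_b is not None:
        d = float(np.linalg.norm(cen_a - cen_b))
        if d <= cutoffs.aromatic_aromatic:
            record("aromatic_aromatic", d, "ring-centroid/ring-centroid")

    # hydrophobic
    if res_a.name in APOLAR_RESIDUES and res_b.name in APOLAR_RESIDUES:
        best = _min_pair(_sidechain_carbons(res_a), _sidechain_carbons(res_b))
        if best and best[0] <= cutoffs.hydrophobic:
            record("hydrophobic", best[0], f"{best[1].name}-{best[2].name}")

    return found
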