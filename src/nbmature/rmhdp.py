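"""Rational mutation-hotspot site nomination.

Combines two independent criteria for where affinity-maturation mutations
should go:

1. *Sequence hotspots* — DNA motifs enriched at somatic-hypermutation sites,
   by default the serine-codon family AGY and the degenerate RGYW motif
   (R = A/G, Y = C/T, W = A/T).  A motif hit covers every residue whose
   codon it overlaps, so a boundary-spanning RGYW marks both flanking
   residues — this is what puts non-serine residues (e.g. V58, T108, F110)
   on a hotspot list.
2. *Interface residues* — antibody residues with any heavy atom within a
   distance cutoff (default 5.0 Angstrom) of the antigen chain.

The intersection of the two sets is the nominated mutation-site panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import CodingSequence, Structure

__all__ = [
    "MotifDef",
    "HotspotHit",
    "SiteSet",
    "DEFAULT_MOTIFS",
    "scan_hotspot_motifs",
    "hotspot_residues",
    "interface_residues",
    "rmhdp_overlap",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


@dataclass(frozen=True)
class MotifDef:
    """A degenerate DNA motif over IUPAC codes."""

    name: str
    pattern: str

    def __post_init__(self):
        bad = [c for c in self.pattern if c not in IUPAC]
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC codes {bad}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def expand(self) -> list[str]:
        """All concrete k-mers the pattern matches (AGY -> 2, RGYW -> 8)."""
        return ["".join(p) for p in itertools.product(*(IUPAC[c] for c in self.pattern))]

    def matches(self, kmer: str) -> bool:
        return len(kmer) == self.length and all(
            b in IUPAC[c] for b, c in zip(kmer, self.pattern))

    def reverse_complement(self) -> "MotifDef":
        rc = self.pattern.translate(_COMPLEMENT)[::-1]
        return MotifDef(name=f"{self.name}-rc", pattern=rc)


DEFAULT_MOTIFS = (MotifDef("AGY", "AGY"), MotifDef("RGYW", "RGYW"))


@dataclass(frozen=True)
class HotspotHit:
    motif: str
    nt_start: int  # 0-based on the forward strand
    strand: str  # "+" or "-"
    covered_residues: frozenset[int]  # author residue numbers


@dataclass
class SiteSet:
    """A set of author residue numbers with provenance.

    provenance is one of {"interface", "hotspot", "overlap"}; for overlap
    sets the residues are a subset of both parents by construction.
    """

    residues: frozenset[int]
    provenance: str
    aa_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.residues = frozenset(self.residues)
        if self.provenance not in ("interface", "hotspot", "overlap", "user"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __contains__(self, residue: int) -> bool:
        return residue in self.residues

    def __len__(self) -> int:
        return len(self.residues)

    def sorted(self) -> list[int]:
        return sorted(self.residues)


def scan_hotspot_motifs(
    cs: CodingSequence,
    motifs=DEFAULT_MOTIFS,
    scan_reverse_complement: bool = False,
) -> list[HotspotHit]:
    """Report every occurrence of every motif on the coding sequence.

    Hits are reported on the forward strand only by default (somatic
    hypermutation hotspots are strand-specific); ``scan_reverse_complement``
    additionally scans each motif's reverse complement (the WRCY mirror of
    RGYW), still reporting forward-strand coordinates.

    A hit covers every residue whose codon interval overlaps the motif
    interval ``[nt_start, nt_start + len)``.
    """
    seq = cs.nucleotides
    hits: list[HotspotHit] = []
    scan_list = [(m, "+") for m in motifs]
    if scan_reverse_complement:
        scan_list += [(m.reverse_complement(), "-") for m in motifs]
    for motif, strand in scan_list:
        k = motif.length
        for start in range(0, len(seq) - k + 1):
            if motif.matches(seq[start:start + k]):
                covered = _covered_residues(cs, start, start + k)
                hits.append(HotspotHit(motif=motif.name, nt_start=start,
                                       strand=strand,
                                       covered_residues=frozenset(covered)))
    hits.sort(key=lambda h: (h.nt_start, h.motif, h.strand))
    return hits


def _covered_residues(cs: CodingSequence, nt_start: int, nt_end: int) -> set[int]:
    covered = set()
    for i in range(cs.n_codons):
        c_start, c_end = cs.codon_span(i)
        if c_start < nt_end and nt_start < c_end:
            covered.add(cs.residue_numbers[i])
    return covered


def hotspot_residues(hits: list[HotspotHit], cs: CodingSequence | None = None) -> SiteSet:
    """Union of residues covered by any hotspot hit."""
    residues: set[int] = set()
    for h in hits:
        residues |= h.covered_residues
    aa = {}
    if cs is not None:
        from .structio import translate

        prot = translate(cs)
        num_to_aa = dict(zip(cs.residue_numbers, prot))
        aa = {r: num_to_aa[r] for r in residues if r in num_to_aa}
    return SiteSet(residues=frozenset(residues), provenance="hotspot", aa_names=aa)


def interface_residues(
    s: Structure,
    query_chain: str,
    partner_chain: str,
    cutoff: float = 5.0,
) -> SiteSet:
    """Residues of ``query_chain`` with a heavy atom within ``cutoff`` of
    any heavy atom of ``partner_chain`` (Angstrom, Euclidean).

    Hydrogens are ignored: the structures this operates on typically come
    from modeling, where hydrogen placement is unreliable.
    """
    query = s.chain(query_chain)
    partner = s.chain(partner_chain)
    partner_coords = np.concatenate(
        [r.heavy_coords() for r in partner.residues] or [np.empty((0, 3))])
    if partner_coords.size == 0:
        raise ValueError(f"chain {partner_chain!r} has no heavy atoms")
    tree = cKDTree(partner_coords)
    residues: set[int] = set()
    aa: dict[int, str] = {}
    for res in query.residues:
        coords = res.heavy_coords()
        if coords.size == 0:
            continue
        dmin = tree.query(coords, k=1)[0].min()
        if dmin <= cutoff:
            residues.add(res.author_number)
            aa[res.author_number] = res.aa1 or res.name
    return SiteSet(residues=frozenset(residues), provenance="interface", aa_names=aa)


def rmhdp_overlap(interface: SiteSet, hotspot: SiteSet) -> SiteSet:
    """Intersection of interface and hotspot site sets — the mutation panel."""
    residues = interface.residues & hotspot.residues
    aa = {r: hotspot.aa_names.get(r, interface.aa_names.get(r))
          for r in residues
          if r in hotspot.aa_names or r in interface.aa_names}
    return SiteSet(residues=residues, provenance="overlap", aa_names=aa)


def expand_ranges(spec: str) -> set[int]:
    """Parse "32,35,105-113" -> {32, 35, 105, ..., 113}."""
    out: set[int] = set()
    for part in spec.replace(" ", "").split(","):
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-")
            out |= set(range(int(lo), int(hi) + 1))
        else:
            out.add(int(part))
    return out
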