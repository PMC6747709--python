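"""Structural and sequence data model, PDB/FASTA I/O, and mutation notation.

Residue identity throughout the package is the *author* numbering of the PDB
file (integer plus optional insertion code), because the positions a nanobody
engineer talks about (S55, G107, ...) are author numbers, not sequential
indices.  Sequence positions in all user-facing output are therefore 1-based
author numbers; internal arrays are 0-based.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.Seq import Seq

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "CodingSequence",
    "MutationSpec",
    "Variant",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "write_fasta",
    "parse_mutation",
    "parse_variant",
    "apply_variant",
    "revert_variant",
    "translate",
]

STANDARD_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_1TO3 = {v: k.upper() for k, v in protein_letters_3to1.items()}


def three_to_one(resname: str) -> str | None:
    """3-letter residue name -> 1-letter code, or None if non-standard."""
    return _3TO1.get(resname.upper())


class PDBFormatError(ValueError):
    """Raised for unparseable PDB records; message names the line number."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # Angstrom, shape (3,)
    is_hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    author_number: int
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    @property
    def aa1(self) -> str | None:
        """1-letter code, or None for non-standard residues."""
        return three_to_one(self.name)

    def heavy_coords(self) -> np.ndarray:
        coords = [a.xyz for a in self.atoms if a.is_heavy]
        return np.array(coords) if coords else np.empty((0, 3))

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (number, insertion_code):
                return r
        return None

    def sequence_map(self) -> dict[int, str]:
        """author_number -> 1-letter code for standard residues (no icodes)."""
        return {
            r.author_number: r.aa1
            for r in self.residues
            if r.aa1 is not None and not r.insertion_code
        }


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for ch in self.chains:
            for r in ch.residues:
                k = (ch.id, r.author_number, r.insertion_code)
                if k in seen:
                    raise ValueError(f"duplicate residue key {k}")
                seen.add(k)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(f"chain {chain_id!r} not in structure "
                       f"(have {[c.id for c in self.chains]})")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for ch in self.chains for r in ch.residues)


# ---------------------------------------------------------------------------
# PDB I/O
#
# Fixed-column ATOM/HETATM records.  Altloc policy: keep the
# highest-occupancy conformer per (residue, atom name); ties broken by
# altloc letter, for determinism.  Waters and HETATM are excluded by default
# (protein-protein contact analysis never wants them); MODEL 1 only.
# ---------------------------------------------------------------------------

def _locate_bad_record(path) -> int | None:
    """First ATOM/HETATM line whose fixed-column fields do not parse."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line[:6].strip() not in ("ATOM", "HETATM"):
                continue
            try:
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                return lineno
    return None


def read_pdb(path, include_hetero: bool = False, include_waters: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure` (via Bio.PDB, strict mode).

    Only MODEL 1 of multi-model files is read.  HETATM records and waters
    are excluded unless requested; hydrogens are kept (distance routines
    filter on the element themselves).  For disordered atoms the
    highest-occupancy conformer is kept, ties going to the altloc that
    appears first in the file (altloc A in conventionally written files),
    so repeated reads are deterministic.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        lineno = _locate_bad_record(path)
        where = f"line {lineno}: " if lineno else ""
        raise PDBFormatError(f"{path}: {where}unparseable record ({exc})") from exc
    try:
        model = next(iter(bio))
    except StopIteration:
        raise PDBFormatError(f"{path}: empty structure (no ATOM records kept)")
    chains: list[Chain] = []
    for bio_chain in model:
        chain = Chain(id=bio_chain.id.strip() or " ")
        for bio_res in bio_chain:
            hetfield, resseq, icode = bio_res.id
            is_water = hetfield == "W"
            is_het = hetfield.startswith("H_")
            if is_water and not include_waters:
                continue
            if is_het and not include_hetero:
                continue
            res = Residue(author_number=resseq, name=bio_res.resname.strip(),
                          insertion_code=icode.strip())
            for bio_atom in bio_res:
                # DisorderedAtom iteration yields the selected (highest
                # occupancy) conformer only when accessed directly
                atom = (bio_atom.selected_child
                        if bio_atom.is_disordered() else bio_atom)
                res.atoms.append(Atom(
                    name=atom.get_name(),
                    element=(atom.element or "X").strip(),
                    xyz=np.asarray(atom.coord, dtype=float),
                    is_hetero=is_het or is_water,
                    occupancy=float(atom.get_occupancy() or 1.0),
                    altloc=atom.get_altloc().strip()))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    if not chains:
        raise PDBFormatError(f"{path}: empty structure (no ATOM records kept)")
    return Structure(chains=chains)


def write_pdb(structure: Structure, path) -> None:
    """Write ATOM/HETATM records (fixed columns, coordinates to 3 decimals)."""
    serial = 1
    with open(path, "w") as fh:
        for ch in structure.chains:
            for res in ch.residues:
                for a in res.atoms:
                    rec = "HETATM" if a.is_hetero else "ATOM  "
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    fh.write(
                        f"{rec}{serial:>5d} {name}{'':1s}{res.name:>3s} {ch.id}"
                        f"{res.author_number:>4d}{res.insertion_code or ' '}   "
                        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                        f"{a.occupancy:6.2f}{0.0:6.2f}          "
                        f"{a.element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence} (nucleotide or protein)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Coding sequence
# ---------------------------------------------------------------------------

@dataclass
class CodingSequence:
    """Nucleotide coding sequence with a codon -> author-residue-number map.

    ``residue_numbers[i]`` is the author number of the residue encoded by
    codon ``i`` (0-based codon index after ``offset`` nucleotides).  Default
    mapping is 1..n_codons.
    """

    nucleotides: str
    offset: int = 0
    residue_numbers: list[int] | None = None
    allow_internal_stop: bool = False

    def __post_init__(self):
        self.nucleotides = self.nucleotides.upper()
        bad = set(self.nucleotides) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT nucleotides: {sorted(bad)}")
        if len(self.nucleotides) - self.offset < 3:
            raise ValueError("fewer than one codon after frame offset")
        n = self.n_codons
        if self.residue_numbers is None:
            self.residue_numbers = list(range(1, n + 1))
        if len(self.residue_numbers) != n:
            raise ValueError(f"residue_numbers has {len(self.residue_numbers)} entries "
                             f"for {n} codons")
        if any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise ValueError("residue_numbers must be strictly increasing")
        prot = translate(self)
        if "*" in prot[:-1] and not self.allow_internal_stop:
            raise ValueError("internal stop codon in coding sequence")

    @property
    def n_codons(self) -> int:
        return (len(self.nucleotides) - self.offset) // 3

    def codon(self, i: int) -> str:
        start = self.offset + 3 * i
        return self.nucleotides[start:start + 3]

    def codon_span(self, i: int) -> tuple[int, int]:
        """[start, end) nucleotide interval of codon i on the full sequence."""
        start = self.offset + 3 * i
        return start, start + 3


def translate(cs: CodingSequence) -> str:
    """Translate with the standard genetic code; stops render as '*'."""
    n = cs.n_codons
    coding = cs.nucleotides[cs.offset:cs.offset + 3 * n]
    return str(Seq(coding).translate())


# ---------------------------------------------------------------------------
# Mutation notation: "G107W", variants joined with "+"
# ---------------------------------------------------------------------------

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class MutationSpec:
    position: int  # author residue number
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.wt_aa not in STANDARD_AA1 or self.mut_aa not in STANDARD_AA1:
            raise ValueError(f"{self}: non-standard amino acid letter")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self.wt_aa}{self.position}{self.mut_aa}: "
                             "wild-type and mutant residues are identical")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class Variant:
    """One or more point mutations at distinct positions.

    The canonical label sorts mutations by position and joins with "+",
    e.g. ``G107W+T108H+S109V+F110A``.
    """

    mutations: frozenset[MutationSpec]

    def __post_init__(self):
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError("variant mutates the same position more than once")

    @property
    def label(self) -> str:
        return "+".join(str(m) for m in sorted(self.mutations)) or "WT"

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    @property
    def order(self) -> int:
        return len(self.mutations)

    def __str__(self) -> str:
        return self.label

    def __len__(self) -> int:
        return len(self.mutations)


def parse_mutation(text: str) -> MutationSpec:
    """Parse "G107W" -> MutationSpec(wt=G, position=107, mut=W)."""
    m = _MUT_RE.match(text.strip())
    if not m:
        raise ValueError(f"{text!r}: expected e.g. 'G107W'")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    return MutationSpec(position=pos, wt_aa=wt, mut_aa=mut)


def parse_variant(text: str) -> Variant:
    """Parse "G107W+T108H" (any order) -> canonical Variant."""
    text = text.strip()
    if text in ("", "WT"):
        return Variant(mutations=frozenset())
    return Variant(mutations=frozenset(parse_mutation(t) for t in text.split("+")))


def apply_variant(seq_map: dict[int, str], v: Variant) -> dict[int, str]:
    """Apply a variant to a {author position: 1-letter aa} map.

    Raises if the map's residue at any mutated position does not match the
    variant's stated wild type — this guards against numbering drift between
    the sequence and the structure.
    """
    out = dict(seq_map)
    for m in sorted(v.mutations):
        if m.position not in out:
            raise KeyError(f"{m}: position {m.position} absent from sequence map")
        if out[m.position] != m.wt_aa:
            raise ValueError(
                f"{m}: sequence has {out[m.position]} at position {m.position}, "
                f"not {m.wt_aa} (numbering drift?)")
        out[m.position] = m.mut_aa
    return out


def revert_variant(seq_map: dict[int, str], v: Variant) -> dict[int, str]:
    """Inverse of :func:`apply_variant`."""
    inverse = Variant(mutations=frozenset(
        MutationSpec(position=m.position, wt_aa=m.mut_aa, mut_aa=m.wt_aa)
        for m in v.mutations))
    return apply_variant(seq_map, inverse)
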