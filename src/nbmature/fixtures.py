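"""Synthetic-data generators and packaged reference tables.

Everything the pipeline consumes can be generated here at desk scale:
a toy two-chain complex with a chosen contact footprint, a coding DNA
sequence with hypermutation-hotspot motifs planted at chosen residues, and
raw score tables with planted affinity effects for end-to-end tests of the
consensus/round machinery.

The packaged tables under ``data/`` are hand transcriptions of published
reference values for an anti-CD47 nanobody campaign (site panels, a
50-entry consensus Z table, and measured K_D / T_M values); they are data,
not computed output, and are checksummed against drift.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .consensus import WT_LABEL
from .rmhdp import SiteSet
from .structio import Atom, Chain, CodingSequence, Residue, Structure, Variant

__all__ = [
    "PlantedScenario",
    "ReferenceTables",
    "gen_toy_complex",
    "gen_coding_dna",
    "gen_score_table",
    "load_reference_tables",
]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# standard genetic code, amino acid -> codons
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    _aa = _AA_ORDER[_i]
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_b1 + _b2 + _b3)

_AGY = ("AGC", "AGT")
_RGYW = tuple("".join(p) for p in itertools.product("AG", "G", "CT", "AT"))


def _motif_hits(seq: str) -> list[tuple[str, int, int]]:
    """(motif name, start, length) of every AGY/RGYW occurrence.

    Plain substring enumeration over the expanded concrete k-mers —
    independent of the scanning module, used to build fixture manifests.
    """
    hits = []
    for name, kmers in (("AGY", _AGY), ("RGYW", _RGYW)):
        k = len(kmers[0])
        for start in range(len(seq) - k + 1):
            if seq[start:start + k] in kmers:
                hits.append((name, start, k))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def _covered(seq_len: int, hits, offset: int = 0) -> set[int]:
    covered = set()
    n_codons = (seq_len - offset) // 3
    for _, start, k in hits:
        for i in range(n_codons):
            c0 = offset + 3 * i
            if c0 < start + k and start < c0 + 3:
                covered.add(i + 1)
    return covered


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

def gen_toy_complex(
    n_residues: int,
    contact_residues,
    seed: int = 0,
    sequence: dict[int, str] | None = None,
    partner_sequence: list[str] | None = None,
    pdb_path=None,
) -> Structure:
    """Two-chain Calpha/Cbeta toy complex with an exact contact footprint.

    Chain A holds ``n_residues`` residues (author numbers 1..n) strung along
    the x axis at 8 A spacing; every residue in ``contact_residues`` gets a
    chain-B partner residue placed 4.5 A away, so the 5 A interface
    criterion flags exactly the requested set while every other chain-A
    residue stays > 8 A from chain B.  Coordinates carry a small seeded
    jitter (< 0.05 A) that never threatens those margins; the contract is
    self-checked on every generation.

    ``sequence``/``partner_sequence`` assign residue identities (1-letter);
    default is alanine everywhere.  Glycines get no Cbeta.
    """
    contact = sorted(set(contact_residues))
    if contact and (contact[0] < 1 or contact[-1] > n_residues):
        raise ValueError(f"contact residues {contact} outside chain A (1..{n_residues})")
    rng = np.random.default_rng(seed)
    spacing = 8.0

    def jitter():
        return rng.uniform(-0.05, 0.05, size=3)

    def make_residue(number, aa1, origin, flip):
        name = _AA3[aa1]
        atoms = [Atom(name="CA", element="C", xyz=np.asarray(origin) + jitter())]
        if aa1 != "G":
            cb = np.asarray(origin) + np.array([0.0, 1.5 * flip, 0.0])
            atoms.append(Atom(name="CB", element="C", xyz=cb + jitter()))
        return Residue(author_number=number, name=name, atoms=atoms)

    seq = sequence or {}
    chain_a = Chain(id="A")
    for i in range(1, n_residues + 1):
        aa = seq.get(i, "A")
        # Cbeta points away from chain B so non-contact margins stay > 8 A
        chain_a.residues.append(make_residue(i, aa, (spacing * i, 0.0, 0.0), -1.0))

    chain_b = Chain(id="B")
    pseq = list(partner_sequence or [])
    for j, res in enumerate(contact, start=1):
        aa = pseq[j - 1] if j - 1 < len(pseq) else "A"
        chain_b.residues.append(
            make_residue(j, aa, (spacing * res, 4.5, 0.0), +1.0))
    # distal anchor keeps chain B non-empty for empty contact sets
    chain_b.residues.append(make_residue(len(contact) + 1, "A",
                                         (0.0, 100.0, 0.0), +1.0))
    s = Structure(chains=[chain_a, chain_b])

    from .rmhdp import interface_residues

    got = interface_residues(s, "A", "B", cutoff=5.0).residues
    if got != frozenset(contact):
        raise RuntimeError(f"toy complex violated its contact contract: "
                           f"wanted {contact}, got {sorted(got)}")
    if pdb_path is not None:
        from .structio import write_pdb

        write_pdb(s, pdb_path)
    return s


# ---------------------------------------------------------------------------
# Coding DNA with planted hotspots
# ---------------------------------------------------------------------------

def gen_coding_dna(
    protein: str,
    hotspot_positions,
    seed: int = 0,
) -> tuple[CodingSequence, dict]:
    """Coding sequence whose AGY/RGYW hits cover the requested residues.

    Serine hotspots are planted directly as AGY codons; other residues get
    an RGYW motif spanning a codon boundary, found by searching synonymous
    codon choices for the residue and a neighbour.  Non-hotspot positions
    use codons chosen (greedily, seeded) to avoid spurious motifs where
    possible.  Returns the sequence and a manifest recording the requested
    positions, the residues the scan actually covers, and any unavoidable
    extras.  Raises if a requested position cannot be planted.
    """
    protein = protein.upper()
    if any(aa not in _CODONS for aa in protein):
        raise ValueError("protein sequence contains non-standard letters")
    hotspots = sorted(set(hotspot_positions))
    if hotspots and (hotspots[0] < 1 or hotspots[-1] > len(protein)):
        raise ValueError(f"hotspot positions outside 1..{len(protein)}")
    rng = np.random.default_rng(seed)
    n = len(protein)
    fixed: dict[int, str] = {}  # 0-based codon index -> codon

    def choices(i: int) -> list[str]:
        if i in fixed:
            return [fixed[i]]
        opts = list(_CODONS[protein[i]])
        rng.shuffle(opts)
        return opts

    # plant hotspots first (left to right); serine -> aligned AGY,
    # otherwise search neighbour codon assignments for a covering RGYW
    infeasible: list[int] = []
    for pos in hotspots:
        i = pos - 1
        if protein[i] == "S" and i not in fixed:
            fixed[i] = rng.choice(_AGY)
            continue
        planted = False
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < n]
        for cur in choices(i):
            for j in neighbours:
                for nb in choices(j):
                    lo = min(i, j)
                    window = (cur + nb) if j > i else (nb + cur)
                    hits = _motif_hits(window)
                    cover = _covered(len(window), hits)
                    if (i - lo + 1) in cover:
                        fixed[i], fixed[j] = cur, nb
                        planted = True
                        break
                if planted:
                    break
            if planted:
                break
        if not planted:
            infeasible.append(pos)
    if infeasible:
        raise ValueError(f"cannot plant AGY/RGYW hotspots at positions {infeasible} "
                         f"(residues {[protein[p-1] for p in infeasible]})")

    # fill the rest, preferring codons that add no spurious coverage
    requested = set(hotspots)
    codons: list[str] = [""] * n
    for i in range(n):
        if i in fixed:
            codons[i] = fixed[i]
            continue
        best, best_extra = None, None
        for cand in choices(i):
            prefix = "".join(codons[:i]) + cand
            extra = len(_covered(len(prefix), _motif_hits(prefix)) - requested)
            if best_extra is None or extra < best_extra:
                best, best_extra = cand, extra
            if extra == 0:
                break
        codons[i] = best
    dna = "".join(codons)
    covered = _covered(len(dna), _motif_hits(dna))
    missing = requested - covered
    if missing:
        raise ValueError(f"planting failed for positions {sorted(missing)}")
    manifest = {
        "seed": seed,
        "protein": protein,
        "requested": hotspots,
        "covered": sorted(covered),
        "extra": sorted(covered - requested),
    }
    cs = CodingSequence(nucleotides=dna, allow_internal_stop=False)
    return cs, manifest


# ---------------------------------------------------------------------------
# Planted score tables
# ---------------------------------------------------------------------------

@dataclass
class PlantedScenario:
    """Ground truth for simulated scoring runs.

    ``planted_effects`` maps single-mutant labels to true binding ddG
    (kcal/mol, negative = improved); multi-point variants are additive over
    their component singles unless an ``epistasis`` term is given for a
    specific combination.  Each scorer reports
    ``baseline + scale * ddG_true + N(0, sd)``.
    """

    seed: int = 0
    planted_effects: dict[str, float] = field(default_factory=dict)
    scorers: tuple[tuple[str, float, float, float], ...] = (
        # name, baseline, scale, noise sd (score units)
        ("scorerA", -20.0, 1.0, 0.25),
        ("scorerB", 5.0, 2.0, 0.50),
        ("scorerC", 0.0, 1.5, 0.40),
    )
    #: sd (kcal/mol) of the ddG *estimates* fed to the round engine — the
    #: run-to-run consistency of a consensus over several scorers, which is
    #: much tighter than any single scorer's absolute accuracy.
    ddg_noise_sd: float = 0.12
    epistasis: dict[frozenset, float] = field(default_factory=dict)

    #: the six-site panel and its wild-type identities used by the standard
    #: campaign scenario
    CAMPAIGN_SITES = {55: "S", 58: "V", 107: "G", 108: "T", 109: "S", 110: "F"}

    @classmethod
    def default_campaign(cls, seed: int = 0) -> "PlantedScenario":
        """The standard planted-signal scenario for end-to-end tests.

        Four beneficial singles — the components of a known quadruple
        winner — with effects in the 9- to 22-fold range typical of kept
        round-1 singles (ddG -1.30 to -1.82 kcal/mol); everything else is
        neutral.  Multi-point effects are additive.
        """
        return cls(seed=seed, planted_effects={
            "G107W": -1.55, "T108H": -1.40, "S109V": -1.82, "F110A": -1.30})

    @classmethod
    def zero_signal(cls, seed: int = 0) -> "PlantedScenario":
        """Pure-noise scenario: no variant has any true effect."""
        return cls(seed=seed, planted_effects={})

    def true_ddg(self, v: Variant) -> float:
        total = sum(self.planted_effects.get(str(m), 0.0) for m in v.mutations)
        key = frozenset(str(m) for m in v.mutations)
        return total + self.epistasis.get(key, 0.0)

    def ddg_estimator(self, noise_sd: float | None = None, seed: int | None = None):
        """Callable variant -> estimated ddG with optional Gaussian error.

        The error is drawn once per variant label and cached, so repeated
        queries are consistent within a run.
        """
        if noise_sd is None:
            noise_sd = self.ddg_noise_sd
        rng = np.random.default_rng(self.seed if seed is None else seed)
        cache: dict[str, float] = {}

        def estimate(v: Variant) -> float:
            lab = v.label
            if lab not in cache:
                err = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                cache[lab] = self.true_ddg(v) + err
            return cache[lab]

        return estimate


def gen_score_table(variants, scenario: PlantedScenario,
                    include_wt: bool = True) -> pd.DataFrame:
    """Raw score matrix (variants x scorers) under a planted scenario.

    Deterministic under the scenario seed; lower score = better predicted
    binding, consistent with the consensus module's sign convention.
    """
    rng = np.random.default_rng(scenario.seed)
    from .structio import parse_variant

    vs = [v if isinstance(v, Variant) else parse_variant(str(v)) for v in variants]
    labels = [v.label for v in vs]
    rows = list(labels) + ([WT_LABEL] if include_wt and WT_LABEL not in labels else [])
    data = {}
    ddgs = {lab: scenario.true_ddg(v) for v, lab in zip(vs, labels)}
    ddgs[WT_LABEL] = 0.0
    for name, baseline, scale, sd in scenario.scorers:
        col = [baseline + scale * ddgs[lab] + rng.normal(0.0, sd) for lab in rows]
        data[name] = col
    return pd.DataFrame(data, index=pd.Index(rows, name="variant"))


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTables:
    interface: SiteSet
    hotspot: SiteSet
    consensus_z: pd.DataFrame  # columns: position, wt, mut, z (long form)
    kd_tm: pd.DataFrame  # index M0..M7: label, kd_nM, kd_err_nM, tm_C
    fold_calculated: pd.DataFrame  # sparse published fold values
    reference_z: float  # parent clone's own consensus Z


def _read_packaged(name: str) -> str:
    return resources.files("nbmature.data").joinpath(name).read_text()


def load_reference_tables() -> ReferenceTables:
    """Load the transcribed published tables, verifying checksums.

    The site panels come from a two-criteria binding-site analysis
    (interface residues within 5 A; AGY/RGYW hotspot residues), the
    consensus-Z table lists the 50 negative-Z single mutants, and the
    K_D / T_M table carries the measured values for the parent (M0) and
    seven multi-point mutants (M1..M7).
    """
    sums = json.loads(_read_packaged("checksums.json"))
    texts = {}
    for name, expected in sums.items():
        text = _read_packaged(name)
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != expected:
            raise ValueError(f"packaged table {name} checksum mismatch "
                             f"(expected {expected[:12]}..., got {digest[:12]}...)")
        texts[name] = text

    import io

    def read(name, **kw):
        return pd.read_csv(io.StringIO(texts[name]), sep="\t", comment="#", **kw)

    sites = read("table1_sites.tsv", dtype={"residues": str})
    sets = {}
    for criterion in ("interface", "hotspot"):
        sub = sites[sites["criterion"] == criterion]
        residues: set[int] = set()
        aa: dict[int, str] = {}
        from .rmhdp import expand_ranges

        for _, row in sub.iterrows():
            nums = expand_ranges(str(row["residues"]))
            residues |= nums
            if isinstance(row["aa"], str) and row["aa"] != "-" and len(nums) == 1:
                aa[next(iter(nums))] = row["aa"]
        sets[criterion] = SiteSet(residues=frozenset(residues),
                                  provenance=criterion, aa_names=aa)

    ztab = read("table2_consensus_z.tsv")
    kd_tm = read("kd_tm.tsv", index_col=0)
    folds = read("fig3_folds.tsv")
    return ReferenceTables(interface=sets["interface"], hotspot=sets["hotspot"],
                       consensus_z=ztab, kd_tm=kd_tm, fold_calculated=folds,
                       reference_z=-0.20)
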