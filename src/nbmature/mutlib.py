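"""Mutant library enumeration.

Single-point scanning mutagenesis at a nominated site panel, with the
standard nanobody-engineering exclusions: cysteine and proline are never
introduced (C to protect the conserved C24-C99 disulfide, P for backbone
geometry), and positions holding structural cysteines are never touched.
Each eligible site therefore yields 17 mutants (20 - {C, P} - wild type);
six sites give 6 x 17 = 102 single-point variants.

Multi-point variants are k-subsets of kept singles with pairwise-distinct
positions, in deterministic order so downstream ranks are reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .rmhdp import SiteSet
from .structio import STANDARD_AA1, MutationSpec, Variant

__all__ = ["MutagenesisPolicy", "enumerate_single_mutants", "combine_variants"]

log = logging.getLogger(__name__)


@dataclass
class MutagenesisPolicy:
    """What may be mutated and to what.

    ``excluded_target_aas`` are never introduced; ``protected_positions``
    are skipped entirely (with a logged reason).  When
    ``protect_cysteines`` is set, every wild-type C position is protected
    automatically — the disulfide is a hallmark of the nanobody fold.
    """

    sites: SiteSet
    excluded_target_aas: frozenset[str] = frozenset({"C", "P"})
    protected_positions: frozenset[int] = frozenset()
    protect_cysteines: bool = True

    def __post_init__(self):
        self.excluded_target_aas = frozenset(self.excluded_target_aas)
        self.protected_positions = frozenset(self.protected_positions)


def enumerate_single_mutants(wt_sequence: dict[int, str],
                             policy: MutagenesisPolicy) -> list[Variant]:
    """All single-point mutants at the policy's sites.

    ``wt_sequence`` maps author residue numbers to 1-letter codes.  Output
    order is position ascending, then mutant amino acid alphabetical.
    Skipped sites (absent, protected, cysteine, or wild type already in the
    excluded set) are logged, never silently dropped.
    """
    variants: list[Variant] = []
    for pos in sorted(policy.sites.residues):
        if pos not in wt_sequence:
            raise KeyError(f"site {pos} absent from wild-type sequence map")
        wt = wt_sequence[pos]
        if pos in policy.protected_positions:
            log.warning("site %d (%s) skipped: protected position", pos, wt)
            continue
        if policy.protect_cysteines and wt == "C":
            log.warning("site %d skipped: wild-type cysteine (disulfide guard)", pos)
            continue
        if wt in policy.excluded_target_aas:
            log.warning("site %d skipped: wild type %s is in the excluded set", pos, wt)
            continue
        for mut in sorted(STANDARD_AA1 - policy.excluded_target_aas - {wt}):
            variants.append(Variant(mutations=frozenset(
                [MutationSpec(position=pos, wt_aa=wt, mut_aa=mut)])))
    return variants


def combine_variants(singles: list[Variant], k: int) -> list[Variant]:
    """All k-subsets of single-point variants with pairwise-distinct positions.

    Returns canonically labelled variants without duplicates, sorted by
    label.  ``k`` larger than the number of distinct positions yields an
    empty list (not an error).
    """
    if k < 2:
        raise ValueError("combination order k must be >= 2")
    for v in singles:
        if v.order != 1:
            raise ValueError(f"{v.label}: combine_variants takes single-point inputs")
    seen: set[frozenset] = set()
    out: list[Variant] = []
    for combo in itertools.combinations(singles, k):
        positions = [next(iter(v.mutations)).position for v in combo]
        if len(set(positions)) != k:
            continue
        mutations = frozenset(m for v in combo for m in v.mutations)
        if mutations in seen:
            continue
        seen.add(mutations)
        out.append(Variant(mutations=mutations))
    out.sort(key=lambda v: v.label)
    return out
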