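"""Robust Z-scores and consensus ranking over pluggable scoring functions.

External structure-based scorers (SIE-type, FoldX-type, Rosetta-type energy
functions) are consumed as a table of raw per-variant scores, one column per
scorer, lower = stronger predicted binding.  Each column is standardised
with a robust Z-score

    Z_i = (s_i - median(s)) / (1.4826 * MAD(s))

(1.4826 makes the MAD a consistent estimator of the standard deviation
under normality), and the consensus is the arithmetic mean of per-scorer
Z-scores.  More-negative consensus Z = predicted-better binder.

A deliberately simple residue-contact scorer is included so that the whole
pipeline can run at desk scale without any external software; it makes no
claim to the accuracy of the force-field scorers it stands in for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import Structure, Variant

__all__ = [
    "WT_LABEL",
    "ConsensusResult",
    "robust_z",
    "consensus_z",
    "select_top",
    "toy_contact_score",
    "HYDROPHOBICITY",
    "FORMAL_CHARGE",
]

log = logging.getLogger(__name__)

WT_LABEL = "WT"

#: Kyte-Doolittle hydropathy rescaled to [0, 1] (1 = most hydrophobic).
HYDROPHOBICITY = {
    "I": 1.000, "V": 0.967, "L": 0.922, "F": 0.811, "C": 0.778, "M": 0.711,
    "A": 0.700, "G": 0.456, "T": 0.422, "S": 0.411, "W": 0.400, "Y": 0.356,
    "P": 0.322, "H": 0.144, "E": 0.111, "Q": 0.111, "D": 0.111, "N": 0.111,
    "K": 0.067, "R": 0.000,
}

#: Formal side-chain charges at neutral pH (His neutral).
FORMAL_CHARGE = {aa: 0 for aa in HYDROPHOBICITY}
FORMAL_CHARGE.update({"D": -1, "E": -1, "K": +1, "R": +1})


def robust_z(scores, mad_scale: float = 1.4826) -> np.ndarray:
    """Median/MAD standardisation of one scorer's raw-score column.

    Degenerate fallbacks: MAD = 0 -> sample standard deviation; that also
    0 -> all zeros (a constant column carries no ranking information).
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("robust_z needs a 1-D column of >= 2 values")
    if not np.all(np.isfinite(s)):
        raise ValueError("robust_z: non-finite raw scores")
    med = np.median(s)
    mad = np.median(np.abs(s - med))
    scale = mad_scale * mad
    if scale == 0:
        scale = s.std(ddof=1)
    if scale == 0:
        return np.zeros_like(s)
    return (s - med) / scale


@dataclass
class ConsensusResult:
    """Per-scorer Z-scores, their consensus, and the resulting rank."""

    z: pd.DataFrame  # index = variant labels, columns = scorers
    consensus: pd.Series  # mean Z per variant, index = variant labels
    ranked: pd.DataFrame  # columns: consensus_z, rank (1 = most negative)

    def top_labels(self, n: int) -> list[str]:
        return list(self.ranked.index[:n])


def consensus_z(score_matrix: pd.DataFrame) -> ConsensusResult:
    """Consensus Z-ranking of a raw-score table.

    ``score_matrix``: index = variant labels (a "WT" reference row is
    allowed and is standardised with the rest), columns = scorer names,
    cells = raw scores with lower = better predicted binding.  Ties in the
    consensus are broken by variant label for determinism.
    """
    if score_matrix.shape[1] < 1:
        raise ValueError("score matrix needs at least one scorer column")
    bad = score_matrix.index[score_matrix.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing scores for variants: {list(bad)}")
    z = pd.DataFrame(
        {col: robust_z(score_matrix[col].to_numpy()) for col in score_matrix.columns},
        index=score_matrix.index,
    )
    consensus = z.mean(axis=1)
    order = sorted(consensus.index, key=lambda lab: (consensus[lab], lab))
    ranked = pd.DataFrame({
        "consensus_z": consensus.loc[order],
        "rank": np.arange(1, len(order) + 1),
    })
    return ConsensusResult(z=z, consensus=consensus, ranked=ranked)


def select_top(
    result: ConsensusResult,
    n: int = 50,
    max_z: float = 0.0,
    per_site_cap: int | None = None,
    exclude_wt: bool = True,
) -> list[str]:
    """Shortlist variant labels: consensus Z strictly below ``max_z``,
    ranked, truncated to ``n``, then optionally capped per position.

    The per-position cap keeps the most-negative entries at each mutated
    position — a deterministic stand-in for the manual "site diversity"
    sub-selection step of interactive campaigns.
    """
    from .structio import parse_variant

    labels = [lab for lab in result.ranked.index
              if result.ranked.loc[lab, "consensus_z"] < max_z]
    if exclude_wt:
        labels = [lab for lab in labels if lab != WT_LABEL]
    labels = labels[:n]
    if per_site_cap is not None:
        counts: dict[int, int] = {}
        capped = []
        for lab in labels:
            positions = parse_variant(lab).positions
            if any(counts.get(p, 0) >= per_site_cap for p in positions):
                continue
            for p in positions:
                counts[p] = counts.get(p, 0) + 1
            capped.append(lab)
        labels = capped
    return labels


# ---------------------------------------------------------------------------
# Toy contact scorer
# ---------------------------------------------------------------------------

def _representative_point(residue) -> np.ndarray | None:
    """Cbeta coordinate, or Calpha for glycine / Cbeta-less residues."""
    cb = residue.atom("CB")
    if cb is not None:
        return cb.xyz
    ca = residue.atom("CA")
    return ca.xyz if ca is not None else None


def toy_contact_score(
    s: Structure,
    v: Variant,
    antibody_chain: str,
    antigen_chain: str,
    contact_cutoff: float = 8.0,
    w_hydrophobic: float = 1.0,
    w_charge: float = 2.0,
) -> float:
    """Pairwise-contact pseudo-energy of the complex under a variant.

    E = sum over cross-chain residue pairs whose representative points
    (Cbeta, Calpha for Gly) lie within ``contact_cutoff`` of

        eps(a, b) = -h(a) * h(b) * w_hydrophobic + q(a) * q(b) * w_charge

    with normalised hydrophobicities ``h`` and formal charges ``q``.  Lower
    is better (favourable hydrophobic packing and opposite charges are
    negative).  The mutation changes residue identities only; the geometry
    stays frozen at the input structure.  Variant positions that are not in
    contact with the antigen leave the score unchanged (logged).
    """
    ab = s.chain(antibody_chain)
    ag = s.chain(antigen_chain)
    identity = {r.author_number: r.aa1 for r in ab.residues if r.aa1}
    for m in v.mutations:
        if m.position not in identity:
            raise KeyError(f"{m}: position {m.position} not on chain {antibody_chain}")
        if identity[m.position] != m.wt_aa:
            raise ValueError(f"{m}: chain {antibody_chain} has "
                             f"{identity[m.position]} at {m.position}")
        identity[m.position] = m.mut_aa

    contact_positions: set[int] = set()
    energy = 0.0
    for res_a in ab.residues:
        a_aa = identity.get(res_a.author_number)
        pa = _representative_point(res_a)
        if a_aa is None or pa is None:
            continue
        for res_b in ag.residues:
            b_aa = res_b.aa1
            pb = _representative_point(res_b)
            if b_aa is None or pb is None:
                continue
            if np.linalg.norm(pa - pb) <= contact_cutoff:
                contact_positions.add(res_a.author_number)
                energy += (-HYDROPHOBICITY[a_aa] * HYDROPHOBICITY[b_aa] * w_hydrophobic
                           + FORMAL_CHARGE[a_aa] * FORMAL_CHARGE[b_aa] * w_charge)
    for m in v.mutations:
        if m.position not in contact_positions:
            log.info("toy_contact_score: %s is outside the %0.1f A contact shell; "
                     "score unchanged from WT at that site", m, contact_cutoff)
    return energy
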