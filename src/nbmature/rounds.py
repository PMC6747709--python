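"""Multi-round affinity-maturation engine.

Round 1 evaluates single-point mutants; variants whose predicted affinity
improvement (fold change in K_D relative to the parent) meets the
carry-forward threshold — five-fold by default — seed the next round, where
kept components are combined into doubles, then triples, then quadruples,
up to a configurable maximum order.  Manual campaign steps have
deterministic counterparts: forced inclusions (``include_overrides``) and a
component-drop heuristic that retires a single whose combinations mostly
fail.

Fold changes interconvert with binding free-energy differences through

    fold = K_D(wt) / K_D(mut) = exp(-ddG / RT)

with R = 1.987e-3 kcal/(mol K), so ddG = -RT ln(fold); negative ddG means
improved binding.  At 298.15 K, RT ln(10) = 1.364 kcal/mol per 10-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .mutlib import combine_variants
from .structio import Variant, parse_variant

__all__ = [
    "R_KCAL",
    "AffinityEstimate",
    "RoundConfig",
    "RoundResult",
    "fold_from_ddg",
    "ddg_from_fold",
    "kd_cal_from_ddg",
    "fold_from_kds",
    "run_round",
    "maturation_pipeline",
]

R_KCAL = 1.987e-3  # gas constant, kcal/(mol K)


def fold_from_ddg(ddg_kcal: float, temperature_K: float = 298.15) -> float:
    """K_D fold improvement implied by a binding ddG (mut - wt, kcal/mol)."""
    if not math.isfinite(ddg_kcal):
        raise ValueError("ddG must be finite")
    return math.exp(-ddg_kcal / (R_KCAL * temperature_K))


def ddg_from_fold(fold: float, temperature_K: float = 298.15) -> float:
    """Inverse of :func:`fold_from_ddg`."""
    if fold <= 0:
        raise ValueError("fold improvement must be positive")
    return -R_KCAL * temperature_K * math.log(fold)


def kd_cal_from_ddg(kd_wt_nM: float, ddg_kcal: float,
                    temperature_K: float = 298.15) -> float:
    """Predicted mutant K_D (nM) from the parent K_D and a binding ddG."""
    if kd_wt_nM <= 0:
        raise ValueError("parent K_D must be positive")
    return kd_wt_nM / fold_from_ddg(ddg_kcal, temperature_K)


def fold_from_kds(kd_wt_nM: float, kd_mut_nM: float) -> float:
    """Measured fold improvement K_D(wt) / K_D(mut); > 1 means improved."""
    if kd_wt_nM <= 0 or kd_mut_nM <= 0:
        raise ValueError("K_D values must be positive")
    return kd_wt_nM / kd_mut_nM


@dataclass(frozen=True)
class AffinityEstimate:
    """Predicted affinity change of one variant relative to the parent."""

    label: str
    ddg_kcal: float
    kd_wt_nM: float | None = None
    temperature_K: float = 298.15

    @property
    def fold_improvement(self) -> float:
        return fold_from_ddg(self.ddg_kcal, self.temperature_K)

    @property
    def kd_cal_nM(self) -> float | None:
        if self.kd_wt_nM is None:
            return None
        return self.kd_wt_nM / self.fold_improvement


@dataclass
class RoundConfig:
    carry_forward_fold: float = 5.0  # keep variants at or above this fold
    discard_fold: float = 1.0  # combinations below this count against components
    max_order: int = 4  # stop after quadruples
    include_overrides: frozenset[str] = frozenset()  # labels always carried forward
    drop_rule_fraction: float = 0.5  # fraction of failing combos that retires a single

    def __post_init__(self):
        if self.carry_forward_fold <= 0 or self.discard_fold <= 0:
            raise ValueError("fold thresholds must be positive")
        if self.max_order < 2:
            raise ValueError("max_order must be >= 2")
        self.include_overrides = frozenset(self.include_overrides)


@dataclass
class RoundResult:
    round_index: int
    evaluated: dict[str, AffinityEstimate]
    kept: list[str]
    discarded: dict[str, str]  # label -> reason
    dropped_components: list[str]  # singles retired from future combinations
    next_round_plan: list[Variant]

    def audit(self) -> list[dict]:
        log = []
        for label, est in self.evaluated.items():
            entry = {"round": self.round_index, "variant": label,
                     "fold": est.fold_improvement, "ddg_kcal": est.ddg_kcal}
            entry["decision"] = "kept" if label in self.kept else "discarded"
            if label in self.discarded:
                entry["reason"] = self.discarded[label]
            log.append(entry)
        return log


def run_round(
    candidates: dict[str, AffinityEstimate],
    cfg: RoundConfig,
    round_index: int = 1,
    component_singles: list[str] | None = None,
) -> RoundResult:
    """Apply keep/discard rules to one round of evaluated variants.

    kept = fold >= carry_forward_fold, plus any evaluated override labels.
    Discard reasons: ``decreased`` (fold < discard_fold, i.e. worse than the
    parent) or ``below_threshold``.  From round 2 on, a component single is
    dropped from future combinations when at least ``drop_rule_fraction`` of
    its evaluated combinations come out below ``discard_fold``; the next
    round's plan combines the surviving component singles at order
    ``round_index + 1`` (empty once past ``max_order``).
    """
    kept, discarded = [], {}
    for label in sorted(candidates):
        fold = candidates[label].fold_improvement
        if fold >= cfg.carry_forward_fold or label in cfg.include_overrides:
            kept.append(label)
        elif fold < cfg.discard_fold:
            discarded[label] = "decreased"
        else:
            discarded[label] = "below_threshold"

    # retire components whose combinations mostly fail
    dropped: list[str] = []
    if round_index >= 2 and component_singles:
        for single in component_singles:
            containing = [lab for lab in candidates
                          if single in lab.split("+") and "+" in lab]
            if not containing:
                continue
            failing = [lab for lab in containing
                       if candidates[lab].fold_improvement < cfg.discard_fold]
            if len(failing) / len(containing) >= cfg.drop_rule_fraction:
                dropped.append(single)

    # components surviving into the next order of combinations
    if round_index == 1:
        pool = kept
    else:
        pool = [s for s in (component_singles or []) if s not in dropped]
        # only components that appear in at least one kept combination stay live
        kept_components = {m for lab in kept for m in lab.split("+")}
        pool = [s for s in pool if s in kept_components] or []
    next_order = round_index + 1
    plan: list[Variant] = []
    if next_order <= cfg.max_order and len(pool) >= next_order:
        singles = [parse_variant(lab) for lab in pool]
        plan = combine_variants(singles, next_order)
    return RoundResult(round_index=round_index, evaluated=dict(candidates),
                       kept=kept, discarded=discarded,
                       dropped_components=dropped, next_round_plan=plan)


def maturation_pipeline(
    wt_sequence: dict[int, str],
    sites,
    score_fn,
    ddg_fn,
    cfg: RoundConfig | None = None,
    top_n: int = 50,
    max_z: float = 0.0,
    per_site_cap: int | None = None,
    n_scorers_hint: int | None = None,
) -> list[RoundResult]:
    """End-to-end deterministic campaign: enumerate -> score -> consensus ->
    select -> iterate rounds of combination up to ``cfg.max_order``.

    ``score_fn(variants) -> pandas.DataFrame`` returns the raw score matrix
    (variant labels x scorers, lower = better) used for consensus shortlisting
    of round-1 singles; ``ddg_fn(variant) -> float`` supplies the binding
    ddG (kcal/mol) used for fold thresholds in every round — in a real
    campaign both would come from external structure-based scoring runs.
    """
    from .consensus import consensus_z, select_top
    from .mutlib import MutagenesisPolicy, enumerate_single_mutants

    cfg = cfg or RoundConfig()
    policy = MutagenesisPolicy(sites=sites)
    singles = enumerate_single_mutants(wt_sequence, policy)
    if not singles:
        return []
    try:
        matrix = score_fn(singles)
        cr = consensus_z(matrix)
        shortlist = select_top(cr, n=top_n, max_z=max_z, per_site_cap=per_site_cap)
    except Exception as exc:
        raise RuntimeError(f"consensus stage failed: {exc}") from exc
    shortlist_variants = [parse_variant(lab) for lab in shortlist]

    results: list[RoundResult] = []
    try:
        estimates = {v.label: AffinityEstimate(label=v.label, ddg_kcal=ddg_fn(v))
                     for v in shortlist_variants}
    except Exception as exc:
        raise RuntimeError(f"round 1 affinity stage failed: {exc}") from exc
    r1 = run_round(estimates, cfg, round_index=1)
    results.append(r1)
    component_singles = list(r1.kept)
    plan = r1.next_round_plan
    round_index = 2
    while plan and round_index <= cfg.max_order:
        estimates = {v.label: AffinityEstimate(label=v.label, ddg_kcal=ddg_fn(v))
                     for v in plan}
        rr = run_round(estimates, cfg, round_index=round_index,
                       component_singles=component_singles)
        results.append(rr)
        plan = rr.next_round_plan
        component_singles = [s for s in component_singles
                             if s not in rr.dropped_components]
        round_index += 1
    return results
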