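# nbmature

In silico affinity maturation for nanobodies (VHHs): a Python toolkit for
the computational half of a structure-guided antibody-engineering campaign,
from mutation-site nomination through multi-round mutant selection to
fitting the wet-lab validation assays.

## The problem

A nanobody pulled from a display library often binds its antigen too weakly
for therapeutic use (hundreds of nM). Affinity maturation fixes this by
mutating a handful of binding-site residues and keeping the combinations
that improve the equilibrium dissociation constant K_D. Doing this in
silico requires four pieces of machinery, all provided here:

1. **Site nomination.** Mutations are worth making where two independent
   criteria agree: the residue sits at the antibody-antigen interface
   (any heavy atom within 5 Å of the partner chain), and its codon lies
   under a somatic-hypermutation hotspot motif on the coding DNA — AGY or
   RGYW (R = A/G, Y = C/T, W = A/T). The intersection of the two sets is
   the mutation panel. A motif that spans a codon boundary marks every
   residue it overlaps, which is how non-serine residues end up on the
   hotspot list.
2. **Library enumeration.** Each panel site is mutated to the 17 allowed
   residues (cysteine and proline are never introduced; cysteine positions
   are never touched, protecting the conserved VHH disulfide). Kept singles
   are combined into doubles, triples and quadruples with pairwise-distinct
   positions.
3. **Consensus ranking and rounds.** Raw scores from any set of scoring
   functions (lower = better binding) are standardised per scorer with a
   robust Z-score, Z = (s − median) / (1.4826 · MAD), and averaged; the
   negative-Z shortlist advances. Variants whose predicted fold improvement
   K_D(wt)/K_D(mut) = exp(−ΔΔG/RT) meets a five-fold threshold seed the
   next round of combinations.
4. **Validation numerics.** SPR sensorgrams are fit globally with the 1:1
   Langmuir model (shared ka, kd, Rmax across analyte concentrations;
   K_D = kd/ka), and melting temperatures are read from the derivative
   extremum of smoothed thermal-shift curves; ΔT_M reports the stability
   change.

External force-field scorers are consumed as score tables, not
re-implemented; a simple built-in contact scorer lets the whole pipeline
run at desk scale. Synthetic-data generators (toy complexes with exact
contact footprints, coding DNA with planted hotspot motifs, score tables
with planted effects) make every stage testable offline.

## Worked example

```bash
python examples/04_maturation_campaign.py
```

```
round 1: evaluated 50, kept  4, best S109V (21.0-fold)
round 2: evaluated  6, kept  6, best G107W+S109V (377.4-fold)
round 3: evaluated  4, kept  4, best G107W+T108H+S109V (3989.9-fold)
round 4: evaluated  1, kept  1, best G107W+T108H+S109V+F110A (30774.5-fold)
final variant: G107W+T108H+S109V+F110A
```

Round 1 scores the 102 single mutants of the six-site panel, shortlists
the negative consensus-Z set, and keeps the four variants with ≥ 5-fold
predicted improvement; rounds 2–4 combine survivors into ever-higher-order
variants until the planted quadruple wins. The fold numbers are
exp(−ΔΔG/RT) for the additive planted effects plus estimation noise.

The other scripts in `examples/` each demonstrate one capability (site
nomination, library enumeration, consensus ranking, SPR fitting, T_M
extraction, interaction classification) and print the numbers they
compute alongside the ground truth used to generate the inputs.

There is also a thin CLI: `nbmature hotspots|scan|consensus|rounds|
interactions|fit-spr|fit-melt|simulate` — each subcommand is file plumbing
over one library call.

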