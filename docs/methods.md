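# Methods

This note records the models, conventions and numerical choices behind
`nbmature`, and what its synthetic-data tests do and do not demonstrate.

## Residue identity and notation

All user-facing residue positions are PDB *author* numbers (integer plus
optional insertion code) — the numbers an antibody engineer quotes (S55,
G107) — never sequential indices; internal arrays are 0-based. The
numbering scheme itself (Kabat, IMGT, sequential) is treated as opaque:
the toolkit intersects and mutates whatever numbers the inputs carry.
Variants use the `G107W+T108H` micro-format; the canonical label sorts
mutations by position, and parsing/formatting is a bijection on canonical
labels. `apply_variant` refuses a mutation whose stated wild type
disagrees with the sequence, which catches numbering drift between
sequence and structure early.

PDB reading is delegated to Bio.PDB in strict mode behind `read_pdb`;
waters and HETATM records are excluded by default (the distance criteria
are protein–protein only), only MODEL 1 of multi-model files is read, and
for disordered atoms the highest-occupancy conformer is kept with ties
going to the first altloc in the file, so reads are deterministic.

## Site nomination

Two criteria, each with one tunable:

- **Interface**: a query-chain residue is an interface residue when the
  minimum heavy-atom distance to the partner chain is ≤ 5.0 Å (cutoff
  configurable). Hydrogens are ignored because the input structures are
  typically models with unreliable proton placement. Implementation uses a
  k-d tree; the test oracle is an all-pairs distance loop.
- **Hotspots**: every occurrence of AGY (2 concrete 3-mers) and RGYW
  (8 concrete 4-mers) on the forward strand of the coding sequence. A hit
  covers every residue whose codon it overlaps; this boundary-spanning
  rule is what places non-serine residues (e.g. V, T, F) on hotspot
  lists. Somatic hypermutation hotspots are strand-specific, so the
  forward strand is the default; a flag adds the reverse-complement (WRCY
  mirror) scan.

The mutation panel is the exact set intersection. Interface ranges
(e.g. "105-113" in tabulated inputs) are expanded before intersecting.

## Mutant library

Single mutants: per eligible site, one variant per amino acid in
(20 standard − {C, P} − wild type) = 17, ordered by position then mutant
letter so downstream ranks are reproducible. Cysteine is excluded as a
target *and* protected as a wild type at any site (the C22–C96-type
disulfide is a hallmark of the VHH fold); proline is excluded for backbone
geometry. Skips are logged, never silent. Combinations of order k are the
k-subsets of singles with pairwise-distinct positions. Note that seven
singles spanning five positions give 19 position-distinct doubles
(C(7,2) = 21 minus two same-position pairs); accounts that quote 20 for
this configuration include a same-position pair or an extra single — the
toolkit implements the distinct-position rule and documents the
discrepancy rather than reproducing the larger count.

## Consensus scoring

Per scorer column, Z = (s − median) / (1.4826 · MAD); 1.4826 makes the
MAD a consistent estimator of σ under normality. Degenerate fallbacks:
MAD = 0 → sample standard deviation; that also 0 → all zeros (a constant
column carries no ranking information, and degenerate simulated inputs
must not crash). The consensus is the arithmetic mean of per-scorer Z,
ties broken by variant label. The convention throughout is lower raw
score = better predicted binding, so negative consensus Z marks predicted
improvers. Both per-column Z and the consensus ranking are invariant
under independent positive affine transforms of each scorer — a property
test, because it is what makes mixing heterogeneous energy functions
meaningful.

Interactive campaigns typically apply a manual "site diversity" pruning
to the shortlist; the deterministic counterpart here is `per_site_cap`:
after thresholding (Z < 0) and truncation (top n), at most k variants per
mutated position survive, most-negative first. The manual step's exact
output is irreproducible by construction, so no test asserts a particular
pruned set.

The built-in contact scorer is a deliberately simple stand-in for external
force fields: cross-chain residue pairs whose representative points (Cβ,
Cα for glycine) lie within 8 Å contribute
ε = −h·h′·w_h + q·q′·w_q (normalised Kyte–Doolittle hydrophobicities h,
formal charges q, weights 1.0 and 2.0). Mutations change identities only;
geometry stays frozen. It is deterministic, additive over independent
contacts, and makes no claim of accuracy.

## Rounds and the ΔΔG ↔ K_D bridge

fold = K_D(wt)/K_D(mut) = exp(−ΔΔG/RT) with R = 1.987×10⁻³ kcal/(mol·K),
T = 298.15 K by default (RT·ln 10 ≈ 1.364 kcal/mol per decade). The round
engine keeps variants with fold ≥ 5 (configurable), discards the rest with
a machine-readable reason (`decreased` below fold 1, else
`below_threshold`), and plans the next round as order-(k+1) combinations
of surviving components, stopping at order 4. Two manual campaign steps
have deterministic counterparts: forced inclusions
(`include_overrides`, e.g. retaining a marginal but structurally
interesting single), and a component-drop rule — from round 2 on, a single
is retired when at least half (configurable fraction) of its evaluated
combinations fall below the discard fold. Computed K_D^cal values come
from the thermodynamic conversion rather than external webserver calls,
which keeps the pipeline self-contained; externally computed fold columns
are accepted wherever folds are consumed.

## Interaction classification

Distance-only criteria with literature-standard cutoffs (all
configurable): salt bridge 4.0 Å (side-chain N of K/R vs carboxylate O of
D/E), hydrogen bond 3.5 Å (any N/O pair), cation-π 6.0 Å (charged-group
atom to aromatic ring centroid), aromatic-aromatic 7.0 Å
(centroid–centroid), hydrophobic 4.5 Å (side-chain carbons of apolar
residues). Histidine counts as aromatic but not charged by default (flag
to flip). Angular terms are deliberately omitted: the intended inputs are
models whose hydrogen positions and side-chain orientations do not
support angle thresholds; distance-only criteria are also what published
interface analyses of this kind report. Residues with incomplete side
chains (modeling artifacts) are skipped with a warning.

## Assay numerics

**SPR.** The 1:1 Langmuir model: association
R(t) = Req·(1 − e^(−(ka·C+kd)·t)) with Req = ka·C·Rmax/(ka·C+kd),
dissociation R(t) = R(t_a)·e^(−kd·(t−t_a)). Fitting is global across all
concentrations sharing (ka, kd, Rmax), the standard Biacore practice;
per-curve fits follow from passing single-trace sensorgrams (with a
warning, since ka and Rmax are then strongly correlated). Parameters vary
on log10 scale (positive by construction) with three log-spaced starts
(ka from 1e3 to 1e7 M⁻¹s⁻¹, kd from 1e-5 to 1e-1 s⁻¹) and best-χ²
selection, making the result deterministic for given data. χ² is the
per-point residual variance Σr²/(N−p); its absolute scale depends on the
instrument noise and is reported but not asserted against any reference.

**Thermal shift.** Fluorescence is smoothed with a 5-point quadratic
Savitzky–Golay window (default chosen for the canonical 1 °C grid) and
T_M is the grid-refined extremum of dF/dT, excluding the half-window at
each edge where the filter is one-sided. Dye-binding unfolding curves
rise through the transition (peak in +dF/dT) while instruments often
display −dF/dT; the sign is auto-detected from the overall trend and can
be forced. A curve whose derivative peak does not stand out from the bulk
of the derivative (robust z ≥ 6, median/MAD) raises "no transition
detected". Both the detection criterion and T_M itself are invariant
under positive affine transforms of the fluorescence. Aggregation at high
temperature is not modeled.

## Synthetic data: what it emulates, what it does not

- `gen_toy_complex` builds two Cα/Cβ chains where exactly the requested
  residues have a heavy atom within 5 Å of the partner and all others are
  beyond 8 Å (seeded jitter < 0.05 Å never threatens the margins; the
  contract is self-checked on every generation). It emulates a contact
  *footprint*, not protein geometry: no packing, no side chains, no
  realistic interface shape.
- `gen_coding_dna` plants AGY codons at serine hotspots and
  boundary-spanning RGYW motifs elsewhere by searching synonymous codon
  choices of the residue and a neighbour; remaining positions greedily
  avoid spurious motifs. Planting is not always exact — boundary-spanning
  motifs unavoidably cover neighbours — so the manifest records the
  residues actually covered (computed with a naive substring enumeration
  independent of the scanner) and the extras; requested-but-unplantable
  positions raise.
- `PlantedScenario`/`gen_score_table` simulate scoring runs: score =
  baseline + scale·ΔΔG_true + N(0, sd) per scorer, with additive
  multi-point effects and an optional pairwise-epistasis hook (off by
  default; real mutation effects are not reliably additive, and the hook
  exists to stress-test the round engine under violations). The default
  campaign plants four beneficial singles at −1.30 to −1.82 kcal/mol
  (9- to 22-fold), the range typical of kept round-1 singles. The ddG
  estimates fed to the round engine carry 0.12 kcal/mol of Gaussian error,
  modeling the run-to-run consistency of a consensus over several scorers
  — much tighter than any single predictor's absolute accuracy. Passing
  the planted-signal test therefore shows the *machinery* (enumeration,
  ranking, thresholding, combination) is correct under conditions where
  the signal is recoverable; it says nothing about the accuracy of any
  real scoring function on real mutants.

Packaged reference tables (site panels, the 50-entry negative-Z single-
mutant table, measured K_D and T_M values for a parent clone and seven
multi-point mutants) are hand transcriptions shipped as data with SHA-256
checksums; they are inputs for arithmetic (set overlap, fold ratios, ΔT_M)
and are never regenerated computationally.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
motif-scan and interface oracles at 1,000 random instances, sensorgrams
with three concentrations at 1 s sampling over 300 s, melt curves on the
25–95 °C × 1 °C grid, campaigns over the 102-mutant panel, and the
zero-signal control over 100 seeds. These sizes give stable statistics
for every asserted property while keeping a full run in seconds.

## Known limitations

- No structure repair, protonation, side-chain rebuilding or mmCIF input.
- The toy scorer ignores geometry changes upon mutation entirely.
- Distance-only interaction criteria over-count contacts relative to
  angle-aware definitions, particularly hydrogen bonds.
- The Langmuir fitter assumes no mass-transport limitation and a
  monovalent analyte.
- Fold/ΔΔG interconversion assumes rigid two-state binding at a single
  temperature.
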