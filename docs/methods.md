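# Methods

This note documents the models implemented in `pepvax`, the choices made
where the design was genuinely open, the parameter defaults and why, and
what the synthetic test surface does and does not demonstrate.

## Interaction potentials

**Interface definition.** Two residues of opposite role (receptor vs
ligand) interact when their Cα–Cα distance is at most 8 Å; the boundary
is inclusive and computed in double precision without rounding. Only
model 1 of a PDB file is read; the first alternate location wins;
modified residues with a standard parent (e.g. selenomethionine) are
mapped to it, others are skipped, so the 20-letter alphabet stays
closed. For TCR–pMHC complexes the TCR chains are the receptor and the
MHC chain plus presented peptide together are the ligand, because the
potential scores the TCR against the composite pMHC surface.

**Decoys.** A decoy keeps the full geometry and receptor sequence of an
observed complex and resamples every ligand residue i.i.d. from a
general protein-surface amino-acid composition. The bundled composition
table fixes glycine at 6.9 % — the value used as the glycine-split
threshold, keeping the two constants consistent — with the remaining
frequencies chosen as typical surface (hydrophilic-enriched) values
normalized to 1; it is package data and user-overridable.

**Derivation.** Crystal and decoy pair-count matrices are each divided
by their number of contributing structures before subtraction, so the
number of decoys per structure (default 1; 2 in the bundled synthetic
environment to reduce decoy noise) cannot bias the difference. The
difference matrix is divided by its maximum entry, making the maximum
exactly 1.0 bit-for-bit; a non-positive maximum (no enriched pair)
is an error, not a silent result. No log or frequency transform is
applied before subtraction: the derivation works directly on mean
counts. Normalization divides by the maximum (signed) entry, not the
maximum absolute value.

**Glycine split.** Antibody–antigen sets are partitioned by the glycine
fraction among *distinct* ligand-side interface residues; fractions
strictly above 6.9 % go to the high set, ties go low. Higher interface
glycine permits sharper backbone turns and plausibly a different
recognition mode, which is why separate potentials are derived per
stratum.

**Scoring.** A contact matrix (binary receptor-position × ligand-position
template from one structure) turns a potential into a sequence score:
the mean potential value over contacting pairs. The score of a best pair
is 1.0 by construction, so the interaction probability is the clamp of
the score to [0, 1] — the minimal monotone map; a logistic alternative
exists behind the same interface for sensitivity work. Sequences longer
than the template are scored over all contiguous windows and the best
window wins; shorter sequences are an error. Uncrystallized MHC alleles
map to the template with maximal global-alignment sequence identity,
ties broken lexically by template id.

## Evaluation

Structures are split 90/10 (training fraction rounded half away from
zero, so 33 → 30/3) with a seeded permutation. The potential is derived
on training crystals only; validation crystals are scored against
freshly generated decoys so nothing from the validation set can reach
the matrix (a test verifies the matrix hash equals a train-only
re-derivation). Separation is the Mann-Whitney AUC, `U/(n₁·n₂)` with
ties counted half; p-values use the exact U distribution for small
tie-free samples and the tie-corrected normal approximation otherwise;
fully tied inputs return (0.5, 1.0) by convention. Train, validation and
pooled AUCs are all reported because a training-set AUC is inflated by
overfitting of the 400-entry matrix — on null data the train AUC sits
well above 0.5 while the validation AUC stays at chance, which is why
the acceptance checks assert on the validation set.

The bundled general-purpose contact table used in head-to-head
comparisons is synthetic package data (scaled Kyte–Doolittle
hydrophobicity products), playing the role of an immune-nonspecific
potential. The comparison test selects a planted pair that is neutral
under that table (its value closest to the composition-weighted row
mean), so the derived potential's advantage follows from construction,
not from the table's particular values.

## MHC binding and self peptides

A PSSM scores a peptide as the sum of per-position entries; binder
prediction scans all windows of a protein and keeps the top k, ties to
the earlier start. Presentation probability is a logistic in
(score − binder threshold) with configurable slope (default 1.0 in score
units); the midpoint-at-threshold convention makes the threshold
interpretable as the 50 % presentation point. Self-peptide filtering
keeps the 50 pool peptides most similar to each injected peptide, with
similarity = global-alignment identity under unit gap cost; less similar
peptides cannot interfere with the injected epitope and are dropped for
speed. Class II binding uses a fixed 9-mer core; variable-length cores
are out of scope. No third-party trained allele matrices are bundled;
the reader accepts any matrix in the documented TSV dialect and a
fixture generator produces synthetic ones.

## Repertoires and thymus selection

TCRs and BCRs are uniform-random sequences with length equal to the
contact template's receptor dimension. T-cells pass an implicit thymus:
a clone survives iff (positive selection) its mean score over some
allele's presented self background reaches `positive_min`, and
(negative selection) its maximum score over every (allele, self-peptide)
combination stays at or below `negative_max`. Selection is a pure,
order-preserving filter; BCRs are not selected. The quantitative
criteria are calibration, not published values: the defaults
(`positive_min = 0.0006`, `negative_max = 0.05`) were set once so that
roughly half of a uniform-random repertoire survives against the
synthetic self set (measured 47 % on a 2000-TCR probe; the realized
fraction varies by environment seed). Because self peptides are chosen
for similarity to the injected (tumor) peptide, negative selection
preferentially removes the strongest anti-tumor clones — the surviving
pool's mean anti-tumor reactivity never exceeds the pre-selection pool's
when tumor epitopes overlap self, and a test asserts exactly that.

## The vaccination simulator

**Geometry and time.** A cubic lattice with
`sites = volume_µl × 1600 sites/µl` (5 µl → 20³ = 8000 sites); a site is
a neighborhood volume, not an exclusive slot. Steps are 8 hours — 3 per
day, 84 per 28-day boost interval, 1095 per year. The default schedule
is step 0 plus five boosts 28 days apart.

**Initial state.** Cancer cells (default 100) are packed contiguously
around the lattice center, four per site, as a solid tumor. Leukocytes
seed uniformly at per-µl densities (TH 60, TC 60, B 40, MA 20, DC 20 —
order-of-magnitude blood-like ratios at a downscaled absolute level).
The TCR pool (600) is thymus-filtered before cells draw receptors.

**Phase order within a step** (fixed; simultaneous conflicts resolved by
a per-step random permutation of candidate order): injection → movement
(random walk to a neighboring site, tumor immobile) → phagocytosis →
presentation → T-cell recognition → clonal expansion → cytotoxicity →
humoral arm → tumor division → molecule decay/diffusion → recording.

**Recognition and danger.** Macrophages require local danger signal to
activate and present; dendritic cells phagocytose and present
regardless; B-cells ingest antigen only upon `IP_B high`/`IP_B low`
recognition (split by the peptide's glycine content). T-cell recognition
of a presented peptide uses the precomputed clamp-mapped `IP_T` score
for that (allele, peptide, receptor) triple; with local danger at or
above threshold the cell activates, otherwise it becomes anergic — an
absorbing state. This single gate is what makes adjuvant-free
vaccination fail: presentation still happens, but every recognition
event anergizes the clone. Memory cells re-encounter antigen with a
×2 recognition bonus and do not anergize.

**Population dynamics.** Active T-cells duplicate (p = 0.10/step,
boosted by local IL-2 at 0.05 per unit) and seed memory (p = 0.08);
active cells die at 0.03/step (clonal contraction), so responses peak
and subside. Active TC kill tumor cells at their site — each (TC, tumor
cell) pair is an independent attempt at the TC's clamp-mapped best
tumor-epitope probability, aggregated exactly as a per-site survival
product — and kill presenting APCs (p = 0.5 per attacker). TH-stimulated
B-cells spawn plasma and memory cells; plasma secrete antibodies (2
units/step) that clear antigen 1:1 at their site. Tumor cells divide
with p = 2^(1/1095) − 1 ≈ 6.33·10⁻⁴ per step, calibrated so the
untreated tumor doubles over one simulated year; tumor growth is never
subject to the immune-agent cap (8000), which only suppresses
lymphocyte duplication.

**Molecules.** The four fields diffuse by a 3×3×3 box filter each step
and decay multiplicatively (antigen 0.995, antibody 0.97, IL-2 0.90,
danger 0.97), clamped at zero. An injection deposits 400 antigen units
per peptide over 25 random sites, plus 160 danger units per site when
adjuvant is on; with these constants the danger field stays above the
activation threshold (0.05) over most of the lattice for roughly two to
three weeks after each boost.

**Determinism and conservation.** One seeded generator drives
everything; (config, seed) fully determines the trajectory. Every birth
(division, differentiation) and death (killing, contraction) is counted
in a per-step ledger, and tests assert the alive-count balance at every
step, plus non-negativity of all counts and fields.

**Outcome metrics.** Reactiveness = 100·(1 − final_treated /
final_untreated), floored at 0, undefined when the untreated tumor is
extinct; success = final tumor strictly below the initial count.
Replicate ratios are averaged after, not before, the division. The
failure profile reports, among failing runs, the fraction in which each
key population (active TC/TH, DC presenting I/II, MA presenting II) ever
appeared, with experiments grouped at the 50 % success-rate line. The
bias sweep multiplies every potential-derived probability by a factor
before clamping and reruns replicates per factor.

## Synthetic study environment

Real campaigns need curated PDB sets, allele sequences and trained MHC
matrices; the bundled environment replaces them with internally
consistent synthetic objects: potentials derived from planted-preference
fixture sets (enriched pair A/G), all-contact fixture templates whose
pMHC ligand is a 3-residue groove segment plus a 9-mer peptide, a
60-residue antigen with two planted glycine-rich epitopes (one per MHC
class) that the synthetic PSSMs favor, and a 200-peptide self pool
filtered to the 50 most similar per epitope. Fixture geometry places
contacting ligand residues ~5 Å above receptor positions and
non-contacting ones > 10 Å away, so the realized contact fraction is
exact to one residue.

What passing tests on this surface demonstrate: correctness of the
counting, derivation, normalization and scoring machinery against
brute-force oracles; recovery of a planted interface preference and its
held-out discriminability; and the emergent phenomenology of the
coupled model (adjuvant dependence, thymic damping of anti-tumor
reactivity, dose–response of outcome vs recognition bias). What they do
not demonstrate: the discrimination performance of potentials derived
from real crystal structures, PSSM accuracy for real alleles, or
quantitative immunological kinetics — real interfaces, repertoires and
rate constants differ from these synthetic stand-ins in composition,
correlation structure and scale.

## Problem sizes and numerical choices

Simulation experiments run at desk scale: 2–5 µl volumes (≈3200–8000
sites), 100 initial cancer cells, horizons of 250–1095 steps, and 30–100
replicates per condition, chosen so full experiment batteries complete
in minutes on one CPU while leaving Monte-Carlo noise well below the
effect sizes asserted. Degenerate inputs fail loudly rather than
silently: empty interfaces are errors where a template or fraction is
required (but legal for non-binding geometry), an empty post-thymus
repertoire logs prominently and yields a guaranteed-failure run, and
fully tied AUC inputs return chance with p = 1.

## Known limitations

Cytokines beyond IL-2 and the danger signal, regulatory T-cells, tumor
epitope mutation/escape and metastasis are out of scope by design. Cell
lifespans are effectively unlimited except for active-cell contraction
and cytotoxic killing; there is no homeostatic influx. APCs carry one
peptide at a time, and a cell presents on one MHC class at a time. The
per-step sub-ordering and all rate constants are this package's own
documented choices, not reproductions of any published automaton's
internal values.
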