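# pepvax

Immune-specific residue-pair interaction potentials, and an agent-based
simulator of peptide vaccination against solid tumors in which every
specific recognition event is scored with those potentials.

## The problem

Peptide vaccination tries to direct the adaptive immune system against a
tumor by injecting MHC-binding fragments of a tumor-associated protein.
Whether a vaccine works depends on sequence-level events — which peptides
the patient's MHC alleles present, which T-cell clones survive thymic
selection, and how strongly surviving receptors engage the presented
epitopes — entangled with cell-population dynamics. `pepvax` couples the
two levels: an empirical statistical potential scores every
receptor–ligand encounter, and a lattice multi-agent model turns those
scores into population outcomes.

## The potentials

Given a set of receptor–ligand complex structures, two residues of
opposite sides *interact* when their Cα atoms are at most 8 Å apart.
Counting interacting amino-acid pairs in observed complexes
(`C_crystal`) and in decoys whose ligand sequence is replaced by a random
sequence with general protein-surface composition (`C_random`), the
potential is the per-structure mean difference

```
M = C_crystal − C_random ,     M ← M / max(M)
```

normalized so its maximum entry is exactly 1.0. Positive entries mark
residue pairs enriched in real interfaces. Variants: `IP_T` (T-cell
receptor vs peptide–MHC, the MHC chain and peptide forming one composite
ligand) and `IP_B` (antibody vs antigen), the latter split into
`IP_B_high` / `IP_B_low` at 6.9 % interface glycine — glycine's frequency
on protein surfaces.

A receptor/ligand sequence pair is scored through a binary *contact
matrix* taken from a template structure: the score is the mean potential
value over the template's contacting position pairs, clamped to [0, 1]
when used as an interaction probability. Discrimination of observed from
decoy complexes is measured as the Mann-Whitney AUC on a 90/10
train/validation split.

## The simulator

A 3D lattice holds helper and cytotoxic T-cells, B-cells, macrophages,
dendritic cells, cancer cells, and four molecule fields (antigen,
antibody, IL-2, danger signal), advanced in 8-hour steps (1095 per
simulated year). Vaccine peptides are injected on a schedule (default:
step 0 plus five boosts at 28-day intervals), emulsified in adjuvant
modelled as a danger signal. APCs take up antigen (B-cells only upon
`IP_B` recognition), present peptides with a PSSM-derived probability,
and T-cells recognize presented peptides through `IP_T` and the
allele-matched contact matrix — activation with danger present, anergy
without. Activated clones expand, kill tumor cells and presenting APCs,
and drive the humoral arm. The initial T-cell pool passes positive and
negative thymic selection against self peptides (the 50 most similar to
each injected peptide).

## Worked example

```python
import pepvax as pv
from pepvax.synthetic import build_environment, synthetic_config

comp = pv.SurfaceComposition.default()
structures = pv.make_fixture_set(200, seed=1, preset="planted", planted_pair=("A", "G"))
report = pv.evaluate_potential(structures, "IP_T", comp, decoys_per_structure=2, seed=3)
print(report.to_text())

env = build_environment(0)
treated   = pv.run(synthetic_config(seed=1, env=env))
untreated = pv.run(synthetic_config(seed=1, env=env, schedule=[], adjuvant=False))
print("reactiveness: %.1f%%" % pv.reactiveness(treated, untreated))
```

prints

```
potential variant: IP_T
structures: 180 train / 20 validation
train AUC      = 1.0000 (p = 3.95e-80)
validation AUC = 1.0000 (p = 3.74e-10)
pooled AUC     = 1.0000 (p = 7.73e-89)
  train_crystal: mean +0.6399 +/- 0.1399
  train_random: mean +0.0046 +/- 0.0667
  validation_crystal: mean +0.6831 +/- 0.1269
  validation_random: mean +0.0130 +/- 0.0799
reactiveness: 98.6%
```

The potential derived on the planted-preference fixture set separates
held-out observed-like complexes from decoys perfectly (validation AUC
1.0, p < 0.01), and the vaccination run reduces the tumor from 100 cells
to 3 while the untreated tumor grows to 209 — a 98.6 % reduction
relative to unlimited growth (100 % would be eradication).

The same operations are available from the shell:

```
pepvax fixtures --preset planted --n 200 --seed 0 --out fx/
pepvax derive-potential --crystal fx/ --variant IP_T --seed 1 --out ipt.tsv
pepvax evaluate --crystal fx/ --variant IP_T --seed 2 --out eval/
pepvax simulate --seed 1 --out sim/
pepvax bias-sweep --seed 1 --replicates 20 --out sweep.csv
```

Every command writes a JSON manifest (seed, parameter hash, input
digests) next to its outputs.

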