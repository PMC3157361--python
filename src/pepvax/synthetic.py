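"""A fully synthetic, self-contained study setup for the simulator.

Real campaigns need curated crystal structures, allele groove sequences
and trained MHC matrices.  This module builds an internally consistent
stand-in for all of them from the package's own fixture generators, so a
complete vaccination experiment can run from a single seed:

* ``IP_T`` is derived from a planted-preference TCR--pMHC fixture set
  (enriched receptor/ligand pair A/G), ``IP_B high``/``IP_B low`` from
  glycine-rich and glycine-poor antibody--antigen fixture sets;
* contact templates come from all-contact fixture complexes whose ligand
  side is an MHC groove segment followed by a 9-mer peptide;
* the tumor antigen is a random surface-composition 60-mer with two
  planted glycine-rich 9-mer epitopes, one per MHC class, and each
  synthetic allele's PSSM favors its epitope so the vaccine peptides are
  genuine predicted binders;
* self peptides are the 50 pool members most similar to each injected
  peptide, mirroring the thymus-selection input filter.

Everything is deterministic in the seed.  The defaults below *are* the
study conditions; they are not tuned per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mhc_binding import Pssm, make_fixture_pssm, select_self_peptides
from .potential import (
    ContactMatrix,
    InteractionPotential,
    SurfaceComposition,
    build_contact_matrix,
    derive_potential,
)
from .repertoire import SelectionThresholds
from .simulator import Rates, SimulationConfig, build_schedule
from .structure_io import make_fixture_complex, make_fixture_set

#: receptor length shared by every synthetic contact template
TCR_LENGTH = 10
BCR_LENGTH = 10
PEPTIDE_LENGTH = 9
#: ligand columns of the pMHC templates: groove segment + peptide
MHC_SEGMENT = 3

#: thymus-selection window calibrated on uniform-random repertoires
#: against the synthetic self set so that roughly half the pool survives
#: (see docs/methods.md); both are plain config values, overridable.
DEFAULT_POSITIVE_MIN = 0.0006
DEFAULT_NEGATIVE_MAX = 0.05


@dataclass
class SyntheticEnvironment:
    """All sequence/structure inputs of one synthetic vaccination study."""

    comp: SurfaceComposition
    ip_t: InteractionPotential
    ip_b_high: InteractionPotential
    ip_b_low: InteractionPotential
    templates_I: list[tuple[str, str, ContactMatrix]]
    templates_II: list[tuple[str, str, ContactMatrix]]
    b_template: ContactMatrix
    alleles_I: list[tuple[str, str]]
    alleles_II: list[tuple[str, str]]
    antigen: str
    peptides_I: list[str]
    peptides_II: list[str]
    pssms_I: dict[str, Pssm]
    pssms_II: dict[str, Pssm]
    self_peptides: list[str]


def _random_seq(rng: np.random.Generator, comp: SurfaceComposition, n: int) -> str:
    letters = list(comp.freq.keys())
    probs = np.asarray([comp.freq[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(letters[i] for i in rng.choice(len(letters), size=n, p=probs))


def _pmhc_template(
    template_id: str, mhc_seq: str, seed: int
) -> tuple[str, str, ContactMatrix]:
    n_lig = MHC_SEGMENT + PEPTIDE_LENGTH
    c, _ = make_fixture_complex(
        TCR_LENGTH, n_lig, "A" * TCR_LENGTH, "G" * n_lig, 1.0, seed,
        complex_kind="tcr_pmhc", structure_id=template_id,
    )
    return template_id, mhc_seq, build_contact_matrix(c)


def build_environment(seed: int = 0) -> SyntheticEnvironment:
    """Construct the full synthetic study environment for one seed."""
    rng = np.random.default_rng(seed)
    comp = SurfaceComposition.default()

    # interaction potentials from planted fixture sets
    ip_t = derive_potential(
        make_fixture_set(80, seed=int(rng.integers(2**31)), preset="planted",
                         planted_pair=("A", "G")),
        "IP_T", comp, decoys_per_structure=2, rng=rng,
    )
    ip_b_high = derive_potential(
        make_fixture_set(60, seed=int(rng.integers(2**31)), preset="planted",
                         planted_pair=("A", "G"), complex_kind="antibody_antigen"),
        "IP_B_high", comp, decoys_per_structure=2, rng=rng,
    )
    ip_b_low = derive_potential(
        make_fixture_set(60, seed=int(rng.integers(2**31)), preset="planted",
                         planted_pair=("A", "S"), complex_kind="antibody_antigen"),
        "IP_B_low", comp, decoys_per_structure=2, rng=rng,
    )

    # synthetic genotype: one class-I and one class-II allele, each with a
    # matching contact template (identity 1 under template mapping)
    groove_I = _random_seq(rng, comp, 30)
    groove_II = _random_seq(rng, comp, 30)
    alleles_I = [("SYN-A1", groove_I)]
    alleles_II = [("SYN-D1", groove_II)]
    templates_I = [_pmhc_template("TPL-I1", groove_I, int(rng.integers(2**31)))]
    templates_II = [_pmhc_template("TPL-II1", groove_II, int(rng.integers(2**31)))]

    b_fix, _ = make_fixture_complex(
        BCR_LENGTH, PEPTIDE_LENGTH, "A" * BCR_LENGTH, "G" * PEPTIDE_LENGTH,
        1.0, int(rng.integers(2**31)),
        complex_kind="antibody_antigen", structure_id="TPL-B1",
    )
    b_template = build_contact_matrix(b_fix)

    # tumor antigen with planted glycine-rich epitopes (one per MHC class)
    antigen = list(_random_seq(rng, comp, 60))
    antigen[20:29] = "GGGAGGGAG"
    antigen[40:49] = "GAGGGAGGG"
    antigen = "".join(antigen)
    epitope_I = antigen[20:29]
    epitope_II = antigen[40:49]

    pssms_I = {
        "SYN-A1": make_fixture_pssm(
            PEPTIDE_LENGTH, int(rng.integers(2**31)), "SYN-A1", favored_peptide=epitope_I
        )
    }
    pssms_II = {
        "SYN-D1": make_fixture_pssm(
            PEPTIDE_LENGTH, int(rng.integers(2**31)), "SYN-D1", favored_peptide=epitope_II
        )
    }

    # self-peptide background: random pool filtered to the 50 most similar
    # to each injected peptide, then pooled
    pool = [_random_seq(rng, comp, PEPTIDE_LENGTH) for _ in range(200)]
    self_peptides = sorted(
        set(select_self_peptides(pool, epitope_I, 50))
        | set(select_self_peptides(pool, epitope_II, 50))
    )

    return SyntheticEnvironment(
        comp=comp, ip_t=ip_t, ip_b_high=ip_b_high, ip_b_low=ip_b_low,
        templates_I=templates_I, templates_II=templates_II, b_template=b_template,
        alleles_I=alleles_I, alleles_II=alleles_II,
        antigen=antigen, peptides_I=[epitope_I], peptides_II=[epitope_II],
        pssms_I=pssms_I, pssms_II=pssms_II, self_peptides=self_peptides,
    )


def synthetic_config(
    seed: int = 0,
    env: SyntheticEnvironment | None = None,
    env_seed: int = 0,
    volume_ul: float = 5.0,
    initial_cancer: int = 100,
    duration: int = 1095,
    schedule: list[int] | None = None,
    adjuvant: bool = True,
    ip_bias: float = 1.0,
    rates: Rates | None = None,
    thresholds: SelectionThresholds | None = None,
) -> SimulationConfig:
    """A ready-to-run config: 100 cancer cells in 5 µl over one simulated
    year, injections at time zero plus five 28-day boosts.

    ``env`` (or ``env_seed``) fixes the study environment — potentials,
    templates, antigen, PSSMs, self peptides — while ``seed`` drives the
    stochastic trajectory, so replicate runs share one environment.
    """
    if env is None:
        env = build_environment(env_seed)
    return SimulationConfig(
        volume_ul=volume_ul,
        initial_cancer=initial_cancer,
        duration=duration,
        schedule=build_schedule() if schedule is None else schedule,
        adjuvant=adjuvant,
        seed=seed,
        alleles_I=env.alleles_I,
        alleles_II=env.alleles_II,
        peptides_I=env.peptides_I,
        peptides_II=env.peptides_II,
        pssms_I=env.pssms_I,
        pssms_II=env.pssms_II,
        templates_I=env.templates_I,
        templates_II=env.templates_II,
        b_template=env.b_template,
        ip_t=env.ip_t,
        ip_b_high=env.ip_b_high,
        ip_b_low=env.ip_b_low,
        self_peptides=env.self_peptides,
        thresholds=thresholds
        or SelectionThresholds(DEFAULT_POSITIVE_MIN, DEFAULT_NEGATIVE_MAX),
        rates=rates or Rates(),
        ip_bias=ip_bias,
    )
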