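"""Empirical immune-specific residue-pair interaction potentials.

The potential is derived by comparing the amino-acid pair composition of
observed receptor--ligand interfaces against decoy interfaces in which
the ligand sequence is replaced by a random sequence with general
protein-surface composition.  With mean-per-structure count matrices
``C_crystal`` and ``C_random`` the raw potential is

    M = C_crystal - C_random

which is then normalized so that its maximum entry is exactly 1.0.
Positive entries mark residue pairs enriched in real interfaces, negative
entries depleted ones.  Variants: ``IP_T`` (TCR vs peptide--MHC), ``IP_B``
(antibody vs antigen), and the glycine split of the latter, ``IP_B_high``
/ ``IP_B_low``, separated at 6.9% interface glycine — the frequency of
glycine on protein surfaces.

Scoring a receptor/ligand sequence pair uses a binary *contact matrix*
taken from a template structure: the score is the mean potential value
over all contacting position pairs, and is mapped to an interaction
probability by clamping to [0, 1] (the matrix maximum is 1.0 by
construction).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import global_identity
from ._alphabet import AA_INDEX, AMINO_ACIDS, N_AA, encode
from .structure_io import (
    Chain,
    ComplexStructure,
    DEFAULT_CUTOFF,
    LIGAND,
    Residue,
    extract_interface,
)

logger = logging.getLogger(__name__)

GLYCINE_SURFACE_FREQUENCY = 0.069

VARIANTS = ("IP_T", "IP_B", "IP_B_high", "IP_B_low")


class DerivationError(ValueError):
    """Raised when no residue pair is enriched over the decoy background."""


@dataclass
class SurfaceComposition:
    """Amino-acid frequencies observed on general protein surfaces."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.freq)
        if missing:
            raise ValueError(f"composition missing amino acids {sorted(missing)}")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, not 1.0")

    def as_array(self) -> np.ndarray:
        return np.asarray([self.freq[a] for a in AMINO_ACIDS], dtype=float)

    @classmethod
    def uniform(cls) -> "SurfaceComposition":
        return cls({a: 1.0 / N_AA for a in AMINO_ACIDS})

    @classmethod
    def default(cls) -> "SurfaceComposition":
        """The bundled surface-composition table (glycine at 6.9%)."""
        text = (
            importlib.resources.files("pepvax.data")
            .joinpath("surface_composition.tsv")
            .read_text()
        )
        freq: dict[str, float] = {}
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("aa"):
                continue
            aa, val = line.split("\t")
            freq[aa] = float(val)
        return cls(freq)


@dataclass
class PairCountMatrix:
    """20x20 interface pair counts; rows = receptor aa, columns = ligand aa."""

    counts: np.ndarray
    n_structures: int
    source: str  # "crystal" | "random"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_AA, N_AA):
            raise ValueError("counts must be 20x20")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class InteractionPotential:
    """A normalized 20x20 interaction potential (max entry exactly 1.0)."""

    matrix: np.ndarray
    variant: str
    max_before_norm: float = float("nan")
    derivation_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_AA, N_AA):
            raise ValueError("potential matrix must be 20x20")

    def entry(self, receptor_aa: str, ligand_aa: str) -> float:
        return float(self.matrix[AA_INDEX[receptor_aa], AA_INDEX[ligand_aa]])

    def to_tsv(self) -> str:
        lines = [
            f"# interaction potential variant={self.variant} "
            f"max_before_norm={self.max_before_norm!r}",
            "# rows = receptor amino acid, columns = ligand amino acid",
            "\t" + "\t".join(AMINO_ACIDS),
        ]
        for i, aa in enumerate(AMINO_ACIDS):
            lines.append(aa + "\t" + "\t".join(repr(float(v)) for v in self.matrix[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, variant: str = "IP_T") -> "InteractionPotential":
        max_before = float("nan")
        rows: dict[str, list[float]] = {}
        col_order: list[str] | None = None
        for line in text.splitlines():
            if line.startswith("#"):
                if "max_before_norm=" in line:
                    try:
                        max_before = float(line.split("max_before_norm=")[1].split()[0])
                    except ValueError:
                        pass
                if "variant=" in line:
                    variant = line.split("variant=")[1].split()[0]
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "":
                col_order = parts[1:]
                continue
            rows[parts[0]] = [float(v) for v in parts[1:]]
        if col_order is None or set(rows) != set(AMINO_ACIDS):
            raise ValueError("malformed potential table")
        m = np.zeros((N_AA, N_AA))
        for aa, vals in rows.items():
            for col_aa, v in zip(col_order, vals):
                m[AA_INDEX[aa], AA_INDEX[col_aa]] = v
        return cls(m, variant, max_before)


@dataclass
class ContactMatrix:
    """Binary receptor-position x ligand-position contact template."""

    template_id: str
    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m)
        if self.m.ndim != 2:
            raise ValueError("contact matrix must be 2-D")
        vals = set(np.unique(self.m).tolist())
        if not vals <= {0, 1, False, True}:
            raise ValueError("contact matrix entries must be 0/1")
        self.m = self.m.astype(bool)
        if not self.m.any():
            raise ValueError("contact matrix must contain at least one contact")

    @property
    def n_contacts(self) -> int:
        return int(self.m.sum())

    def to_tsv(self) -> str:
        lines = [f"# contact matrix template={self.template_id}",
                 "# rows = receptor positions, columns = ligand positions",
                 "\t" + "\t".join(str(j) for j in range(self.m.shape[1]))]
        for i in range(self.m.shape[0]):
            lines.append(str(i) + "\t" + "\t".join(str(int(v)) for v in self.m[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "ContactMatrix":
        template_id = "template"
        rows = []
        for line in text.splitlines():
            if line.startswith("#"):
                if "template=" in line:
                    template_id = line.split("template=")[1].split()[0]
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "":
                continue
            rows.append([int(v) for v in parts[1:]])
        return cls(template_id, np.asarray(rows, dtype=int))


def make_decoy(
    c: ComplexStructure, comp: SurfaceComposition, rng: np.random.Generator
) -> ComplexStructure:
    """A non-binding stand-in: same geometry, ligand sequence resampled.

    Every ligand-side residue's amino acid is drawn independently from the
    surface composition; receptor side and all coordinates are unchanged.
    """
    probs = comp.as_array()
    chains: list[Chain] = []
    for chain in c.chains:
        if chain.role == LIGAND:
            idx = rng.choice(N_AA, size=len(chain.residues), p=probs)
            residues = [
                Residue(AMINO_ACIDS[k], r.chain_id, r.seq_index, r.ca_xyz)
                for k, r in zip(idx, chain.residues)
            ]
        else:
            residues = list(chain.residues)
        chains.append(Chain(chain.chain_id, chain.role, residues))
    return ComplexStructure(c.id + "_decoy", chains, c.complex_kind)


def count_pairs(
    structures: Sequence[ComplexStructure],
    cutoff: float = DEFAULT_CUTOFF,
    source: str = "crystal",
) -> PairCountMatrix:
    """Total interface amino-acid pair counts over a structure set."""
    if not structures:
        raise ValueError("empty structure list")
    counts = np.zeros((N_AA, N_AA))
    for c in structures:
        pairs = extract_interface(c, cutoff)
        if not pairs:
            logger.info("structure %s has an empty interface", c.id)
            continue
        for p in pairs:
            counts[AA_INDEX[p.receptor_residue.aa], AA_INDEX[p.ligand_residue.aa]] += 1
    return PairCountMatrix(counts, len(structures), source)


def derive_potential(
    crystal: Sequence[ComplexStructure],
    variant: str,
    comp: SurfaceComposition | None = None,
    decoys_per_structure: int = 1,
    rng: np.random.Generator | int | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> InteractionPotential:
    """Derive a potential from observed complexes and generated decoys.

    Crystal and decoy pair counts are each averaged per contributing
    structure before subtraction, so ``decoys_per_structure`` > 1 reduces
    decoy noise without biasing the difference.  The difference matrix is
    divided by its maximum entry, making the maximum exactly 1.0.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if not crystal:
        raise ValueError("empty crystal set")
    if decoys_per_structure < 1:
        raise ValueError("decoys_per_structure must be >= 1")
    if comp is None:
        comp = SurfaceComposition.default()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    c_crystal = count_pairs(crystal, cutoff, "crystal")
    decoys = [
        make_decoy(c, comp, rng) for c in crystal for _ in range(decoys_per_structure)
    ]
    c_random = count_pairs(decoys, cutoff, "random")

    m_raw = c_crystal.counts / c_crystal.n_structures - c_random.counts / c_random.n_structures
    m_max = m_raw.max()
    if m_max <= 0:
        raise DerivationError("no residue pair enriched over the decoy background")
    return InteractionPotential(
        m_raw / m_max,
        variant,
        max_before_norm=float(m_max),
        derivation_meta={
            "n_structures": len(crystal),
            "decoys_per_structure": decoys_per_structure,
            "cutoff": cutoff,
            "glycine_threshold": GLYCINE_SURFACE_FREQUENCY
            if variant in ("IP_B_high", "IP_B_low")
            else None,
        },
    )


def glycine_fraction(c: ComplexStructure, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Glycine fraction among the distinct ligand-side interface residues."""
    pairs = extract_interface(c, cutoff)
    if not pairs:
        raise ValueError(f"structure {c.id} has an empty interface")
    seen: dict[tuple[str, int], str] = {}
    for p in pairs:
        r = p.ligand_residue
        seen[(r.chain_id, r.seq_index)] = r.aa
    return sum(1 for aa in seen.values() if aa == "G") / len(seen)


def split_by_glycine(
    structures: Sequence[ComplexStructure],
    threshold: float = GLYCINE_SURFACE_FREQUENCY,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[ComplexStructure], list[ComplexStructure]]:
    """Partition antibody--antigen complexes at the interface-glycine threshold.

    High set: fraction strictly above ``threshold``; ties go to the low set.
    """
    high, low = [], []
    for c in structures:
        if c.complex_kind != "antibody_antigen":
            raise ValueError("glycine split applies to antibody_antigen complexes only")
        if glycine_fraction(c, cutoff) > threshold:
            high.append(c)
        else:
            low.append(c)
    return high, low


def build_contact_matrix(
    template: ComplexStructure, cutoff: float = DEFAULT_CUTOFF
) -> ContactMatrix:
    """Binary contact template from one structure (1 = Cα pair within cutoff)."""
    rec = template.receptor_residues
    lig = template.ligand_residues
    pairs = extract_interface(template, cutoff)
    if not pairs:
        raise ValueError(f"template {template.id} has an empty interface")
    rec_index = {(r.chain_id, r.seq_index): i for i, r in enumerate(rec)}
    lig_index = {(r.chain_id, r.seq_index): j for j, r in enumerate(lig)}
    m = np.zeros((len(rec), len(lig)), dtype=bool)
    for p in pairs:
        i = rec_index[(p.receptor_residue.chain_id, p.receptor_residue.seq_index)]
        j = lig_index[(p.ligand_residue.chain_id, p.ligand_residue.seq_index)]
        m[i, j] = True
    return ContactMatrix(template.id, m)


def _best_window_scores(
    codes: np.ndarray, needed: int
) -> Iterable[np.ndarray]:
    for start in range(len(codes) - needed + 1):
        yield codes[start : start + needed]


def score_interaction(
    receptor_seq: str,
    ligand_seq: str,
    cm: ContactMatrix,
    ip: InteractionPotential,
) -> float:
    """Mean potential value over the template's contacting position pairs.

    Sequences longer than the template dimension are scored over every
    contiguous window and the maximal window score is returned; shorter
    sequences are an error.  Never exceeds 1.0 (the normalized maximum).
    """
    n_rec, n_lig = cm.m.shape
    r_codes = encode(receptor_seq)
    l_codes = encode(ligand_seq)
    if len(r_codes) < n_rec or len(l_codes) < n_lig:
        raise ValueError(
            f"sequence shorter than contact template ({len(r_codes)}x{len(l_codes)} "
            f"vs {n_rec}x{n_lig})"
        )
    ii, jj = np.nonzero(cm.m)
    n = len(ii)
    best = -np.inf
    for rw in _best_window_scores(r_codes, n_rec):
        for lw in _best_window_scores(l_codes, n_lig):
            s = ip.matrix[rw[ii], lw[jj]].sum() / n
            if s > best:
                best = s
    return float(best)


def score_complex(
    c: ComplexStructure, ip: InteractionPotential, cutoff: float = DEFAULT_CUTOFF
) -> float:
    """Score a structure with its own geometry as the contact template."""
    pairs = extract_interface(c, cutoff)
    if not pairs:
        raise ValueError(f"structure {c.id} has an empty interface")
    total = sum(
        ip.matrix[AA_INDEX[p.receptor_residue.aa], AA_INDEX[p.ligand_residue.aa]]
        for p in pairs
    )
    return float(total / len(pairs))


def score_to_probability(
    score: float, strategy: str = "clamp", slope: float = 0.2, midpoint: float = 0.5
) -> float:
    """Map an interaction score to a probability in [0, 1].

    The default is the minimal monotone map — clamp to [0, 1]; scores are
    normalized to a maximum of 1.0, so no rescaling is needed.  A logistic
    alternative is available for sensitivity experiments.
    """
    if strategy == "clamp":
        return float(min(1.0, max(0.0, score)))
    if strategy == "logistic":
        return float(1.0 / (1.0 + np.exp(-(score - midpoint) / slope)))
    raise ValueError(f"unknown strategy {strategy!r}")


def load_general_potential() -> InteractionPotential:
    """The bundled synthetic general-purpose contact table.

    A hydrophobicity-product score table standing in for a general
    (immune-nonspecific) contact potential in head-to-head comparisons;
    it is synthetic package data, not a published energy table.
    """
    text = (
        importlib.resources.files("pepvax.data")
        .joinpath("general_contact_potential_synthetic.tsv")
        .read_text()
    )
    rows: dict[str, list[float]] = {}
    col_order: list[str] | None = None
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "":
            col_order = parts[1:]
            continue
        rows[parts[0]] = [float(v) for v in parts[1:]]
    m = np.zeros((N_AA, N_AA))
    for aa, vals in rows.items():
        for col_aa, v in zip(col_order, vals):
            m[AA_INDEX[aa], AA_INDEX[col_aa]] = v
    return InteractionPotential(m, "IP_T", max_before_norm=float("nan"),
                                derivation_meta={"source": "synthetic_general"})


def map_mhc_to_template(
    mhc_seq: str,
    templates: Sequence[tuple[str, str, ContactMatrix]],
) -> ContactMatrix:
    """Contact matrix of the template closest to an uncrystallized MHC.

    Closeness is global-alignment sequence identity; ties break by
    lexical template id.
    """
    if not templates:
        raise ValueError("empty template library")
    best_cm: ContactMatrix | None = None
    best_identity = -1.0
    # iterate in lexical template-id order so strict > breaks ties lexically
    for template_id, template_seq, cm in sorted(templates, key=lambda t: t[0]):
        identity = global_identity(mhc_seq, template_seq)
        if identity > best_identity:
            best_identity = identity
            best_cm = cm
    assert best_cm is not None
    return best_cm
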