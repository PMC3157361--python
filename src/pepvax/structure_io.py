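"""Complex structures: PDB parsing, interface extraction, synthetic fixtures.

A *complex structure* is a receptor--ligand pair of chain groups: for
TCR--pMHC complexes the TCR chains are the receptor and the MHC heavy
chain plus the presented peptide together form the ligand; for
antibody--antigen complexes the antibody chains are the receptor and the
antigen the ligand.  Interface membership is decided purely on Cα--Cα
distance: two residues of opposite role interact when their Cα atoms are
no more than ``cutoff`` (default 8 Å) apart, boundary inclusive.

Real structures are read from PDB-format text (model 1, ATOM records with
a Cα); synthetic fixture complexes with a controllable interface
composition are generated by :func:`make_fixture_complex` and friends and
written back out as minimal valid PDB.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from ._alphabet import AA_INDEX, AMINO_ACIDS, THREE_TO_ONE

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 8.0

RECEPTOR = "receptor"
LIGAND = "ligand"

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


class StructureError(ValueError):
    """A structure is unusable (e.g. a mapped chain has no Cα at all)."""


@dataclass(frozen=True)
class Residue:
    """One standard residue represented by its Cα atom."""

    aa: str
    chain_id: str
    seq_index: int
    ca_xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.aa not in AA_INDEX:
            raise ValueError(f"residue letter {self.aa!r} outside the 20-letter alphabet")
        if not all(math.isfinite(v) for v in self.ca_xyz):
            raise ValueError("non-finite Cα coordinate")


@dataclass
class Chain:
    chain_id: str
    role: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if self.role not in (RECEPTOR, LIGAND):
            raise ValueError(f"unknown chain role {self.role!r}")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"chain {self.chain_id}: seq_index not strictly increasing")


@dataclass
class ComplexStructure:
    """A receptor--ligand complex reduced to per-residue Cα coordinates."""

    id: str
    chains: list[Chain]
    complex_kind: str  # "tcr_pmhc" or "antibody_antigen"

    def __post_init__(self) -> None:
        if self.complex_kind not in ("tcr_pmhc", "antibody_antigen"):
            raise ValueError(f"unknown complex_kind {self.complex_kind!r}")
        roles = {c.role for c in self.chains}
        if roles != {RECEPTOR, LIGAND}:
            raise ValueError("complex needs at least one receptor and one ligand chain")

    def residues_by_role(self, role: str) -> list[Residue]:
        return [r for c in self.chains if c.role == role for r in c.residues]

    @property
    def receptor_residues(self) -> list[Residue]:
        return self.residues_by_role(RECEPTOR)

    @property
    def ligand_residues(self) -> list[Residue]:
        return self.residues_by_role(LIGAND)

    def sequence(self, role: str) -> str:
        return "".join(r.aa for r in self.residues_by_role(role))


@dataclass(frozen=True)
class InterfacePair:
    receptor_residue: Residue
    ligand_residue: Residue
    distance: float


def parse_structure(
    pdb_text: str,
    role_map: Mapping[str, str],
    complex_kind: str,
    structure_id: str = "complex",
) -> ComplexStructure:
    """Parse PDB-format text into a :class:`ComplexStructure`.

    Only model 1 and chains listed in ``role_map`` are used.  Residues are
    kept when they carry a Cα atom and map onto a standard amino acid
    (selenomethionine and similar modified residues are mapped to their
    parent); anything else is skipped with a logged warning.  For
    alternate locations the first one wins.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise StructureError("no model in PDB text")
    model = models[0]

    present = {chain.id for chain in model}
    missing = set(role_map) - present
    if missing:
        raise ValueError(f"chains {sorted(missing)} in role_map absent from file")

    chains: list[Chain] = []
    for chain in model:
        if chain.id not in role_map:
            continue
        residues: list[Residue] = []
        for res in chain:
            if "CA" not in res:
                continue
            resname = res.get_resname().strip()
            aa = THREE_TO_ONE.get(resname)
            if aa is None:
                logger.warning(
                    "skipping non-standard residue %s %s%s", resname, chain.id, res.id[1]
                )
                continue
            atom = res["CA"]
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]
            x, y, z = (float(v) for v in atom.coord)
            # insertion codes preserved in ordering via a fractional offset
            icode = res.id[2].strip()
            seq_index = res.id[1]
            residues.append(Residue(aa, chain.id, seq_index, (x, y, z)))
        if not residues:
            raise StructureError(f"chain {chain.id} has no standard residue with a Cα")
        # de-duplicate seq indices (insertion codes): keep file order, reindex
        reindexed = [
            Residue(r.aa, r.chain_id, i, r.ca_xyz) for i, r in enumerate(residues)
        ]
        chains.append(Chain(chain.id, role_map[chain.id], reindexed))

    return ComplexStructure(structure_id, chains, complex_kind)


def extract_interface(
    c: ComplexStructure, cutoff: float = DEFAULT_CUTOFF
) -> list[InterfacePair]:
    """All receptor x ligand residue pairs with Cα distance <= cutoff.

    The boundary is inclusive; an empty result is a legal outcome for
    non-binding geometry.
    """
    rec = c.receptor_residues
    lig = c.ligand_residues
    if not rec or not lig:
        return []
    d = cdist(
        np.asarray([r.ca_xyz for r in rec], dtype=float),
        np.asarray([r.ca_xyz for r in lig], dtype=float),
    )
    pairs = []
    for i, j in zip(*np.nonzero(d <= cutoff)):
        pairs.append(InterfacePair(rec[i], lig[j], float(d[i, j])))
    return pairs


def write_pdb(c: ComplexStructure) -> str:
    """Serialize a complex as minimal valid PDB (Cα-only ATOM records)."""
    lines = []
    serial = 1
    for chain in c.chains:
        for r in chain.residues:
            x, y, z = r.ca_xyz
            lines.append(
                f"ATOM  {serial:5d}  CA  {ONE_TO_THREE[r.aa]} {chain.chain_id}{r.seq_index + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[chain.residues[-1].aa]} "
                     f"{chain.chain_id}{chain.residues[-1].seq_index + 1:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _resolve_seq(
    spec: str | Mapping[str, float], n: int, rng: np.random.Generator
) -> str:
    """A sequence literal, or i.i.d. sampling from an aa->probability map."""
    if isinstance(spec, str):
        if len(spec) != n:
            raise ValueError(f"sequence length {len(spec)} != requested {n}")
        for a in spec:
            if a not in AA_INDEX:
                raise ValueError(f"letter {a!r} outside the alphabet")
        return spec
    letters = list(spec.keys())
    probs = np.asarray([spec[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(letters), size=n, p=probs)
    return "".join(letters[i] for i in idx)


def make_fixture_complex(
    n_receptor: int,
    n_ligand: int,
    receptor_seq: str | Mapping[str, float],
    ligand_seq: str | Mapping[str, float],
    contact_fraction: float,
    seed: int | np.random.Generator,
    complex_kind: str = "tcr_pmhc",
    structure_id: str = "fixture",
) -> tuple[ComplexStructure, str]:
    """Generate a deterministic synthetic complex with a chosen interface size.

    The receptor is laid out along the x axis at 3.8 Å spacing.  A fraction
    ``contact_fraction`` of ligand residues (rounded to the nearest residue)
    is placed ~5 Å above distinct receptor positions, hence within the 8 Å
    interface cutoff; the remaining ligand residues are placed more than
    10 Å away from every receptor residue.  Returns the structure and its
    PDB serialization.
    """
    if n_receptor < 1 or n_ligand < 1:
        raise ValueError("lengths must be >= 1")
    if not 0.0 <= contact_fraction <= 1.0:
        raise ValueError("contact_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rseq = _resolve_seq(receptor_seq, n_receptor, rng)
    lseq = _resolve_seq(ligand_seq, n_ligand, rng)
    n_contact = int(round(contact_fraction * n_ligand))

    spacing = 3.8
    rec = [
        Residue(rseq[i], "R", i, (i * spacing, 0.0, 0.0)) for i in range(n_receptor)
    ]
    lig: list[Residue] = []
    jitter = rng.uniform(-0.4, 0.4, size=(n_ligand, 3))
    for j in range(n_ligand):
        if j < n_contact:
            anchor = (j % n_receptor) * spacing
            xyz = (anchor + jitter[j, 0], 5.0 + jitter[j, 1], jitter[j, 2])
        else:
            # far plane: > 10 Å from every receptor Cα
            xyz = (j * spacing, 60.0 + jitter[j, 1], jitter[j, 2])
        lig.append(Residue(lseq[j], "L", j, tuple(float(v) for v in xyz)))

    c = ComplexStructure(
        structure_id,
        [Chain("R", RECEPTOR, rec), Chain("L", LIGAND, lig)],
        complex_kind,
    )
    return c, write_pdb(c)


def make_fixture_set(
    n_structures: int,
    seed: int,
    preset: str = "planted",
    planted_pair: tuple[str, str] = ("A", "G"),
    planted_strength: float = 0.8,
    composition: Mapping[str, float] | None = None,
    n_receptor: int = 12,
    n_ligand: int = 10,
    contact_fraction: float = 1.0,
    complex_kind: str = "tcr_pmhc",
) -> list[ComplexStructure]:
    """A synthetic crystal-like set with or without a planted pair preference.

    ``preset='planted'`` draws each receptor (ligand) residue as the planted
    receptor (ligand) amino acid with probability ``planted_strength`` and
    from the surface composition otherwise, enriching the planted pair in
    every interface.  ``preset='null'`` draws both sides from the surface
    composition, so interfaces carry no pair signal at all.
    """
    if composition is None:
        from .potential import SurfaceComposition

        composition = SurfaceComposition.default().freq
    if preset not in ("planted", "null"):
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    letters = list(composition.keys())
    probs = np.asarray([composition[a] for a in letters], dtype=float)
    probs = probs / probs.sum()

    def draw(n: int, planted_aa: str | None) -> str:
        base = rng.choice(len(letters), size=n, p=probs)
        seq = [letters[i] for i in base]
        if planted_aa is not None:
            mask = rng.random(n) < planted_strength
            seq = [planted_aa if m else s for m, s in zip(mask, seq)]
        return "".join(seq)

    out = []
    r_aa, l_aa = (planted_pair if preset == "planted" else (None, None))
    for k in range(n_structures):
        rseq = draw(n_receptor, r_aa)
        lseq = draw(n_ligand, l_aa)
        c, _ = make_fixture_complex(
            n_receptor,
            n_ligand,
            rseq,
            lseq,
            contact_fraction,
            rng,
            complex_kind=complex_kind,
            structure_id=f"{preset}{k:04d}",
        )
        out.append(c)
    return out
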