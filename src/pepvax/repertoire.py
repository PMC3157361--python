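"""Random immune-receptor repertoires and implicit thymus selection.

TCR and BCR sequences are uniform-random strings over the 20-letter
alphabet, with length matched to the receptor dimension of the contact
template used for scoring.  Before entering the simulation, the T-cell
pool passes through an implicit thymus: positive selection keeps clones
with sufficient reactivity to the self-peptide background presented on
the individual's MHC alleles, negative selection removes clones that are
strongly reactive to any single self peptide.  BCRs are not thymically
selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._alphabet import AMINO_ACIDS, N_AA, decode, encode
from .potential import ContactMatrix, InteractionPotential, map_mhc_to_template

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReceptorSequence:
    seq: str
    kind: str  # "TCR" | "BCR"

    def __post_init__(self) -> None:
        if self.kind not in ("TCR", "BCR"):
            raise ValueError(f"unknown receptor kind {self.kind!r}")
        encode(self.seq)  # validates alphabet


@dataclass
class SelectionThresholds:
    """Survival window for thymus selection.

    ``positive_min``: minimum mean reactivity against an allele's presented
    self background (survive positive selection on at least one allele).
    ``negative_max``: maximum tolerated score against any single
    (allele, self-peptide) combination.
    """

    positive_min: float
    negative_max: float

    def __post_init__(self) -> None:
        if self.positive_min > self.negative_max:
            logger.warning(
                "positive_min (%g) > negative_max (%g): empty repertoires likely",
                self.positive_min,
                self.negative_max,
            )


def generate_repertoire(
    n: int, kind: str, length: int, rng: np.random.Generator | int | None = None
) -> list[ReceptorSequence]:
    """n i.i.d. uniform-alphabet receptor sequences, deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    codes = rng.integers(0, N_AA, size=(n, length))
    return [ReceptorSequence(decode(row), kind) for row in codes]


def batch_scores(
    receptor_codes: np.ndarray,
    ligand_codes: np.ndarray,
    cm: ContactMatrix,
    ip: InteractionPotential,
) -> np.ndarray:
    """Interaction scores of many receptors against one ligand at once.

    ``receptor_codes`` is (n, len_receptor) uint8; ligand must match the
    template's ligand dimension exactly.  Returns the mean potential value
    over the template contacts for each receptor — identical to
    :func:`pepvax.potential.score_interaction` without windowing.
    """
    ii, jj = np.nonzero(cm.m)
    if receptor_codes.shape[1] != cm.m.shape[0]:
        raise ValueError("receptor length does not match contact template")
    if len(ligand_codes) != cm.m.shape[1]:
        raise ValueError("ligand length does not match contact template")
    return ip.matrix[receptor_codes[:, ii], ligand_codes[jj]].mean(axis=1)


def _pmhc_ligand_codes(
    allele_seq: str, peptide: str, cm: ContactMatrix
) -> np.ndarray:
    """Composite pMHC ligand for a template: MHC segment + presented peptide.

    The template's ligand dimension covers the MHC groove segment followed
    by the peptide; the allele sequence fills the MHC segment (truncated or
    cyclically padded to fit) and the peptide the remainder.
    """
    n_lig = cm.m.shape[1]
    pep_codes = encode(peptide)
    mhc_len = n_lig - len(pep_codes)
    if mhc_len < 0:
        raise ValueError("peptide longer than the template ligand dimension")
    mhc_codes = encode(allele_seq)
    if len(mhc_codes) < mhc_len:
        reps = int(np.ceil(mhc_len / len(mhc_codes)))
        mhc_codes = np.tile(mhc_codes, reps)
    return np.concatenate([mhc_codes[:mhc_len], pep_codes])


def pmhc_recognition_scores(
    receptor_codes: np.ndarray,
    allele_seq: str,
    peptide: str,
    templates: Sequence[tuple[str, str, ContactMatrix]],
    ip_t: InteractionPotential,
) -> np.ndarray:
    """Scores of a TCR batch against one peptide presented on one allele."""
    cm = map_mhc_to_template(allele_seq, templates)
    ligand = _pmhc_ligand_codes(allele_seq, peptide, cm)
    return batch_scores(receptor_codes, ligand, cm, ip_t)


def thymus_select(
    repertoire: Sequence[ReceptorSequence],
    self_peptides: Sequence[str],
    mhc_alleles: Sequence[str],
    ip_t: InteractionPotential,
    contact_lib: Sequence[tuple[str, str, ContactMatrix]],
    th: SelectionThresholds,
) -> list[ReceptorSequence]:
    """Filter a TCR repertoire through positive and negative selection.

    A clone survives iff (a) for at least one allele its mean score over
    that allele's presented self peptides reaches ``positive_min`` and
    (b) its maximum score over every (allele, self peptide) combination
    stays at or below ``negative_max``.  Survivors keep their input
    order; an empty survivor set is legal and logged prominently.
    """
    if not repertoire or not self_peptides or not mhc_alleles:
        raise ValueError("repertoire, self_peptides and mhc_alleles must be non-empty")
    codes = np.stack([encode(r.seq) for r in repertoire])
    positive_ok = np.zeros(len(repertoire), dtype=bool)
    negative_max_seen = np.full(len(repertoire), -np.inf)
    for allele in mhc_alleles:
        per_pep = np.stack(
            [
                pmhc_recognition_scores(codes, allele, pep, contact_lib, ip_t)
                for pep in self_peptides
            ]
        )  # (n_self, n_repertoire)
        positive_ok |= per_pep.mean(axis=0) >= th.positive_min
        negative_max_seen = np.maximum(negative_max_seen, per_pep.max(axis=0))
    survive = positive_ok & (negative_max_seen <= th.negative_max)
    survivors = [r for r, s in zip(repertoire, survive) if s]
    if not survivors:
        logger.warning(
            "thymus selection eliminated the entire repertoire "
            "(n=%d, positive_min=%g, negative_max=%g)",
            len(repertoire),
            th.positive_min,
            th.negative_max,
        )
    return survivors
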