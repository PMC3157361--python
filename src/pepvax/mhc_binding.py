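"""Peptide--MHC binding via position-specific scoring matrices (PSSMs).

A PSSM assigns one score per (position, amino acid); a peptide's binding
score is the sum over its positions.  The module scores peptides, ranks
the binding windows of a protein, maps scores to a presentation
probability, and implements the self-peptide similarity filter that keeps
only the 50 self peptides most similar to each injected peptide.

No third-party trained allele matrices are bundled; the PSSM reader
accepts any matrix in the documented tab-separated dialect, and a fixture
generator produces synthetic matrices for testing and simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._align import global_identity
from ._alphabet import AA_INDEX, AMINO_ACIDS, N_AA, encode

logger = logging.getLogger(__name__)


@dataclass
class Pssm:
    """Position x amino-acid score table for one MHC allele."""

    allele_id: str
    peptide_length: int
    scores: np.ndarray
    binder_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.binder_threshold = float(self.binder_threshold)
        if self.scores.shape != (self.peptide_length, N_AA):
            raise ValueError(
                f"PSSM must be {self.peptide_length}x{N_AA}, got {self.scores.shape}"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError("PSSM entries must be finite")

    def to_tsv(self) -> str:
        lines = [
            f"# pssm allele={self.allele_id} length={self.peptide_length} "
            f"binder_threshold={self.binder_threshold!r}",
            "\t" + "\t".join(AMINO_ACIDS),
        ]
        for i in range(self.peptide_length):
            lines.append(str(i) + "\t" + "\t".join(repr(float(v)) for v in self.scores[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "Pssm":
        allele = "unknown"
        threshold = 0.0
        col_order: list[str] | None = None
        rows: list[list[float]] = []
        for line in text.splitlines():
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("allele="):
                        allele = tok.split("=", 1)[1]
                    elif tok.startswith("binder_threshold="):
                        threshold = float(tok.split("=", 1)[1])
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "":
                col_order = parts[1:]
                continue
            rows.append([float(v) for v in parts[1:]])
        if col_order is None:
            raise ValueError("malformed PSSM: missing header row")
        table = np.zeros((len(rows), N_AA))
        for i, vals in enumerate(rows):
            for aa, v in zip(col_order, vals):
                table[i, AA_INDEX[aa]] = v
        return cls(allele, len(rows), table, threshold)


@dataclass(frozen=True)
class PredictedPeptide:
    sequence: str
    source_protein: str
    mhc_class: str  # "I" | "II"
    score: float
    start: int


PeptideSet = list  # list[PredictedPeptide]


def score_peptide(p: Pssm, pep: str) -> float:
    """Sum of per-position PSSM scores for a peptide of matching length."""
    codes = encode(pep)
    if len(codes) != p.peptide_length:
        raise ValueError(
            f"peptide length {len(codes)} != PSSM length {p.peptide_length}"
        )
    return float(p.scores[np.arange(p.peptide_length), codes].sum())


def predict_binders(
    protein: str,
    p: Pssm,
    top_k: int,
    source_protein: str = "protein",
    mhc_class: str = "I",
) -> PeptideSet:
    """Score every length-l window of a protein and keep the top k.

    Ties break toward the earlier start position.  When fewer windows
    exist than requested, all are returned (logged).
    """
    if len(protein) < p.peptide_length:
        raise ValueError("protein shorter than the PSSM peptide length")
    windows = [
        (protein[s : s + p.peptide_length], s)
        for s in range(len(protein) - p.peptide_length + 1)
    ]
    scored = [
        PredictedPeptide(w, source_protein, mhc_class, score_peptide(p, w), s)
        for w, s in windows
    ]
    if top_k > len(scored):
        logger.info(
            "top_k=%d exceeds the %d available windows; returning all", top_k, len(scored)
        )
        top_k = len(scored)
    scored.sort(key=lambda pp: (-pp.score, pp.start))
    return scored[:top_k]


def select_self_peptides(
    pool: Sequence[str], injected: str, k: int = 50
) -> list[str]:
    """The k pool peptides most similar to an injected peptide.

    Similarity is global-alignment identity; ties keep the earlier pool
    position.  Self peptides less similar than these cannot interfere
    with the injected peptide and are dropped to keep thymus selection
    fast.  Pools smaller than k are returned whole.
    """
    if not pool:
        raise ValueError("empty self-peptide pool")
    sims = [global_identity(p, injected) for p in pool]
    order = sorted(range(len(pool)), key=lambda i: (-sims[i], i))
    return [pool[i] for i in order[: min(k, len(pool))]]


def presentation_probability(
    score: float, p: Pssm, slope: float = 1.0
) -> float:
    """Logistic map from a PSSM score to a presentation probability.

    Centered on the matrix's binder threshold: a peptide scoring exactly
    at threshold is presented with probability 0.5, and the probability
    saturates toward 0/1 with distance from it at the configured slope.
    """
    return float(1.0 / (1.0 + np.exp(-(score - p.binder_threshold) / slope)))


def make_fixture_pssm(
    peptide_length: int,
    seed: int,
    allele_id: str = "SYN-ALLELE",
    favored_peptide: str | None = None,
    favor_bonus: float = 2.0,
) -> Pssm:
    """A synthetic PSSM for tests and simulation inputs.

    Entries are i.i.d. standard normal; when ``favored_peptide`` is given,
    its residues receive an additive bonus per position so that it becomes
    a clear top binder.  The binder threshold is set at the expected score
    of a uniform-random peptide plus one standard deviation.
    """
    rng = np.random.default_rng(seed)
    table = rng.normal(0.0, 1.0, size=(peptide_length, N_AA))
    if favored_peptide is not None:
        codes = encode(favored_peptide)
        if len(codes) != peptide_length:
            raise ValueError("favored peptide length mismatch")
        table[np.arange(peptide_length), codes] += favor_bonus
    mean_random = table.mean(axis=1).sum()
    sd_random = float(np.sqrt((table.var(axis=1)).sum()))
    return Pssm(allele_id, peptide_length, table, binder_threshold=mean_random + sd_random)
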