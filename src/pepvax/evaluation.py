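"""Validation of derived potentials: train/validation campaigns and
Mann-Whitney AUC.

The protocol mirrors a standard discrimination experiment: structures are
split 90/10 into training and validation sets, a potential is derived on
the training crystals only, and both crystal structures and freshly
generated decoys are scored with it.  Separation between crystal and
decoy scores is summarized as the Mann-Whitney AUC (the probability that
a random crystal outscores a random decoy, ties counted half) with a
two-sided significance test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .potential import (
    InteractionPotential,
    SurfaceComposition,
    derive_potential,
    make_decoy,
    score_complex,
)
from .structure_io import ComplexStructure


@dataclass
class ScoreSet:
    """Scores of one labelled group under one potential."""

    labels: list[str]            # "crystal" | "random", parallel to scores
    scores: list[float]
    potential_variant: str
    subset: str                  # "train" | "validation"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.scores):
            raise ValueError("labels and scores must have equal length")


def split_train_validation(
    structures: Sequence[ComplexStructure],
    frac_train: float = 0.9,
    seed: int | None = None,
) -> tuple[list[ComplexStructure], list[ComplexStructure]]:
    """Random disjoint 90/10 (by default) split, deterministic per seed.

    The training size is ``round(frac_train * n)`` with half-values rounded
    away from zero, so 33 structures split 30/3.
    """
    if not 0.0 < frac_train < 1.0:
        raise ValueError("frac_train must be in (0, 1)")
    n = len(structures)
    if n < 2:
        raise ValueError("need at least 2 structures to split")
    # round half away from zero (Python's round() is banker's rounding)
    n_train = int(np.floor(frac_train * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = [structures[i] for i in order[:n_train]]
    validation = [structures[i] for i in order[n_train:]]
    return train, validation


def mann_whitney_auc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, float]:
    """AUC = U / (n1*n2) with ties counted 0.5, plus a two-sided p-value.

    The p-value uses the exact Mann-Whitney distribution for small
    tie-free samples and the tie-corrected normal approximation otherwise.
    Fully tied inputs give (0.5, 1.0) by convention.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.concatenate([pos, neg])
    if np.all(pooled == pooled[0]):
        return 0.5, 1.0
    ranks = stats.rankdata(pooled)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = u / (len(pos) * len(neg))
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(len(pos), len(neg)) < 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(auc), p


@dataclass
class EvaluationReport:
    """Summary of one train/validation discrimination campaign."""

    variant: str
    n_train: int
    n_validation: int
    train_auc: float
    train_p: float
    validation_auc: float
    validation_p: float
    pooled_auc: float
    pooled_p: float
    group_stats: dict[str, tuple[float, float]]  # (mean, sd) per group
    potential: InteractionPotential = field(repr=False)
    score_sets: list[ScoreSet] = field(default_factory=list, repr=False)

    def to_text(self) -> str:
        lines = [
            f"potential variant: {self.variant}",
            f"structures: {self.n_train} train / {self.n_validation} validation",
            f"train AUC      = {self.train_auc:.4f} (p = {self.train_p:.3g})",
            f"validation AUC = {self.validation_auc:.4f} (p = {self.validation_p:.3g})",
            f"pooled AUC     = {self.pooled_auc:.4f} (p = {self.pooled_p:.3g})",
        ]
        for name, (mean, sd) in self.group_stats.items():
            lines.append(f"  {name}: mean {mean:+.4f} +/- {sd:.4f}")
        return "\n".join(lines) + "\n"

    def to_csv(self) -> str:
        rows = ["subset,label,score"]
        for ss in self.score_sets:
            for label, score in zip(ss.labels, ss.scores):
                rows.append(f"{ss.subset},{label},{score!r}")
        return "\n".join(rows) + "\n"


def _matrix_hash(ip: InteractionPotential) -> str:
    return hashlib.sha256(ip.matrix.tobytes()).hexdigest()


def evaluate_potential(
    crystal_set: Sequence[ComplexStructure],
    variant: str,
    comp: SurfaceComposition | None = None,
    decoys_per_structure: int = 1,
    frac_train: float = 0.9,
    seed: int = 0,
    potential: InteractionPotential | None = None,
) -> EvaluationReport:
    """Run the full split / derive / score / AUC campaign.

    The potential is derived from the *training* crystal structures only;
    validation crystals are scored with it against freshly generated
    decoys (never the training decoys), so no validation information can
    leak into the matrix.  Passing ``potential`` skips derivation and
    evaluates that matrix instead (e.g. a general contact table).
    """
    if comp is None:
        comp = SurfaceComposition.default()
    rng = np.random.default_rng(seed)
    train, validation = split_train_validation(crystal_set, frac_train, seed)

    if potential is None:
        potential = derive_potential(
            train, variant, comp, decoys_per_structure, rng
        )

    def campaign(structures: Sequence[ComplexStructure], subset: str) -> ScoreSet:
        labels, scores = [], []
        for c in structures:
            labels.append("crystal")
            scores.append(score_complex(c, potential))
        for c in structures:
            for _ in range(decoys_per_structure):
                labels.append("random")
                scores.append(score_complex(make_decoy(c, comp, rng), potential))
        return ScoreSet(labels, scores, potential.variant, subset)

    train_set = campaign(train, "train")
    val_set = campaign(validation, "validation")

    def group(ss: ScoreSet, label: str) -> list[float]:
        return [s for l, s in zip(ss.labels, ss.scores) if l == label]

    train_auc, train_p = mann_whitney_auc(group(train_set, "crystal"), group(train_set, "random"))
    val_auc, val_p = mann_whitney_auc(group(val_set, "crystal"), group(val_set, "random"))
    pooled_auc, pooled_p = mann_whitney_auc(
        group(train_set, "crystal") + group(val_set, "crystal"),
        group(train_set, "random") + group(val_set, "random"),
    )

    group_stats = {}
    for subset_name, ss in (("train", train_set), ("validation", val_set)):
        for label in ("crystal", "random"):
            vals = np.asarray(group(ss, label))
            group_stats[f"{subset_name}_{label}"] = (
                float(vals.mean()),
                float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            )

    return EvaluationReport(
        variant=variant,
        n_train=len(train),
        n_validation=len(validation),
        train_auc=train_auc,
        train_p=train_p,
        validation_auc=val_auc,
        validation_p=val_p,
        pooled_auc=pooled_auc,
        pooled_p=pooled_p,
        group_stats=group_stats,
        potential=potential,
        score_sets=[train_set, val_set],
    )
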