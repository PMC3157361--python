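"""Global-alignment sequence identity, shared by the self-peptide filter
and the MHC template mapping."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    # match 1, mismatch 0, unit gap cost
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_identity(a: str, b: str) -> float:
    """Fraction of identical positions in the best global alignment.

    Identities are counted in the optimal alignment and divided by the
    longer sequence length, giving a similarity in [0, 1] with 1.0 only
    for identical sequences.
    """
    if not a or not b:
        return 0.0
    alignment = _aligner().align(a, b)[0]
    identities = alignment.counts().identities
    return identities / max(len(a), len(b))
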