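"""The 20-letter amino-acid alphabet and integer encodings used package-wide.

Every matrix in the package (pair counts, interaction potentials, PSSMs)
is indexed in the fixed order :data:`AMINO_ACIDS`; sequences are encoded
as ``uint8`` arrays of indices into that order.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1_extended

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_AA: int = 20
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# three-letter -> standard one-letter, restricted to codes that land on a
# standard residue (MSE -> M etc.); anything else is non-mappable.
THREE_TO_ONE: dict[str, str] = {
    code3: code1
    for code3, code1 in protein_letters_3to1_extended.items()
    if len(code1) == 1 and code1 in AA_INDEX
}


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into :data:`AMINO_ACIDS`.

    Raises ``ValueError`` on any letter outside the 20-letter alphabet.
    """
    try:
        return np.fromiter((AA_INDEX[a] for a in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard amino-acid letter {exc.args[0]!r} in sequence") from exc


def decode(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[int(c)] for c in codes)
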