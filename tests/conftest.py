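import logging

import numpy as np
import pytest

from pepvax.potential import SurfaceComposition
from pepvax.synthetic import build_environment

logging.getLogger("pepvax").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def comp() -> SurfaceComposition:
    return SurfaceComposition.default()


@pytest.fixture(scope="session")
def env():
    """One shared synthetic study environment (potentials, templates,
    antigen, PSSMs, self peptides)."""
    return build_environment(0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_interface(c, cutoff=8.0):
    """Independent O(n^2) interface oracle: plain double loop, no numpy."""
    import math

    pairs = []
    for r in c.receptor_residues:
        for l in c.ligand_residues:
            d = math.dist(r.ca_xyz, l.ca_xyz)
            if d <= cutoff:
                pairs.append((r, l, d))
    return pairs
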