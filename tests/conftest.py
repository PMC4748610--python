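import logging

import numpy as np
import pytest

from cprselect.alignment import CprAlignment
from cprselect.motifs import toy_motif_set

logging.getLogger("msprime").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def motifs():
    return toy_motif_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_alignment(rng, n=4, L=20, cpr_id="cpr"):
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=L)]
    seqs = np.tile(ref, (n, 1))
    # sprinkle some variants
    for _ in range(max(L // 4, 1)):
        j = rng.integers(0, L)
        row = rng.integers(0, n)
        seqs[row, j] = bases[rng.integers(0, 4)]
    return CprAlignment(
        cpr_id=cpr_id, chrom="chr", start=0, end=L, strand="+",
        line_ids=[f"l{i}" for i in range(n)], seqs=seqs,
    )


@pytest.fixture()
def make_alignment():
    return CprAlignment.from_strings
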