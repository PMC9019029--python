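import numpy as np
import pytest

from betapipe import sketch as sketchmod
from betapipe.simdata import ReadSet


def random_dna(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def make_readset(seqs, quals=None, paired=False, names=None) -> ReadSet:
    """Small hand-built read set; quals default to Q40."""
    if quals is None:
        quals = [np.full(len(s), 40, dtype=np.uint8) for s in seqs]
    else:
        quals = [np.asarray(q, dtype=np.uint8) for q in quals]
    if names is None:
        names = [f"r{i}" for i in range(len(seqs))]
    return ReadSet(names, list(seqs), quals, paired=paired)


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    # compile the k-mer scan kernel once so timings inside tests are stable
    sketchmod.build_sketch("ACGT" * 20, name="warm", k=5, s=4, m=1)
    yield
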