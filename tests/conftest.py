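import numpy as np
import pytest

from ovitrace.seqio import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_alignment(rng, n, L, mutate_prob=0.15, metadata=False):
    """Small random alignment: a base sequence plus per-cell mutations."""
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, L)
    M = np.tile(root, (n, 1))
    mask = rng.random((n, L)) < mutate_prob
    M[mask] = rng.choice(bases, mask.sum())
    ids = [f"t{i}" for i in range(n)]
    meta = None
    if metadata:
        meta = {
            i: {"breed": f"b{k % 2}", "region": "r0", "haplogroup": ""}
            for k, i in enumerate(ids)
        }
    return Alignment(ids, ["".join(row) for row in M], meta)


@pytest.fixture
def small_alignment(rng):
    return random_alignment(rng, 6, 20)


@pytest.fixture
def four_singleton():
    """n=4 with exactly one singleton site: the hand-checked fixture for
    Tajima's D (-0.612) and Fu & Li's D*/F*."""
    return Alignment(["a", "b", "c", "d"], ["AAAA", "AAAA", "AAAA", "AAAT"])
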