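import numpy as np
import pytest

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = [b for b in "ACGT" if b != out[i]][rng.integers(0, 3)]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
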