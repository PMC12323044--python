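import numpy as np
import pytest

from layersim import GenomeRef


@pytest.fixture
def toy_genome() -> GenomeRef:
    return GenomeRef([("chr1", "ACGT" * 2500)])  # 10 kb


def random_sequence(rng: np.random.Generator, length: int,
                    n_frac: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=length)]
    if n_frac > 0:
        seq[rng.random(length) < n_frac] = "N"
    return "".join(seq)
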