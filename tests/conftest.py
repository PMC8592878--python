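import numpy as np
import pytest

from parse_llps import generate_sequence


@pytest.fixture(scope="session")
def natural_500():
    """A 500-residue average-composition sequence, fixed seed."""
    return generate_sequence("natural", 500, seed=20210)


@pytest.fixture(scope="session")
def natural_records():
    """Thirty average-composition records of varying length."""
    rng = np.random.default_rng(7)
    return [
        generate_sequence("natural", int(n), seed=int(s), seq_id=f"nat{i}")
        for i, (n, s) in enumerate(zip(rng.integers(50, 300, 30), rng.integers(0, 2**31, 30)))
    ]
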