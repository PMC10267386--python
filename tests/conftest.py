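import numpy as np
import pytest

from casagm import MutationMatrix


@pytest.fixture
def worked_example() -> MutationMatrix:
    """The 3x3 matrix with non-zeros at (0,0),(0,2),(1,2),(2,0),(2,1),(2,2).

    Values 1..6 stand in for the six symbolic entries, numbered in
    row-major order.
    """
    return MutationMatrix(
        ["s0", "s1", "s2"],
        ["g0", "g1", "g2"],
        np.array([[1, 0, 2], [0, 0, 3], [4, 5, 6]]),
    )


def random_matrix(rng: np.random.Generator, m: int, n: int, density: float,
                  signed: bool = False, real: bool = False) -> MutationMatrix:
    """Seeded random test matrix with roughly the requested density."""
    nnz = max(0, min(m * n, round(density * m * n)))
    cells = rng.choice(m * n, size=nnz, replace=False)
    flat = np.zeros(m * n, dtype=np.float64 if real else np.int64)
    if real:
        vals = rng.normal(size=nnz)
        vals[vals == 0] = 1.0
    else:
        lo = -9 if signed else 1
        vals = rng.integers(1, 10, size=nnz)
        if signed:
            vals *= rng.choice([-1, 1], size=nnz)
    flat[cells] = vals
    A = flat.reshape(m, n)
    return MutationMatrix([f"s{i}" for i in range(m)], [f"g{j}" for j in range(n)], A)
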