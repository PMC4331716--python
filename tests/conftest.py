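import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mfselector import canonicalize_design
from mfselector.examples import five_stage_demo


@pytest.fixture(scope="session")
def demo():
    """The built-in 20-sample five-stage profile: (values, design)."""
    return five_stage_demo()


@pytest.fixture
def small_design():
    """Three stages of sizes (2, 3, 2)."""
    labels = ["A", "A", "B", "B", "B", "C", "C"]
    samples = [f"s{i}" for i in range(7)]
    return canonicalize_design(dict(zip(samples, labels)), ("A", "B", "C"), samples)


def random_instance(rng, max_samples=15, max_stages=5):
    """A random small (values, stages, design) triple for oracle checks."""
    n = int(rng.integers(3, max_stages + 1))
    sizes = rng.integers(1, max(2, max_samples // n) + 1, size=n)
    while sizes.sum() < n + 1:
        sizes[int(rng.integers(0, n))] += 1
    total = int(sizes.sum())
    stages = [i + 1 for i in range(n) for _ in range(int(sizes[i]))]
    samples = list(range(total))
    design = canonicalize_design(
        dict(zip(samples, stages)), tuple(range(1, n + 1)), samples
    )
    # duplicate values now and then, to exercise the equality rule
    if rng.random() < 0.3:
        values = rng.integers(0, 6, size=total).astype(float)
    else:
        values = rng.normal(size=total)
    return values, stages, design
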