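import numpy as np
import pytest

from nucmap import CenterKernel, GenomicRegion
from nucmap.simulate import MotifPlacement, RegionSpec, SimConfig, make_world


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def kernel():
    return CenterKernel()


@pytest.fixture
def small_region():
    return GenomicRegion(name="reg", chrom="chr1", start=10_000, end=12_000)


@pytest.fixture
def small_world():
    """Two 4 kb regions with three planted motifs each (seeded, cheap)."""
    placements = [
        MotifPlacement("regA", 500, "+", functional=True),
        MotifPlacement("regA", 1500, "-", functional=False),
        MotifPlacement("regA", 2500, "+", functional=False),
        MotifPlacement("regB", 700, "-", functional=True),
        MotifPlacement("regB", 1900, "+", functional=False),
        MotifPlacement("regB", 3100, "+", functional=True),
    ]
    config = SimConfig(
        seed=42,
        regions=[RegionSpec("regA", 4000, gene_class="class2_poised"),
                 RegionSpec("regB", 4000, gene_class="class1_active")],
        placements=placements,
        depth=20_000,
    )
    return make_world(config)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
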