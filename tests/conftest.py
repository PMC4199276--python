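import numpy as np
import pytest

from axodiff.protocol import table_fixtures
from axodiff.substrates import CylinderSubstrate


@pytest.fixture(scope="session")
def fixtures():
    """The built-in ActiveAx protocol fixtures (seeded direction sets)."""
    return table_fixtures(seed=0)


@pytest.fixture(scope="session")
def proto300(fixtures):
    return fixtures["ActiveAx300"]


@pytest.fixture(scope="session")
def proto060(fixtures):
    return fixtures["ActiveAx060"]


@pytest.fixture()
def single_cylinder():
    """One 4 um cylinder centred in a roomy periodic cell."""
    d = 4.0
    return CylinderSubstrate(cell_size=2 * d, centers=[[d, d]], radii=[d / 2])


def brute_force_overlap(sub: CylinderSubstrate) -> bool:
    """Independent overlap oracle: all pairs against all 9 periodic images."""
    n = sub.n_cylinders
    L = sub.cell_size
    shifts = [(i * L, j * L) for i in (-1, 0, 1) for j in (-1, 0, 1)]
    for i in range(n):
        for j in range(n):
            for sx, sy in shifts:
                if i == j and sx == 0 and sy == 0:
                    continue
                dx = sub.centers[i, 0] - sub.centers[j, 0] - sx
                dy = sub.centers[i, 1] - sub.centers[j, 1] - sy
                if dx * dx + dy * dy < (sub.radii[i] + sub.radii[j]) ** 2:
                    return True
    return False
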