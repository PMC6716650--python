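import numpy as np
import pytest

from arealscan import Region, StudyArea
from arealscan.simulate import generate, scenario_suite


def make_area(xs, ys, pops, cases, ids=None, mode="planar"):
    n = len(xs)
    ids = ids or [chr(ord("A") + i) for i in range(n)]
    regions = [
        Region(id=ids[i], name=ids[i], x=float(xs[i]), y=float(ys[i]),
               population=int(pops[i]), cases=int(cases[i]))
        for i in range(n)
    ]
    return StudyArea(regions, coordinate_mode=mode)


@pytest.fixture
def collinear_area():
    """Three equal-population regions on a line at x = 0, 1, 3."""
    return make_area([0, 1, 3], [0, 0, 0], [100, 100, 100], [3, 3, 3])


@pytest.fixture(scope="session")
def florida_like():
    """67 irregular regions, log-uniform populations, largest = 13% of total."""
    area, _ = generate(scenario_suite()["florida-like"], seed=42)
    return area


@pytest.fixture(scope="session")
def disk_area():
    """10x10 uniform grid with a 5-cell disk hotspot at relative risk 2."""
    area, truth = generate(scenario_suite()["disk-hotspot"], seed=7)
    return area, truth
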