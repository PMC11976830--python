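import math
import random

import pytest

from rodsphere import LJParams, Rod, Sphere, min_distance_to_rod
from rodsphere.mechanics import config_from_xc_h


@pytest.fixture(scope="session")
def lj():
    return LJParams()


def make_config(rng: random.Random, branch: str = "any", a_range=(2.0, 15.0),
                L_range=(1.0, 20.0), margin=0.3):
    """Random non-overlapping sphere-rod configuration.

    `branch` targets the geometric regime of the rod axis relative to the
    sphere: 'gt' (axis clears the sphere), 'lt' (axis pierces it, rod
    outside), 'near' (|h-a| < 0.01), or 'any'.
    """
    while True:
        a = rng.uniform(*a_range)
        L = rng.uniform(*L_range)
        if branch == "gt":
            h = a + rng.uniform(0.5, 6.0)
        elif branch == "lt":
            h = rng.uniform(0.15 * a, max(0.2 * a, a - 0.3))
        elif branch == "near":
            h = a + rng.uniform(-0.009, 0.009)
        else:
            h = rng.uniform(0.15 * a, a + 6.0)
        if h > a + margin and rng.random() < 0.5:
            xc = rng.uniform(-5.0, L + 5.0)  # rod may straddle the closest point
        else:
            # keep the whole rod on one side, clear of the sphere
            ycrit = math.sqrt(max((a + margin) ** 2 - h * h, 0.0)) + rng.uniform(0.05, 8.0)
            xc = -ycrit if rng.random() < 0.5 else L + ycrit
        c = config_from_xc_h(xc, h, L)
        if min_distance_to_rod(c) > a + margin:
            return c, Sphere(a=a), Rod(L=L)


@pytest.fixture(scope="session")
def config_factory():
    return make_config
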