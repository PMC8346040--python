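from __future__ import annotations

import numpy as np
import pytest

from fibrecontact import MaskStack


def random_instance(rng: np.random.Generator, shape=(8, 32, 32)):
    """One random test instance: sparse collagen candidates plus a compact
    cell blob (a jittered per-slice disc), as boolean (z, y, x) stacks."""
    nz, ny, nx = shape
    collagen = rng.random(shape) < 0.12
    cy, cx = rng.uniform(ny * 0.25, ny * 0.75), rng.uniform(nx * 0.25, nx * 0.75)
    radius = rng.uniform(3.0, 6.0)
    cell = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for z in range(nz):
        jy, jx = rng.uniform(-1.5, 1.5, size=2)
        cell[z] = (yy - cy - jy) ** 2 + (xx - cx - jx) ** 2 <= radius**2
    return collagen, cell


@pytest.fixture
def rng():
    return np.random.default_rng(20210721)


@pytest.fixture
def small_instance(rng):
    collagen, cell = random_instance(rng)
    return MaskStack(collagen), MaskStack(cell)
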