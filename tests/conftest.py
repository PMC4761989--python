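import numpy as np
import pytest

from pedseg.io import Surface
from pedseg.phantom import CapSpec, PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free desk phantom with one PED cap (session-cached)."""
    params = PhantomParams(seed=7, speckle_scale=0.0)
    volume, truth = generate_phantom(params)
    return params, volume, truth


@pytest.fixture(scope="session")
def speckled_phantom():
    """Speckled phantom with a PED and a confounding fluid pocket."""
    params = PhantomParams(
        seed=11,
        speckle_scale=0.25,
        confounders=(CapSpec(26.0, 5.0, 9.0, 3.0, 7.0),),
    )
    volume, truth = generate_phantom(params)
    return params, volume, truth


@pytest.fixture()
def flat_surfaces():
    """Four flat ordered surfaces on a 30-column single-B-scan grid."""
    levels = {"ILM": 5, "EZ_ROOF": 10, "RPE_FLOOR": 28, "BM": 32}
    return {n: Surface(n, np.full((30, 1), z)) for n, z in levels.items()}


def brute_force_surface(cost2d: np.ndarray, delta: int):
    """Exhaustive minimum-cost surface of a 2D (nx, nz) cost raster.

    Returns (cost, heights) with ties broken lexicographically toward
    smaller z — the independent oracle for the graph search.
    """
    import itertools

    nx, nz = cost2d.shape
    best = None
    for comb in itertools.product(range(nz), repeat=nx):
        if any(abs(comb[i + 1] - comb[i]) > delta for i in range(nx - 1)):
            continue
        c = sum(cost2d[i, comb[i]] for i in range(nx))
        if best is None or c < best[0] - 1e-12 or (
            abs(c - best[0]) <= 1e-12 and comb < best[1]
        ):
            best = (c, comb)
    return best
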