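import numpy as np
import pytest

from lungmorph.geometry import Region
from lungmorph.synth import _disc_idx


def disc_region(radius_px: float, pixel_size: float = 1.0) -> Region:
    """Rasterised disc using the package footprint convention: the pixel
    squares of the region span the requested diameter."""
    side = int(np.ceil(radius_px)) * 2 + 5
    c = side // 2
    yy, xx = _disc_idx((side, side), c, c, radius_px)
    return Region(np.stack([yy, xx], axis=1), pixel_size)


def rect_region(h: int, w: int, pixel_size: float = 1.0) -> Region:
    yy, xx = np.mgrid[0:h, 0:w]
    return Region(np.stack([yy.ravel(), xx.ravel()], axis=1), pixel_size)


def random_blob(rng, max_pixels: int = 400, pixel_size: float = 1.0) -> Region:
    """A random connected blob grown by a lattice walk from the origin."""
    n = int(rng.integers(1, max_pixels))
    pos = np.zeros(2, dtype=int)
    seen = {(0, 0)}
    moves = np.array([(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, -1), (1, -1), (-1, 1)])
    while len(seen) < n:
        pos = pos + moves[rng.integers(0, 8)]
        seen.add((int(pos[0]), int(pos[1])))
    px = np.array(sorted(seen))
    px -= px.min(axis=0)
    return Region(px, pixel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
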