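import numpy as np
import pytest

import ftumask as fm


def naive_stroked_mask(plane: np.ndarray, stroke_width: int) -> np.ndarray:
    """Reference implementation of the stroked rule: explicit per-pixel loop
    over the eight compass lookups at offset ``stroke_width``, out-of-bounds
    reading background.  Kept deliberately independent of the vectorized path.
    """
    h, w = plane.shape
    out = np.zeros((h, w), dtype=bool)
    dirs = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    for r in range(h):
        for c in range(w):
            v = plane[r, c]
            if v == 0:
                continue
            for dr, dc in dirs:
                rr, cc = r + dr * stroke_width, c + dc * stroke_width
                nb = plane[rr, cc] if 0 <= rr < h and 0 <= cc < w else 0
                if nb != v:
                    out[r, c] = True
                    break
    return out


def random_label_plane(rng: np.random.Generator, shape, n_blobs: int) -> np.ndarray:
    """Random multi-instance plane with border-touching blobs allowed."""
    h, w = shape
    plane = np.zeros((h, w), dtype=np.int64)
    for i in range(1, n_blobs + 1):
        r = int(rng.integers(1, max(2, min(h, w) // 3)))
        cr = int(rng.integers(0, h))  # centers may fall near the border
        cc = int(rng.integers(0, w))
        yy, xx = np.ogrid[:h, :w]
        plane[(yy - cr) ** 2 + (xx - cc) ** 2 <= r**2] = i
    return plane


@pytest.fixture(scope="session")
def default_dataset():
    """Standard kidney-like fixture plus ground truth (seed 7)."""
    return fm.generate_dataset(fm.default_spec(seed=7))


@pytest.fixture()
def small_dataset():
    """A tiny hand-built conformant dataset for seeding violations."""
    plane = np.zeros((8, 8), dtype=np.int64)
    plane[1:3, 1:3] = 1
    plane[5:7, 5:7] = 2
    ch = fm.BitmaskChannel("glomerulus", plane)
    table = fm.FeatureTable.from_columns(
        "glomerulus", [1, 2], {"area": [4.0, 4.0]}
    )
    image = np.full((8, 8, 3), 240, dtype=np.uint8)
    return fm.SegmentationDataset(
        bitmask=fm.MultiChannelBitmask([ch]),
        image=image,
        tables={"glomerulus": table},
    )
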