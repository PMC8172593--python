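import numpy as np
import pytest

import roakit as rk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_movie(rng):
    """10-frame 8x8 uint16 stack with distinct values per voxel."""
    return rng.integers(0, 1000, size=(10, 8, 8)).astype(np.uint16)


@pytest.fixture
def meta_30hz():
    return rk.MovieMeta(n_frames=10, height=8, width=8, frame_rate=30.0,
                        pixel_size=1.0)


@pytest.fixture
def tiff_movie(tmp_path, small_movie, meta_30hz):
    return rk.write_movie(tmp_path / "movie.tif", small_movie, meta_30hz)


@pytest.fixture
def hdf5_movie(tmp_path, small_movie, meta_30hz):
    return rk.write_movie(tmp_path / "movie.h5", small_movie, meta_30hz)


def bfs_label(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Brute-force flood-fill labeling oracle (breadth-first search)."""
    mask = np.asarray(mask, dtype=bool)
    offsets = []
    for dt in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dt, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dt) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dt, dy, dx))
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    T, H, W = mask.shape
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        queue = [start]
        labels[start] = current
        while queue:
            t, y, x = queue.pop()
            for dt, dy, dx in offsets:
                u, v, w = t + dt, y + dy, x + dx
                if 0 <= u < T and 0 <= v < H and 0 <= w < W \
                        and mask[u, v, w] and not labels[u, v, w]:
                    labels[u, v, w] = current
                    queue.append((u, v, w))
    return labels


@pytest.fixture
def flood_fill_oracle():
    return bfs_label
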