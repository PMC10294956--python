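import numpy as np
import pytest

import voxel2id as v


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_case():
    """One class-A phantom case (32x32x16), shared across tests."""
    spec = v.PhantomSpec(shape=(32, 32, 16), class_label="A", seed=11)
    phases, labels = v.generate_phantom(spec)
    return phases, labels


@pytest.fixture(scope="session")
def small_identity(small_case):
    phases, labels = small_case
    return v.transform_case(phases, labels, v.TransformConfig(), case_id="c0")


def glrlm_line_walk_oracle(slice_levels, G, direction):
    """Brute-force run-length matrix: walk every line, split into maximal
    constant segments with explicit loops.  Independent of the package's
    vectorized construction."""
    arr = np.asarray(slice_levels)
    h, w = arr.shape
    if direction == 0:
        lines = [list(arr[r, :]) for r in range(h)]
    elif direction == 90:
        lines = [list(arr[:, c]) for c in range(w)]
    elif direction == 135:
        lines = [list(np.diagonal(arr, offset=o))
                 for o in range(-(h - 1), w)]
    elif direction == 45:
        lines = [list(np.diagonal(arr[::-1, :], offset=o))
                 for o in range(-(h - 1), w)]
    else:
        raise ValueError(direction)
    runs = []
    for line in lines:
        k = 0
        while k < len(line):
            j = k
            while j < len(line) and line[j] == line[k]:
                j += 1
            runs.append((int(line[k]), j - k))
            k = j
    R = max((length for _, length in runs), default=1)
    counts = np.zeros((G, R), dtype=np.int64)
    for level, length in runs:
        counts[level, length - 1] += 1
    return counts


def kronecker_histogram_oracle(slice_levels, G):
    """Histogram by explicit double loop with the delta-counting rule."""
    arr = np.asarray(slice_levels)
    counts = np.zeros(G, dtype=np.int64)
    for x in range(arr.shape[0]):
        for y in range(arr.shape[1]):
            for i in range(G):
                if arr[x, y] == i:
                    counts[i] += 1
    return counts
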