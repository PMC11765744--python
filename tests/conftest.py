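import numpy as np
import pytest

import zoocnn as z


@pytest.fixture(scope="session")
def small_imageset():
    """Imbalanced three-class corpus at 1/10 of the reference counts."""
    return z.generate_images({0: 278, 1: 158, 2: 149}, side=32, seed=1)


@pytest.fixture(scope="session")
def tiny_imageset():
    return z.generate_images({0: 30, 1: 20, 2: 18}, side=16, seed=0)


@pytest.fixture()
def gaussian_clusters():
    """Imbalanced 2-D clusters with overlapping boundary (ADASYN testbed)."""
    return z.generate_clusters(
        {0: 200, 1: 60},
        2,
        {0: (0.0, 0.0), 1: (2.0, 2.0)},
        spread=1.0,
        seed=7,
    )


def brute_force_knn_difficulty(points, labels, minority_label, k):
    """Independent oracle: per-minority-point non-minority k-NN fraction."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    out = []
    for i in np.flatnonzero(labels == minority_label):
        d = np.linalg.norm(points - points[i], axis=1)
        order = [j for j in np.argsort(d, kind="stable") if j != i][:k]
        out.append(sum(labels[j] != minority_label for j in order) / k)
    return np.array(out)
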