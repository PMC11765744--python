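"""ADASYN adaptive synthetic oversampling.

ADASYN rebalances a minority class toward the majority by generating
synthetic points along segments between minority points and their minority
neighbours, allocating more synthetic points to minority points whose
k-nearest-neighbour neighbourhood contains many non-minority points — the
"hard" boundary regions where a classifier struggles.

For minority class sizes ``m_s`` vs majority ``m_l`` and balance level
``beta`` in [0, 1]:

    G      = round(beta * (m_l - m_s))            total synthetic count
    r_i    = Delta_i / k                          Delta_i = non-minority
                                                  points among the k-NN of
                                                  minority point i
    r_hat  = r_i / sum_j r_j                      (uniform if all r are 0)
    g_i    = largest-remainder apportionment of G proportional to r_hat

Each synthetic point is ``x_i + lam * (x_z - x_i)`` with ``lam ~ U[0,1]``
and ``x_z`` one of x_i's k nearest *minority* neighbours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data import ClusterSet, LabeledImageSet

__all__ = ["AdasynPlan", "compute_plan", "synthesize_samples", "balance_dataset"]


@dataclass
class AdasynPlan:
    """Per-minority-point synthesis plan for one minority class."""

    minority_label: int
    G: int
    ratios: np.ndarray  # normalized difficulty r_hat_i, sums to 1 when G > 0
    counts: np.ndarray  # g_i, non-negative ints summing to G
    k: int
    beta: float
    minority_indices: np.ndarray  # indices of minority points in the dataset

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = asdict(self)
        for key in ("ratios", "counts", "minority_indices"):
            payload[key] = np.asarray(payload[key]).tolist()
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _as_matrix(data: Union[ClusterSet, LabeledImageSet]) -> np.ndarray:
    if isinstance(data, LabeledImageSet):
        return data.flattened()
    return data.points


def _largest_remainder(ratios: np.ndarray, G: int) -> np.ndarray:
    """Integer apportionment of G proportional to ratios, sums exactly to G."""
    quotas = ratios * G
    counts = np.floor(quotas).astype(int)
    short = G - counts.sum()
    if short > 0:
        remainders = quotas - counts
        # stable tie-break: larger remainder first, then lower index
        order = np.lexsort((np.arange(len(ratios)), -remainders))
        counts[order[:short]] += 1
    return counts


def compute_plan(
    data: Union[ClusterSet, LabeledImageSet],
    minority_label: int,
    k: int = 5,
    beta: float = 1.0,
) -> AdasynPlan:
    """Compute the ADASYN plan for one minority class.

    The difficulty of each minority point is the fraction of non-minority
    points among its k nearest neighbours in the full dataset (Euclidean,
    excluding the point itself).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = _as_matrix(data)
    y = np.asarray(data.labels)
    n = len(y)
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the dataset size ({n})")

    minority_idx = np.flatnonzero(y == minority_label)
    m_s = len(minority_idx)
    if m_s < 1:
        raise ValueError(f"minority class {minority_label} is empty")
    counts_by_class = {c: int((y == c).sum()) for c in np.unique(y)}
    m_l = max(counts_by_class.values())

    if m_s >= m_l:
        # already the (joint) majority: nothing to synthesize
        zeros = np.zeros(m_s)
        return AdasynPlan(
            minority_label, 0, zeros, zeros.astype(int), k, beta, minority_idx
        )

    G = int(round(beta * (m_l - m_s)))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, neigh = nn.kneighbors(X[minority_idx])
    # drop self; the query point is always its own 0-distance neighbour but
    # ties can reorder it, so mask by index rather than slicing column 0
    r = np.empty(m_s)
    for row, i in enumerate(minority_idx):
        others = neigh[row][neigh[row] != i][:k]
        r[row] = np.sum(y[others] != minority_label) / k

    total = r.sum()
    ratios = r / total if total > 0 else np.full(m_s, 1.0 / m_s)
    counts = _largest_remainder(ratios, G) if G > 0 else np.zeros(m_s, dtype=int)
    return AdasynPlan(minority_label, G, ratios, counts, k, beta, minority_idx)


def synthesize_samples(
    data: Union[ClusterSet, LabeledImageSet],
    plan: AdasynPlan,
    seed: int = 0,
) -> np.ndarray:
    """Generate plan.G synthetic minority points (rows of the feature matrix).

    Outputs from image datasets are clipped to [0, 1].
    """
    X = _as_matrix(data)
    if plan.minority_indices.size and plan.minority_indices.max() >= len(X):
        raise ValueError("plan does not match data (index out of range)")
    if plan.G == 0:
        return np.empty((0, X.shape[1]))

    rng = np.random.default_rng(seed)
    minority = X[plan.minority_indices]
    m_s = len(minority)
    k_eff = min(plan.k, m_s - 1)

    if k_eff >= 1:
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority)
        _, neigh = nn.kneighbors(minority)

    out = np.empty((plan.G, X.shape[1]))
    pos = 0
    for row in range(m_s):
        g = int(plan.counts[row])
        if g == 0:
            continue
        x_i = minority[row]
        if k_eff >= 1:
            candidates = neigh[row][neigh[row] != row][:k_eff]
        else:  # single minority point: only itself available
            candidates = np.array([row])
        z = rng.integers(0, len(candidates), size=g)
        lam = rng.uniform(0.0, 1.0, size=g)
        x_z = minority[candidates[z]]
        out[pos : pos + g] = x_i + lam[:, None] * (x_z - x_i)
        pos += g

    if isinstance(data, LabeledImageSet):
        out = np.clip(out, 0.0, 1.0)
    return out


def balance_dataset(
    dataset: LabeledImageSet,
    k: int = 5,
    beta: float = 1.0,
    seed: int = 0,
) -> LabeledImageSet:
    """Rebalance every minority class of an image set toward the majority.

    Each minority class gets its own plan + synthesis pass over flattened
    pixel vectors; with ``beta=1`` all class counts end within 1 of the
    majority count.  Original samples are kept untouched; synthetic rows are
    flagged ``"synthetic"`` in the provenance.
    """
    counts = dataset.class_counts()
    if len(counts) < 2:
        raise ValueError("balancing needs at least 2 classes")
    if beta == 0.0:
        return dataset

    majority = max(counts.values())
    side = dataset.side
    new_images = [dataset.images]
    new_labels = [dataset.labels]
    provenance = list(dataset.provenance)
    rng = np.random.default_rng(seed)
    for label in sorted(counts):
        if counts[label] >= majority:
            continue
        plan = compute_plan(dataset, label, k=k, beta=beta)
        synth = synthesize_samples(dataset, plan, seed=int(rng.integers(2**31)))
        if len(synth) == 0:
            continue
        new_images.append(synth.reshape(-1, side, side))
        new_labels.append(np.full(len(synth), label, dtype=np.int64))
        provenance.extend(["synthetic"] * len(synth))

    return LabeledImageSet(
        np.concatenate(new_images),
        np.concatenate(new_labels),
        dataset.class_names,
        provenance,
    )
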