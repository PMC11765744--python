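"""Sequential classification-based derivative-free optimization (SRACOS).

The optimizer minimizes a black-box objective over the hyperparameter
space using only function evaluations.  It first evaluates a uniform
population, then iterates: the evaluated points are split into a small
*positive* set (the best ones) and a *negative* set; a new candidate is
drawn either uniformly from the whole space (exploration, with a
probability annealed linearly from ``explore_start`` to ``explore_end``)
or from an axis-aligned box learned around a random positive point and
shrunk until it excludes the retained negatives (exploitation).  The best
point seen so far is the incumbent; search stops at the evaluation budget
or after ``patience`` iterations without improvement.

All geometry happens in normalized ``[0, 1]^d`` coordinates (the learning
rate on a log scale), so the step size is a fraction of each interval.

A random linear embedding is also provided to optimize through a
lower-dimensional subspace: ``g(y) = f(decode(lift(y)))`` with a fixed
Gaussian matrix, useful when most coordinates barely matter.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .space import (
    CODEC_LENGTH,
    HyperConfig,
    SearchSpace,
    decode_vector,
    denormalize_vector,
    encode_config,
    normalize_vector,
)

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "EmbeddingMap",
    "sracos_optimize",
    "sracos_minimize",
    "learn_sampling_region",
    "exploration_probability",
    "make_random_embedding",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Search schedule (defaults follow the published tuning recipe)."""

    budget: int = 300
    population: int = 50
    explore_start: float = 0.6
    explore_end: float = 0.3
    step_size: float = 0.1
    patience: int = 30
    positive_set_size: Optional[int] = None  # default: 1 + population // 10
    re_evaluations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.explore_end <= self.explore_start <= 1.0:
            raise ValueError("need 0 <= explore_end <= explore_start <= 1")
        if self.budget < self.population:
            raise ValueError("budget must be >= population")
        if self.re_evaluations < 1:
            raise ValueError("re_evaluations must be >= 1")

    @property
    def n_positive(self) -> int:
        if self.positive_set_size is not None:
            return self.positive_set_size
        return 1 + self.population // 10


@dataclass
class TraceRecord:
    iteration: int
    candidate: object  # HyperConfig or normalized vector
    value: float
    best_so_far: float


@dataclass
class OptimizationTrace:
    records: list[TraceRecord] = field(default_factory=list)
    best_candidate: object = None
    best_value: float = np.inf
    evaluations_used: int = 0

    @property
    def best_config(self):
        return self.best_candidate

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["iteration", "candidate", "value", "best_so_far"])
            for r in self.records:
                cand = (
                    json.dumps(r.candidate.to_dict())
                    if isinstance(r.candidate, HyperConfig)
                    else json.dumps(np.asarray(r.candidate).tolist())
                )
                writer.writerow([r.iteration, cand, r.value, r.best_so_far])

    def summary(self) -> dict:
        best = self.best_candidate
        return {
            "best_value": float(self.best_value),
            "best_candidate": (
                best.to_dict()
                if isinstance(best, HyperConfig)
                else np.asarray(best).tolist()
            ),
            "evaluations_used": self.evaluations_used,
        }


def exploration_probability(
    iteration: int, total_iterations: int, config: OptimizerConfig = OptimizerConfig()
) -> float:
    """Linear anneal from explore_start (iteration 0) to explore_end."""
    if total_iterations <= 0:
        return config.explore_end
    frac = min(max(iteration / total_iterations, 0.0), 1.0)
    return config.explore_start + frac * (config.explore_end - config.explore_start)


def learn_sampling_region(
    positives: Sequence[np.ndarray],
    negatives: Sequence[np.ndarray],
    space: SearchSpace,
    step_size: float,
    rng: np.random.Generator,
    anchor_index: Optional[int] = None,
    max_shrinks: int = 100,
    n_free: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned sub-box of [0,1]^d around a positive point.

    Starts at half-width ``step_size`` (a fraction of each normalized
    interval) around the anchor, then repeatedly picks a retained negative
    still inside the box and shrinks one coordinate (chosen uniformly among
    those that can exclude it while keeping the anchor inside) to a random
    cut between the anchor and the negative.  Stops when every negative is
    excluded or the shrink cap is reached.  With ``n_free`` set, all but
    ``n_free`` randomly chosen coordinates are finally clamped to the
    anchor's exact values (randomized coordinate shrinking), so candidates
    drawn from the box perturb only a few coordinates at a time.  The
    anchor always remains inside.
    """
    if len(positives) == 0:
        raise ValueError("need at least one positive point")
    positives = [np.asarray(p, dtype=float) for p in positives]
    if anchor_index is None:
        anchor_index = int(rng.integers(len(positives)))
    anchor = positives[anchor_index]
    lo = np.clip(anchor - step_size, 0.0, 1.0)
    hi = np.clip(anchor + step_size, 0.0, 1.0)

    retained = [np.asarray(n, dtype=float) for n in negatives]
    for _ in range(max_shrinks):
        inside = [
            n for n in retained if np.all(n >= lo - 1e-12) and np.all(n <= hi + 1e-12)
        ]
        if not inside:
            break
        neg = inside[int(rng.integers(len(inside)))]
        dims = np.flatnonzero(np.abs(neg - anchor) > 1e-12)
        if dims.size == 0:  # duplicate of the anchor: cannot be excluded
            retained = [n for n in retained if n is not neg]
            continue
        d = int(dims[int(rng.integers(dims.size))])
        cut = anchor[d] + rng.uniform(0.0, 1.0) * (neg[d] - anchor[d])
        if neg[d] > anchor[d]:
            hi[d] = min(hi[d], max(cut, np.nextafter(anchor[d], 1.0)))
        else:
            lo[d] = max(lo[d], min(cut, np.nextafter(anchor[d], 0.0)))
    if n_free is not None and n_free < anchor.size:
        free = rng.permutation(anchor.size)[:n_free]
        clamp = np.ones(anchor.size, dtype=bool)
        clamp[free] = False
        lo[clamp] = anchor[clamp]
        hi[clamp] = anchor[clamp]
    return lo, hi


def _average(func: Callable, x, n: int) -> float:
    vals = []
    for _ in range(n):
        try:
            vals.append(float(func(x)))
        except Exception:
            return np.inf
    return float(np.mean(vals))


def sracos_minimize(
    func: Callable[[np.ndarray], float],
    dim: int,
    config: OptimizerConfig = OptimizerConfig(),
    key: Optional[Callable[[np.ndarray], object]] = None,
) -> OptimizationTrace:
    """Minimize a function on the unit box [0,1]^dim (vector interface).

    ``key`` maps a point to a hashable identity (e.g. its decoded discrete
    configuration); when given, candidate draws are retried a few times to
    favour points not evaluated before, so discrete spaces are not burned
    on duplicates.
    """
    # two independent streams: candidate sampling stays reproducible as a
    # pure uniform stream when exploration is pinned at 1, regardless of
    # reservoir bookkeeping
    rng = np.random.default_rng(config.seed)
    pool_rng = np.random.default_rng([config.seed, 1])
    trace = OptimizationTrace()
    # positive set: the n_positive best points seen; negative reservoir:
    # a random-replacement sample of the rest, so the learned region is
    # carved against points representative of the whole space rather than
    # only near-incumbent ones
    positives: list[tuple[np.ndarray, float]] = []
    negatives: list[tuple[np.ndarray, float]] = []
    neg_capacity = max(config.population - config.n_positive, 1)
    seen: set = set()

    def draw_new(sampler: Callable[[], np.ndarray], retries: int = 10) -> np.ndarray:
        u = sampler()
        if key is None:
            return u
        for _ in range(retries):
            if key(u) not in seen:
                break
            u = sampler()
        return u

    def record(u: np.ndarray, value: float) -> None:
        trace.evaluations_used += 1
        if value < trace.best_value:
            trace.best_value = value
            trace.best_candidate = u.copy()
        trace.records.append(
            TraceRecord(trace.evaluations_used, u.copy(), value, trace.best_value)
        )
        if key is not None:
            seen.add(key(u))
        positives.append((u, value))
        positives.sort(key=lambda t: t[1])
        if len(positives) > config.n_positive:
            demoted = positives.pop()
            if len(negatives) < neg_capacity:
                negatives.append(demoted)
            else:
                negatives[int(pool_rng.integers(neg_capacity))] = demoted

    # phase 1: uniform population
    for _ in range(min(config.population, config.budget)):
        u = draw_new(lambda: rng.random(dim))
        record(u, _average(func, u, config.re_evaluations))

    total_refine = config.budget - config.population
    stale = 0
    for t in range(total_refine):
        if stale >= config.patience:
            break
        p_explore = exploration_probability(t, max(total_refine - 1, 1), config)
        if rng.random() < p_explore:
            u = draw_new(lambda: rng.random(dim))
        else:
            # the exploitation step is drawn log-uniformly between step_size
            # and an annealed floor (step_size/100 by the end of the run):
            # refinement resolves ever finer structure while coarse,
            # cell-hopping steps remain possible throughout
            frac = t / max(total_refine - 1, 1)
            step = config.step_size * 0.01 ** (frac * rng.random())
            lo, hi = learn_sampling_region(
                [p for p, _ in positives],
                [p for p, _ in negatives],
                None,
                step,
                rng,
                n_free=max(2, dim // 4),
            )
            u = draw_new(lambda: rng.uniform(lo, hi))
        # an iteration counts as an improvement when its candidate strictly
        # betters the positive set (flat landscapes therefore still stop
        # after `patience` iterations)
        threshold = positives[-1][1] if positives else np.inf
        value = _average(func, u, config.re_evaluations)
        record(u, value)
        if value < threshold:
            stale = 0
        else:
            stale += 1
    return trace


def sracos_optimize(
    objective: Callable[[HyperConfig], float],
    space: SearchSpace,
    config: OptimizerConfig = OptimizerConfig(),
) -> OptimizationTrace:
    """Minimize an objective over hyperparameter configurations.

    Candidates in the trace are :class:`HyperConfig` instances; a raising
    objective marks the candidate failed (value +inf) and the search
    continues, still consuming budget.
    """

    def vec_objective(u: np.ndarray) -> float:
        cfg = decode_vector(denormalize_vector(u, space), space)
        return objective(cfg)

    def vec_key(u: np.ndarray) -> HyperConfig:
        return decode_vector(denormalize_vector(u, space), space)

    trace = sracos_minimize(vec_objective, CODEC_LENGTH, config, key=vec_key)
    # translate vector candidates back to configurations
    for r in trace.records:
        r.candidate = decode_vector(denormalize_vector(r.candidate, space), space)
    if trace.best_candidate is not None:
        trace.best_candidate = decode_vector(
            denormalize_vector(trace.best_candidate, space), space
        )
    return trace


# ---------------------------------------------------------------------------
# random embedding
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingMap:
    """Fixed Gaussian map from a low-dimensional box into the full space."""

    A: np.ndarray  # (source_dim, target_dim), i.i.d. standard normal
    source_dim: int
    target_dim: int
    seed: int

    def lift(self, y: Sequence[float]) -> np.ndarray:
        """[0,1]^target -> [0,1]^source (centred linear map, clipped)."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.target_dim,):
            raise ValueError(f"expected a length-{self.target_dim} vector")
        u = 0.5 + self.A @ (2.0 * y - 1.0)
        return np.clip(u, 0.0, 1.0)


def make_random_embedding(
    space: SearchSpace,
    target_dim: int,
    seed: int = 0,
    objective: Optional[Callable[[HyperConfig], float]] = None,
):
    """Build the embedding and, if given an objective, its lifted version.

    Returns ``EmbeddingMap`` alone, or ``(EmbeddingMap, g)`` where
    ``g(y) = objective(decode(lift(y)))`` is suitable for
    :func:`sracos_minimize` on ``target_dim`` coordinates.
    """
    if not 1 <= target_dim < CODEC_LENGTH:
        raise ValueError(
            f"target_dim must be in [1, {CODEC_LENGTH - 1}], got {target_dim}"
        )
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((CODEC_LENGTH, target_dim))
    emb = EmbeddingMap(A, CODEC_LENGTH, target_dim, seed)
    if objective is None:
        return emb

    def lifted(y: np.ndarray) -> float:
        u = emb.lift(y)
        cfg = decode_vector(denormalize_vector(u, space), space)
        return objective(cfg)

    return emb, lifted
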