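"""The mixed discrete/continuous hyperparameter search space.

A point in the space is a :class:`HyperConfig`: the number of convolutional
blocks (depth ``l``), the per-layer filter counts ``f_1..f_l``, the learning
rate ``eta`` (sampled log-uniformly) and the dropout rate ``d``.  The space
also defines a fixed-length numeric codec (8 slots: depth, five filter
slots, learning rate, dropout) so that derivative-free optimizers and random
embeddings can work in a plain vector space; filter slots beyond the depth
are carried but inert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

__all__ = [
    "SearchSpace",
    "HyperConfig",
    "default_space",
    "sample_config",
    "encode_config",
    "decode_vector",
    "normalize_vector",
    "denormalize_vector",
    "CODEC_LENGTH",
]

CODEC_LENGTH = 8  # depth + 5 filter slots + learning rate + dropout


@dataclass(frozen=True)
class HyperConfig:
    """One candidate configuration Theta."""

    depth: int
    filters: tuple[int, ...]
    learning_rate: float
    dropout: float

    def __post_init__(self) -> None:
        if self.depth != len(self.filters):
            raise ValueError(
                f"depth ({self.depth}) must equal len(filters) ({len(self.filters)})"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.dropout < 1.0:
            raise ValueError("dropout must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "filters": list(self.filters),
            "learning_rate": self.learning_rate,
            "dropout": self.dropout,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperConfig":
        return cls(
            int(d["depth"]),
            tuple(int(f) for f in d["filters"]),
            float(d["learning_rate"]),
            float(d["dropout"]),
        )


@dataclass
class SearchSpace:
    """Intervals for each searchable dimension.

    ``filter_choices[i]`` is the inclusive integer range for the filters of
    conv block ``i+1``; only the first ``depth`` of them are active for a
    given configuration.  Configurations deeper than the number of filter
    slots repeat the last slot's filter count for the extra blocks, so the
    codec length stays fixed.
    """

    depth_range: tuple[int, int] = (3, 7)
    filter_choices: tuple[tuple[int, int], ...] = (
        (16, 64),
        (32, 128),
        (64, 256),
        (16, 512),
        (32, 256),
    )
    lr_range: tuple[float, float] = (1e-5, 1e-1)
    lr_log_uniform: bool = True
    dropout_range: tuple[float, float] = (0.1, 0.7)

    def __post_init__(self) -> None:
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("invalid depth range")
        if len(self.filter_choices) != CODEC_LENGTH - 3:
            raise ValueError("exactly five filter slots are required")
        for lo, hi in self.filter_choices:
            if lo < 1 or lo > hi:
                raise ValueError("filter ranges must be positive and non-empty")
        if self.lr_range[0] <= 0 or self.lr_range[0] > self.lr_range[1]:
            raise ValueError("lr range must be positive and non-empty")
        if not (0.0 < self.dropout_range[0] <= self.dropout_range[1] < 1.0):
            raise ValueError("dropout range must lie inside (0, 1)")

    # -- containment / clipping -------------------------------------------
    def filter_range(self, i: int) -> tuple[int, int]:
        """Filter range of conv block ``i`` (last slot repeats for deep tails)."""
        return self.filter_choices[min(i, len(self.filter_choices) - 1)]

    def contains(self, config: HyperConfig) -> bool:
        if not self.depth_range[0] <= config.depth <= self.depth_range[1]:
            return False
        n_slots = len(self.filter_choices)
        for i, f in enumerate(config.filters):
            lo, hi = self.filter_range(i)
            if not lo <= f <= hi:
                return False
            if i >= n_slots and f != config.filters[n_slots - 1]:
                return False  # deep tails repeat the last slot
        if not self.lr_range[0] <= config.learning_rate <= self.lr_range[1]:
            return False
        return self.dropout_range[0] <= config.dropout <= self.dropout_range[1]

    def clip(self, config: HyperConfig) -> HyperConfig:
        depth = int(np.clip(config.depth, *self.depth_range))
        filters = list(config.filters[:depth])
        while len(filters) < depth:  # deepen with the slot lower bound
            filters.append(self.filter_range(len(filters))[0])
        filters = tuple(
            int(np.clip(f, *self.filter_range(i))) for i, f in enumerate(filters)
        )
        return HyperConfig(
            depth,
            filters,
            float(np.clip(config.learning_rate, *self.lr_range)),
            float(np.clip(config.dropout, *self.dropout_range)),
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "depth_range": list(self.depth_range),
            "filter_choices": [list(r) for r in self.filter_choices],
            "lr_range": list(self.lr_range),
            "lr_log_uniform": self.lr_log_uniform,
            "dropout_range": list(self.dropout_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SearchSpace":
        kwargs = {}
        if "depth_range" in d:
            kwargs["depth_range"] = tuple(d["depth_range"])
        if "filter_choices" in d:
            kwargs["filter_choices"] = tuple(tuple(r) for r in d["filter_choices"])
        if "lr_range" in d:
            kwargs["lr_range"] = tuple(float(x) for x in d["lr_range"])
        if "lr_log_uniform" in d:
            kwargs["lr_log_uniform"] = bool(d["lr_log_uniform"])
        if "dropout_range" in d:
            kwargs["dropout_range"] = tuple(float(x) for x in d["dropout_range"])
        return cls(**kwargs)

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "SearchSpace":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


def default_space() -> SearchSpace:
    """The canonical search space.

    Depth 3-7 conv blocks with per-layer filter ranges f1 in [16,64],
    f2 in [32,128], f3 in [64,256], f4 in [16,512], f5 in [32,256];
    learning rate log-uniform on [1e-5, 1e-1]; dropout on [0.1, 0.7].
    The published tuned optimum (lr 0.0001253981, dropout 0.44) lies inside.
    """
    return SearchSpace()


def sample_config(space: SearchSpace, rng: np.random.Generator) -> HyperConfig:
    """Draw one configuration from the uniform prior over the space."""
    depth = int(rng.integers(space.depth_range[0], space.depth_range[1] + 1))
    n_slots = len(space.filter_choices)
    slot_filters = [
        int(rng.integers(lo, hi + 1))
        for lo, hi in space.filter_choices[: min(depth, n_slots)]
    ]
    filters = tuple(
        slot_filters[min(i, len(slot_filters) - 1)] for i in range(depth)
    )
    if space.lr_log_uniform:
        lo, hi = np.log10(space.lr_range)
        lr = float(10.0 ** rng.uniform(lo, hi))
    else:
        lr = float(rng.uniform(*space.lr_range))
    dropout = float(rng.uniform(*space.dropout_range))
    return HyperConfig(depth, filters, lr, dropout)


# ---------------------------------------------------------------------------
# fixed-length codec (natural units) and normalized coordinates
# ---------------------------------------------------------------------------


def encode_config(config: HyperConfig, space: SearchSpace) -> np.ndarray:
    """Configuration -> length-8 vector in natural units.

    Inactive filter slots (index >= depth) are filled with their range lower
    bound so the codec length is fixed.
    """
    v = np.empty(CODEC_LENGTH)
    v[0] = config.depth
    for i, (lo, _hi) in enumerate(space.filter_choices):
        v[1 + i] = config.filters[i] if i < config.depth else lo
    v[6] = config.learning_rate
    v[7] = config.dropout
    return v


def decode_vector(v: Sequence[float], space: SearchSpace) -> HyperConfig:
    """Vector -> configuration: clip to bounds, round discrete slots.

    ``encode_config(decode_vector(v))`` is idempotent (a projection).
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (CODEC_LENGTH,):
        raise ValueError(f"codec vectors have length {CODEC_LENGTH}, got {v.shape}")
    depth = int(np.clip(np.rint(v[0]), *space.depth_range))
    n_slots = len(space.filter_choices)
    filters = tuple(
        int(
            np.clip(
                np.rint(v[1 + min(i, n_slots - 1)]), *space.filter_range(i)
            )
        )
        for i in range(depth)
    )
    lr = float(np.clip(v[6], *space.lr_range))
    dropout = float(np.clip(v[7], *space.dropout_range))
    return HyperConfig(depth, filters, lr, dropout)


def normalize_vector(v: Sequence[float], space: SearchSpace) -> np.ndarray:
    """Map a natural-units codec vector into [0, 1]^8.

    The learning-rate slot is normalized on a log scale when the space is
    log-uniform, so unit boxes are sensible sampling regions.
    """
    v = np.asarray(v, dtype=float)
    out = np.empty(CODEC_LENGTH)
    out[0] = _unit(v[0], *space.depth_range)
    for i, (lo, hi) in enumerate(space.filter_choices):
        out[1 + i] = _unit(v[1 + i], lo, hi)
    if space.lr_log_uniform:
        out[6] = _unit(np.log10(v[6]), *np.log10(space.lr_range))
    else:
        out[6] = _unit(v[6], *space.lr_range)
    out[7] = _unit(v[7], *space.dropout_range)
    return np.clip(out, 0.0, 1.0)


def denormalize_vector(u: Sequence[float], space: SearchSpace) -> np.ndarray:
    """Inverse of :func:`normalize_vector` (continuous; no rounding)."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    v = np.empty(CODEC_LENGTH)
    v[0] = _affine(u[0], *space.depth_range)
    for i, (lo, hi) in enumerate(space.filter_choices):
        v[1 + i] = _affine(u[1 + i], lo, hi)
    if space.lr_log_uniform:
        lo, hi = np.log10(space.lr_range)
        v[6] = 10.0 ** _affine(u[6], lo, hi)
    else:
        v[6] = _affine(u[6], *space.lr_range)
    v[7] = _affine(u[7], *space.dropout_range)
    return v


def _unit(x: float, lo: float, hi: float) -> float:
    return 0.5 if hi == lo else (x - lo) / (hi - lo)


def _affine(u: float, lo: float, hi: float) -> float:
    return lo + u * (hi - lo)
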