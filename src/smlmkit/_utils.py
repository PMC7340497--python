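"""Shared helpers: ROI geometry, RNG splitting, parameter validation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Conversion between the on-disk/in-memory coordinate unit (nm) and µm.
NM_PER_UM = 1000.0


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle [x, x+w) × [y, y+h) in nm.

    Origin at the ROI top-left, y increasing downward (image convention).
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (np.isfinite([self.x, self.y, self.w, self.h]).all()):
            raise ValueError("ROI coordinates must be finite")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI must have positive width and height")

    @property
    def area_nm2(self) -> float:
        return self.w * self.h

    @property
    def area_um2(self) -> float:
        return self.w * self.h / NM_PER_UM**2

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (N, 2) inside the half-open rectangle."""
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (p[:, 0] >= self.x)
            & (p[:, 0] < self.x + self.w)
            & (p[:, 1] >= self.y)
            & (p[:, 1] < self.y + self.h)
        )

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(float(d["x"]), float(d["y"]), float(d["w"]), float(d["h"]))


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or a Generator; return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_rng(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one seed.

    All randomness in the simulators flows through this splitter so a single
    user-facing seed reproduces every stage bit-for-bit.
    """
    if isinstance(seed, np.random.Generator):
        return seed.spawn(n)
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


def check_unit_interval(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def check_prob_vector(name: str, weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError(f"{name} must be a 1-D probability vector")
    if (w < 0).any() or not np.isfinite(w).all():
        raise ValueError(f"{name} must be non-negative and finite")
    total = w.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"{name} must sum to 1, got {total}")
    return w / total
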