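"""Rectangle random sampling of the latent space.

After each retraining the encoded training data (z = mu) defines a minimal
axis-aligned bounding box; the box is expanded symmetrically about its
center by a fixed rate (20% by default) and new candidates are drawn
i.i.d. uniformly inside the expanded rectangle.  The expansion balances
exploiting the known latent region against exploring just beyond it.

The latent-space scale L summarizes the spread of the encoded data: the
root-mean-square distance of the latent points from their centroid.  It is
zero for coincident points and scales linearly when the cloud is dilated
about its centroid, which makes it a convenient diagnostic for choosing
the loss ratio lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SamplingRectangle", "latent_scale", "make_rectangle", "draw_batch"]

# floor width for a collapsed (zero-extent) rectangle side
DEGENERATE_SIDE = 0.1


def latent_scale(points: np.ndarray) -> float:
    """RMS distance of latent points from their centroid."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise ValueError("need at least one latent point")
    centered = points - points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


@dataclass(frozen=True)
class SamplingRectangle:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if np.any(self.upper < self.lower):
            raise ValueError("rectangle upper bound below lower bound")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.all(
            (points >= self.lower) & (points <= self.upper), axis=1
        )


def make_rectangle(
    points: np.ndarray, expansion_rate: float = 0.2
) -> SamplingRectangle:
    """Minimal bounding box of the latent data, expanded about its center.

    Each side length is multiplied by (1 + expansion_rate) symmetrically.
    Sides with zero extent (e.g. a single latent point) are widened to an
    absolute floor of 0.1 so sampling never collapses to a point.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("empty latent point set")
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0 * (1.0 + expansion_rate)
    half = np.maximum(half, DEGENERATE_SIDE / 2.0)
    return SamplingRectangle(center - half, center + half)


def draw_batch(
    rect: SamplingRectangle, batch_size: int, seed: int | np.random.Generator
) -> np.ndarray:
    """batch_size i.i.d. uniform draws inside the rectangle (seeded)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d = len(rect.lower)
    u = rng.random((batch_size, d))
    return rect.lower + u * (rect.upper - rect.lower)
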