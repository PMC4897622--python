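"""Grand-canonical reservoir coupling.

The cylinder scenario keeps the free-monomer concentration at a reservoir
value ``c_r`` by insertion/deletion moves restricted to an exchange region
far from the scaffold — a frame of configurable width at the lateral box
faces.  Only free (monomeric) homodimers are exchanged; oligomers in the
region are never deleted and no move ever touches a bond.  For an ideal
reservoir the acceptance rules are the standard μVT ones with mean target
count N̄ = c_r · V_ex · N_A:

    acc(insert) = min(1, N̄ / (N + 1)),   acc(delete) = min(1, N / N̄),

which make the stationary region count Poisson(N̄).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import InvalidParameterError
from .units import molar_to_count


@dataclass(frozen=True)
class ExchangeRegion:
    """Exchange slab at the lateral box faces.

    ``width``: slab width (nm) at each x/y face; ``c_r``: reservoir
    concentration (μM); ``every``: BD steps between exchange attempts (one
    insertion plus one deletion attempt each time), short against the time a
    free homodimer needs to diffuse through the region.
    """

    width: float = 5.0
    c_r: float = 5.0
    every: int = 100

    def __post_init__(self):
        if self.width <= 0 or self.c_r < 0 or self.every < 1:
            raise InvalidParameterError("invalid exchange-region parameters")

    def volume(self, box: np.ndarray) -> float:
        lx, ly, lz = float(box[0]), float(box[1]), float(box[2])
        inner = max(lx - 2 * self.width, 0.0) * max(ly - 2 * self.width, 0.0)
        return (lx * ly - inner) * lz

    def mean_count(self, box: np.ndarray) -> float:
        return molar_to_count(self.c_r, self.volume(box))

    def contains(self, xy: np.ndarray, box: np.ndarray) -> bool:
        x, y = float(xy[0]), float(xy[1])
        return (
            x < self.width
            or x > box[0] - self.width
            or y < self.width
            or y > box[1] - self.width
        )


def gcmc_exchange(
    n: int, nbar: float, rng: np.random.Generator
) -> tuple[int, bool, bool]:
    """One symmetric exchange attempt on an ideal-gas region count.

    Chooses insertion or deletion with probability 1/2 and accepts with the
    μVT ratio; the move pair is reversible with respect to the ideal
    grand-canonical measure, so the stationary count is Poisson(N̄).
    Returns (new count, inserted?, deleted?).  This is the acceptance rule
    used by the engine, factored out so its stationary distribution can be
    tested directly.
    """
    inserted = deleted = False
    if rng.random() < 0.5:
        if rng.random() < min(1.0, nbar / (n + 1.0)):
            n += 1
            inserted = True
    elif n > 0:
        acc = 1.0 if nbar <= 0 else min(1.0, n / nbar)
        if rng.random() < acc:
            n -= 1
            deleted = True
    return n, inserted, deleted


def sample_region_counts(
    nbar: float, n_moves: int, seed: int = 0, n0: int = 0
) -> np.ndarray:
    """Markov chain of region counts under the μVT acceptance rule."""
    rng = np.random.default_rng(seed)
    counts = np.empty(n_moves, dtype=np.int64)
    n = n0
    for k in range(n_moves):
        n, _, _ = gcmc_exchange(n, nbar, rng)
        counts[k] = n
    return counts
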