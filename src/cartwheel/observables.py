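"""Observables computed from trajectories and rate-equation output.

Relative cluster populations, scaffold occupancy, ring orientation,
dissociation-constant measurement from a reversible pair trajectory, and a
steady-state detector for time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Cluster, InvalidParameterError
from .scaffolds import Scaffold
from .units import PER_NM3_PER_UM


class UndefinedPopulationError(ValueError):
    """No homodimers present; populations undefined."""


class InsufficientSamplingError(RuntimeError):
    """Too few binding/unbinding transitions to estimate an equilibrium."""


@dataclass
class TrajectoryFrame:
    """One recorded frame: time (ns), per-species counts and scaffold-bound
    homodimer count (sizes 1..9 at indices 0..8, ring at index 9)."""

    time: float
    counts: np.ndarray
    n_bound: int = 0

    @property
    def total_homodimers(self) -> int:
        weights = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 9])
        return int(self.counts @ weights)


def relative_cluster_population(counts: np.ndarray) -> np.ndarray:
    """Probability that a homodimer is part of an oligomer of size i.

    ``counts``: number of clusters per species (chains 1..9, ring last).
    The ring is its own category.  Sums to one.
    """
    counts = np.asarray(counts, float)
    weights = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 9], dtype=float)
    mass = counts * weights
    total = mass.sum()
    if total <= 0:
        raise UndefinedPopulationError("no homodimers in the system")
    return mass / total


def population_from_clusters(clusters: list[Cluster]) -> np.ndarray:
    """Relative populations from explicit clusters (bond-graph based)."""
    counts = np.zeros(10)
    for c in clusters:
        n = c.n_members
        if c.is_ring:
            counts[9] += 1
        else:
            counts[n - 1] += 1
    return relative_cluster_population(counts)


def scaffold_occupancy(clusters: list[Cluster], scaffold: Scaffold) -> int:
    """Number of homodimers bound to the scaffold.

    A homodimer counts as bound iff at least one of its charge sites lies
    within the attractive layer (the layer is the only interaction region).
    """
    total = 0
    for cluster in clusters:
        sites = cluster.world_charge_sites()
        for m in range(cluster.n_members):
            bound = False
            for site in sites[2 * m : 2 * m + 2]:
                r, _ = scaffold.radial(site)
                if r < scaffold.outer_radius:
                    if scaffold.shape == "semisphere" and site[2] <= 0.0:
                        continue
                    bound = True
                    break
            if bound:
                total += 1
    return total


def ring_orientation(ring: Cluster, reference_normal=(0.0, 0.0, 1.0)) -> float:
    """Angle (deg, folded to [0, 90]) between the ring-plane normal and a
    reference direction.

    The ring plane is the least-squares plane of the N-terminal bead
    centers; for the rigid ring the fit residual is ~0 and the choice of
    fitted points is inconsequential.
    """
    if not ring.is_ring:
        raise InvalidParameterError("ring_orientation requires a closed ring")
    pts = ring.world_n_term_centers()
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    ref = np.asarray(reference_normal, float)
    ref = ref / np.linalg.norm(ref)
    cosang = abs(float(np.dot(normal, ref)))
    return math.degrees(math.acos(min(1.0, cosang)))


def measure_kd(
    bound: np.ndarray,
    box_volume: float,
    multiplicity: int = 2,
    min_transitions: int = 100,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Dissociation constant (μM) from a reversible two-cluster trajectory.

    ``bound`` is the per-frame bound indicator of a single donor–acceptor
    pair of homodimers in a periodic box of ``box_volume`` nm³.  The
    two-state relation K_D = g · (1-f)/f / (N_A V) with f the bound
    fraction and g the number of distinguishable binding channels of the
    homodimer pair (2: either donor may engage either acceptor).  Returns
    the estimate and a block-bootstrap confidence interval (2.5–97.5%).

    A trajectory with no transitions is unusable: fully bound gives K_D → 0
    and never-bound K_D → ∞; both raise :class:`InsufficientSamplingError`.
    """
    bound = np.asarray(bound).astype(bool)
    n_trans = int(np.abs(np.diff(bound.astype(np.int8))).sum())
    if n_trans < min_transitions:
        raise InsufficientSamplingError(
            f"only {n_trans} binding/unbinding transitions (< {min_transitions}); "
            + ("trajectory fully bound (K_D -> 0)" if bound.all() else "")
            + ("trajectory never bound (K_D -> inf)" if not bound.any() else "")
        )

    def kd_from(f: float) -> float:
        return multiplicity * (1.0 - f) / f / (box_volume * PER_NM3_PER_UM)

    est = kd_from(float(bound.mean()))
    # block bootstrap with blocks spanning several transitions
    rng = np.random.default_rng(seed)
    block = max(1, len(bound) // max(n_trans // 4, 8))
    n_blocks = len(bound) // block
    blocks = bound[: n_blocks * block].reshape(n_blocks, block)
    boot = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        boot.append(kd_from(float(blocks[pick].mean())))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return est, (float(lo), float(hi))


@dataclass
class SteadyStateResult:
    converged: bool
    time: float | None
    index: int | None


def steady_state_detector(
    times: np.ndarray, series: np.ndarray, n_windows: int = 4, z: float = 2.0
) -> SteadyStateResult:
    """Declare steady state when two consecutive window means agree.

    The series is split into ``n_windows`` equal windows; steady state is
    declared at the first window whose mean differs from the next window's
    mean by less than ``z`` pooled standard errors (a constant series
    converges at the first window, a linear ramp never does).
    """
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    if len(series) < 2 * n_windows:
        return SteadyStateResult(False, None, None)
    size = len(series) // n_windows
    for w in range(n_windows - 1):
        a = series[w * size : (w + 1) * size]
        b = series[(w + 1) * size : (w + 2) * size]
        se = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / size)
        if abs(a.mean() - b.mean()) < max(z * se, 1e-300):
            return SteadyStateResult(True, float(times[(w + 1) * size - 1]), (w + 1) * size - 1)
    return SteadyStateResult(False, None, None)


def rings_in(clusters: list[Cluster]) -> list[Cluster]:
    """Closed rings among explicit clusters (bond-graph criterion)."""
    return [c for c in clusters if c.is_ring]
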