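"""Simulation driver: packs species tables and drives the numba engine.

The :class:`Simulation` owns the flat state arrays (species index, position,
orientation quaternion per cluster), converts the high-level objects
(:class:`~cartwheel.reactions.ReactionParameters`,
:class:`~cartwheel.scaffolds.Scaffold`,
:class:`~cartwheel.gcmc.ExchangeRegion`) into kernel arguments, and records
species counts and scaffold occupancy at a fixed cadence.  Trajectories are
deterministic given (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.transform import Rotation as ScipyRotation

from . import engine
from .gcmc import ExchangeRegion
from .geometry import Cluster, ModelParams, RigidTransform, build_homodimer
from .reactions import ReactionParameters
from .scaffolds import Scaffold
from .species import RING_SPECIES, build_species_tables
from .units import count_to_molar

_SHAPE_CODE = {
    None: engine.SCAFFOLD_NONE,
    "cylinder": engine.SCAFFOLD_CYLINDER,
    "sphere": engine.SCAFFOLD_SPHERE,
    "semisphere": engine.SCAFFOLD_SEMISPHERE,
}


@dataclass
class PackedTables:
    nmem: np.ndarray
    nbead: np.ndarray
    beads: np.ndarray
    brad: np.ndarray
    nchg: np.ndarray
    chg: np.ndarray
    ends: np.ndarray
    gq: np.ndarray
    gp: np.ndarray
    pd_anchor: np.ndarray
    reach: np.ndarray
    mob: np.ndarray
    sqrt2d: np.ndarray


def pack_tables(params: ModelParams | None = None) -> PackedTables:
    tables = build_species_tables(params)
    model = build_homodimer(params or ModelParams())
    maxb = max(t.beads.shape[0] for t in tables)
    maxc = max(t.charge_sites.shape[0] for t in tables)
    n_sp = len(tables)
    nmem = np.zeros(n_sp, dtype=np.int64)
    nbead = np.zeros(n_sp, dtype=np.int64)
    nchg = np.zeros(n_sp, dtype=np.int64)
    beads = np.zeros((n_sp, maxb, 3))
    brad = np.zeros((n_sp, maxb))
    chg = np.zeros((n_sp, maxc, 3))
    ends = np.zeros((n_sp, 2, 3, 3))
    gq = np.zeros((n_sp, 9, 4))
    gp = np.zeros((n_sp, 9, 3))
    mob = np.zeros((n_sp, 6, 6))
    sqrt2d = np.zeros((n_sp, 6, 6))
    for s, t in enumerate(tables):
        nmem[s] = t.size
        nb = t.beads.shape[0]
        nbead[s] = nb
        beads[s, :nb] = t.beads
        brad[s, :nb] = t.bead_radii
        nc = t.charge_sites.shape[0]
        nchg[s] = nc
        chg[s, :nc] = t.charge_sites
        if not t.is_ring:
            ends[s, 0, 0] = t.donor_anchor
            ends[s, 0, 1] = t.donor_c2c
            ends[s, 0, 2] = t.donor_torsion
            ends[s, 1, 0] = t.acceptor_anchor
            ends[s, 1, 1] = t.acceptor_c2c
            ends[s, 1, 2] = t.acceptor_torsion
        gq[s, : t.size] = t.member_quat
        gp[s, : t.size] = t.member_pos
        mob[s] = t.diffusion.mobility
        sqrt2d[s] = np.linalg.cholesky(2.0 * t.diffusion.diffusion)
    donor = next(p for p in model.patches if p.polarity == "donor")
    reach = np.zeros(n_sp)
    for s_idx, t in enumerate(tables):
        if not t.is_ring:
            reach[s_idx] = max(
                float(np.linalg.norm(t.donor_anchor)),
                float(np.linalg.norm(t.acceptor_anchor)),
            )
    return PackedTables(
        nmem, nbead, beads, brad, nchg, chg, ends, gq, gp,
        np.asarray(donor.anchor, float), reach, mob, sqrt2d,
    )


class Simulation:
    """Brownian-dynamics simulation of homodimer assembly in a box.

    Parameters
    ----------
    reaction:
        Microscopic rates, time step and encounter window.  ``reactions_on``
        can disable oligomerization entirely (capture-only controls).
    box:
        (Lx, Ly, Lz) in nm.  Axes are periodic unless ``wall_z`` puts
        repulsive planar walls at z = 0 and z = Lz.
    scaffold, exchange:
        Optional scaffold and grand-canonical reservoir coupling.
    """

    def __init__(
        self,
        reaction: ReactionParameters,
        box: tuple[float, float, float],
        params: ModelParams | None = None,
        scaffold: Scaffold | None = None,
        exchange: ExchangeRegion | None = None,
        wall_z: bool = False,
        k_wall: float = 2.0,
        reactions_on: bool = True,
        capacity: int | None = None,
        seed: int = 0,
    ):
        self.params = params or ModelParams()
        self.reaction = reaction
        self.tables = pack_tables(self.params)
        self.box = np.asarray(box, float)
        self.scaffold = scaffold
        self.exchange = exchange
        self.wall_z = wall_z
        self.k_wall = k_wall
        self.reactions_on = reactions_on
        self.periodic = np.array([True, True, not wall_z])
        if capacity is None:
            capacity = 256
            if exchange is not None:
                capacity = max(capacity, int(8 * exchange.mean_count(self.box)) + 256)
        self.capacity = capacity
        self.species = np.full(capacity, -1, dtype=np.int64)
        self.pos = np.zeros((capacity, 3))
        self.quat = np.zeros((capacity, 4))
        self.quat[:, 0] = 1.0
        self.time = 0.0
        self.records: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        self._rng = np.random.default_rng(seed)
        engine.seed_engine(int(self._rng.integers(0, 2**31 - 1)))

    # -- state construction -------------------------------------------------

    def n_active(self) -> int:
        return int((self.species >= 0).sum())

    def total_homodimers(self) -> int:
        sizes = np.where(self.species == RING_SPECIES, 9, self.species + 1)
        return int(sizes[self.species >= 0].sum())

    def add_cluster(self, species: int, pos, quat=None) -> int:
        slot = int(np.argmin(self.species >= 0))
        if self.species[slot] >= 0:
            raise RuntimeError("capacity exhausted")
        self.species[slot] = species
        self.pos[slot] = np.asarray(pos, float)
        if quat is None:
            q = self._rng.normal(size=4)
            quat = q / np.linalg.norm(q)
        self.quat[slot] = np.asarray(quat, float)
        return slot

    def place_random_homodimers(self, n: int, max_attempts: int = 200) -> float:
        """Uniform overlap-free random placement of n monomers.

        Returns the achieved molar concentration (μM).  Raises if the box is
        too crowded to place them by rejection.
        """
        radius = float(np.linalg.norm(self.tables.beads[0], axis=1).max() + self.tables.brad[0].max())
        placed: list[np.ndarray] = [
            self.pos[i] for i in range(self.capacity) if self.species[i] >= 0
        ]
        for _ in range(n):
            for attempt in range(max_attempts):
                p = self._rng.random(3) * self.box
                ok = True
                for q in placed:
                    d = p - q
                    d -= self.box * np.round(d / self.box) * self.periodic
                    if np.dot(d, d) < (1.2 * radius) ** 2:
                        ok = False
                        break
                if ok:
                    break
            else:
                raise RuntimeError(f"could not place homodimer {len(placed) + 1}: box too dense")
            placed.append(p)
            self.add_cluster(0, p)
        return count_to_molar(n, float(np.prod(self.box)))

    # -- running ------------------------------------------------------------

    def run(self, n_steps: int, record_every: int = 1000) -> None:
        """Advance the simulation, appending (times, counts, occupancy)."""
        r = self.reaction
        n_rec = n_steps // record_every
        rec_counts = np.zeros((n_rec, 10), dtype=np.int64)
        rec_occ = np.zeros(n_rec, dtype=np.int64)
        sc = self.scaffold
        stype = _SHAPE_CODE[None if sc is None else sc.shape]
        center = np.zeros(3) if sc is None else np.asarray(sc.center, float)
        ex = self.exchange
        t = self.tables
        engine.run_chunk(
            self.species, self.pos, self.quat,
            t.nmem, t.nbead, t.beads, t.brad, t.nchg, t.chg,
            t.ends, t.gq, t.gp, t.pd_anchor, t.reach, t.mob, t.sqrt2d,
            self.box, self.periodic, self.wall_z, self.k_wall,
            stype, center,
            0.0 if sc is None else sc.r_s,
            1.0 if sc is None else sc.dr_s,
            0.0 if sc is None else sc.strength,
            2.0 if sc is None else sc.k_rep,
            r.p_assoc, r.p_dissoc, r.p_ring,
            r.window.max_anchor_dist,
            math.cos(math.radians(r.window.max_align_deg)),
            math.cos(math.radians(r.window.max_torsion_deg)),
            self.reactions_on,
            ex is not None,
            1 if ex is None else ex.every,
            0.0 if ex is None else ex.width,
            0.0 if ex is None else ex.mean_count(self.box),
            n_steps, r.delta_t, record_every,
            rec_counts, rec_occ, 0,
        )
        times = self.time + r.delta_t * record_every * np.arange(1, n_rec + 1)
        self.time += n_steps * r.delta_t
        self.records.append((times, rec_counts, rec_occ))

    # -- observables --------------------------------------------------------

    def record_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.records:
            return np.empty(0), np.empty((0, 10), dtype=np.int64), np.empty(0, dtype=np.int64)
        times = np.concatenate([r[0] for r in self.records])
        counts = np.concatenate([r[1] for r in self.records])
        occ = np.concatenate([r[2] for r in self.records])
        return times, counts, occ

    def species_counts(self) -> np.ndarray:
        counts = np.zeros(10, dtype=np.int64)
        for s in self.species[self.species >= 0]:
            counts[s] += 1
        return counts

    def clusters(self) -> list[Cluster]:
        """Reconstruct explicit clusters (world poses) from the flat state."""
        import networkx as nx

        model = build_homodimer(self.params)
        tables = build_species_tables(self.params)
        out = []
        for i in range(self.capacity):
            sp = self.species[i]
            if sp < 0:
                continue
            t = tables[sp]
            rot = Rotation.from_quat(
                np.array([self.quat[i, 1], self.quat[i, 2], self.quat[i, 3], self.quat[i, 0]])
            ).as_matrix()
            pose = RigidTransform(rot, self.pos[i].copy())
            poses = []
            for k in range(t.size):
                q = t.member_quat[k]
                mrot = Rotation.from_quat(np.array([q[1], q[2], q[3], q[0]])).as_matrix()
                poses.append(RigidTransform(mrot, t.member_pos[k].copy()))
            bonds = nx.Graph()
            bonds.add_nodes_from(range(t.size))
            for k in range(t.size - 1):
                bonds.add_edge(k, k + 1, donor=k)
            if t.is_ring:
                bonds.add_edge(t.size - 1, 0, donor=t.size - 1)
            out.append(Cluster(model, poses, pose, bonds, id=i))
        return out


class RelaxationFailure(RuntimeError):
    """Overlap relaxation did not converge; revert the triggering reaction."""


def resolve_overlaps(
    clusters: list[Cluster],
    flagged: list[int],
    box: np.ndarray | None = None,
    wall_z: bool = False,
    k_push: float = 2.0,
    mobility: float = 0.3,
    max_iter: int = 100,
) -> list[Cluster]:
    """Resolve bead overlaps by repulsive relaxation of the flagged clusters.

    Only the clusters whose indices are in ``flagged`` (the newly formed
    ones) move; all others are static obstacles.  Each iteration applies a
    harmonic repulsion between overlapping bead centers (and against a
    planar wall at z = 0 / z = Lz when ``wall_z``) and translates the
    flagged clusters along the net force.  Raises :class:`RelaxationFailure`
    if overlaps persist after ``max_iter`` iterations, in which case the
    caller reverts the reaction that created them.
    """
    from .geometry import check_overlap

    flagged = list(flagged)
    for _ in range(max_iter):
        forces = {i: np.zeros(3) for i in flagged}
        any_overlap = False
        for i in flagged:
            ci = clusters[i]
            pts_i, rad_i = ci.world_beads()
            for j, cj in enumerate(clusters):
                if j == i:
                    continue
                for bi, bj, depth in check_overlap(ci, cj):
                    any_overlap = True
                    pts_j, _ = cj.world_beads()
                    d = pts_i[bi] - pts_j[bj]
                    norm = np.linalg.norm(d)
                    if norm < 1e-9:
                        d = np.array([1.0, 0.0, 0.0])
                        norm = 1.0
                    forces[i] += k_push * depth * d / norm
            if wall_z and box is not None:
                for p, r in zip(pts_i, rad_i):
                    if p[2] < r:
                        any_overlap = True
                        forces[i][2] += k_push * (r - p[2])
                    if p[2] > box[2] - r:
                        any_overlap = True
                        forces[i][2] -= k_push * (p[2] - (box[2] - r))
        if not any_overlap:
            return clusters
        for i in flagged:
            c = clusters[i]
            shift = mobility * forces[i]
            clusters[i] = Cluster(
                c.model,
                c.member_poses,
                RigidTransform(c.pose.rotation, c.pose.translation + shift),
                c.bonds,
                c.id,
            )
    raise RelaxationFailure(f"overlaps persist after {max_iter} iterations")


def propagate(
    cluster: Cluster,
    diffusion,
    delta_t: float,
    rng: np.random.Generator,
    force=None,
    torque=None,
) -> Cluster:
    """One anisotropic Brownian step of a single cluster (reference route).

    Applies the deterministic drift mobility·(F, T)·Δt plus a Gaussian
    displacement with covariance 2 D Δt, both evaluated in the body frame at
    the center of diffusion, and returns the cluster with an updated pose.
    The packed engine performs the identical update; this explicit version
    exists for direct use on :class:`~cartwheel.geometry.Cluster` objects.
    """
    if not np.all(np.isfinite(np.concatenate([
        np.zeros(0) if force is None else np.asarray(force, float).ravel(),
        np.zeros(0) if torque is None else np.asarray(torque, float).ravel(),
    ]))):
        raise ValueError("force/torque must be finite")
    gen = np.zeros(6)
    rot = cluster.pose.rotation
    if force is not None:
        gen[:3] = rot.T @ np.asarray(force, float)
    if torque is not None:
        gen[3:] = rot.T @ np.asarray(torque, float)
    move = diffusion.mobility @ gen * delta_t
    chol = np.linalg.cholesky(2.0 * diffusion.diffusion * delta_t)
    move += chol @ rng.standard_normal(6)
    d_pos = rot @ move[:3]
    d_rot = ScipyRotation.from_rotvec(move[3:]).as_matrix()
    new_rot = rot @ d_rot
    # re-orthonormalize to keep the orientation exactly proper
    u, _, vt = np.linalg.svd(new_rot)
    new_rot = u @ vt
    return Cluster(
        cluster.model,
        cluster.member_poses,
        RigidTransform(new_rot, cluster.pose.translation + d_pos),
        cluster.bonds,
        cluster.id,
    )
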