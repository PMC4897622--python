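"""Rigid coarse-grained homodimer model and ring geometry.

A SAS-6 homodimer is reduced to five spheres: the two globular N-terminal
heads form a dumbbell of radius ``R_N`` and the first six heptad repeats of
the coiled-coil are a string of three spheres of radius ``R_CC``.  Each
homodimer carries two reaction patches located in the N-terminal heads; a
donor patch may only bind an acceptor patch of another homodimer.  The
patch geometry (center-to-center and torsion vectors) encodes a 40° angle
between adjacent spokes, so that nine bound homodimers close into a planar
ring with spokes pointing radially outwards — the cartwheel hub.

All lengths are nm.  Body frames are right-handed, with +x along the spoke
(radially outwards in a ring), +z along the ring normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

R_N_DEFAULT = 1.979
R_CC_DEFAULT = 1.182


class InvalidParameterError(ValueError):
    """A model parameter violates its constraints."""


class IncompatiblePatchError(ValueError):
    """Attempted to bind two patches of like polarity or non-free patches."""


class GeometryClosureError(ValueError):
    """A chain of the requested length does not close into a ring."""


class ConsistencyError(RuntimeError):
    """A bond graph violates the two-patch valence rule."""


# ---------------------------------------------------------------------------
# rigid transforms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def rot_z(angle_rad: float, translation=None) -> "RigidTransform":
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return RigidTransform(rot, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_t = self.rotation.T
        return RigidTransform(rot_t, -rot_t @ self.translation)

    def deviation_from_identity(self) -> tuple[float, float]:
        """(translation norm in nm, rotation angle in rad) away from identity."""
        angle = math.acos(min(1.0, max(-1.0, (np.trace(self.rotation) - 1.0) / 2.0)))
        return float(np.linalg.norm(self.translation)), angle


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Bead:
    offset: np.ndarray  # body frame, nm
    radius: float
    kind: str  # "N-term" | "coiled-coil"

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError(f"bead radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class ReactionPatch:
    anchor: np.ndarray  # body frame, nm
    center_to_center: np.ndarray  # unit vector, body frame
    torsion: np.ndarray  # unit vector, body frame
    polarity: str  # "donor" | "acceptor"

    def __post_init__(self):
        for name in ("center_to_center", "torsion"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise InvalidParameterError(f"{name} must be a unit vector")
        if abs(float(np.dot(self.center_to_center, self.torsion))) > 1e-9:
            raise InvalidParameterError("torsion must be orthogonal to center_to_center")
        if self.polarity not in ("donor", "acceptor"):
            raise InvalidParameterError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class BondGeometryRule:
    """Local bonding rules that encode the ninefold planar ring."""

    spoke_angle_deg: float = 40.0
    ring_size: int = 9
    planarity: bool = True

    @property
    def spoke_angle_rad(self) -> float:
        return math.radians(self.spoke_angle_deg)


@dataclass(frozen=True)
class ModelParams:
    """Geometric parameters of the coarse-grained homodimer."""

    r_n: float = R_N_DEFAULT
    r_cc: float = R_CC_DEFAULT
    extra_cc_beads: int = 0
    rule: BondGeometryRule = field(default_factory=BondGeometryRule)

    def __post_init__(self):
        if self.r_n <= 0 or self.r_cc <= 0:
            raise InvalidParameterError("bead radii must be positive")
        if self.extra_cc_beads < 0:
            raise InvalidParameterError("extra_cc_beads must be >= 0")


@dataclass(frozen=True)
class HomodimerModel:
    """Rigid five-bead homodimer with two reaction patches and two charge sites.

    The body frame has the N-terminal dumbbell centered at the origin with the
    beads on the y-axis, the coiled-coil extending along +x (the spoke) and +z
    the prospective ring normal.  ``hub_center`` is the position of the ring
    axis when the homodimer is part of an ideal ring.
    """

    beads: tuple[Bead, ...]
    patches: tuple[ReactionPatch, ...]
    charge_sites: np.ndarray  # (2, 3) body frame
    params: ModelParams
    hub_center: np.ndarray  # (3,) body frame
    hub_radius: float  # distance ring axis -> N-term bead centers

    @property
    def rule(self) -> BondGeometryRule:
        return self.params.rule

    @property
    def bead_offsets(self) -> np.ndarray:
        return np.array([b.offset for b in self.beads])

    @property
    def bead_radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads])

    @property
    def n_term_indices(self) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.beads) if b.kind == "N-term"])

    def bound_step(self) -> RigidTransform:
        """Pose of the next (donor-side) ring neighbor in this body's frame.

        Composing this transform ``ring_size`` times is the identity: the
        chain closes into the ring encoded by the patch geometry.
        """
        theta = self.rule.spoke_angle_rad
        m = -self.hub_center  # body origin relative to ring axis
        step = RigidTransform.rot_z(theta)
        return RigidTransform(step.rotation, step.rotation @ m - m)


def build_homodimer(params: ModelParams | None = None) -> HomodimerModel:
    """Build the rigid coarse-grained homodimer.

    The dumbbell spacing and patch placement are fully determined by the ring
    constraints: in the closed ring the 2×9 N-terminal beads lie equidistantly
    on a circle in near-contact, which fixes the hub radius to
    ``R_N / sin(spoke_angle/4)`` and places the patch anchors at the contact
    points between neighboring heads.
    """
    params = params or ModelParams()
    r_n, r_cc = params.r_n, params.r_cc
    theta = params.rule.spoke_angle_rad
    quarter = theta / 4.0  # angular offset of each N bead from the spoke axis
    half = theta / 2.0

    r_hub = r_n / math.sin(quarter)  # ring axis -> N bead centers
    r_m = r_n / math.tan(quarter)  # ring axis -> body origin
    hub_center = np.array([-r_m, 0.0, 0.0])

    beads = [
        Bead(np.array([0.0, r_n, 0.0]), r_n, "N-term"),
        Bead(np.array([0.0, -r_n, 0.0]), r_n, "N-term"),
    ]
    # coiled-coil: string of touching spheres along +x, the first tangent to
    # both N-terminal beads
    x0 = math.sqrt((r_n + r_cc) ** 2 - r_n**2)
    for j in range(3 + params.extra_cc_beads):
        beads.append(Bead(np.array([x0 + 2.0 * r_cc * j, 0.0, 0.0]), r_cc, "coiled-coil"))

    # patch anchors: contact points between neighboring N-terminal heads in
    # the ideal ring, on the hub circle at ±(spoke angle)/2
    anchor_d = r_m * np.array([math.cos(half) - 1.0, math.sin(half), 0.0])
    anchor_a = r_m * np.array([math.cos(half) - 1.0, -math.sin(half), 0.0])
    c2c_d = np.array([-math.sin(half), math.cos(half), 0.0])
    c2c_a = np.array([-math.sin(half), -math.cos(half), 0.0])
    torsion = np.array([0.0, 0.0, 1.0])
    patches = (
        ReactionPatch(anchor_d, c2c_d, torsion, "donor"),
        ReactionPatch(anchor_a, c2c_a, torsion, "acceptor"),
    )

    # charge sites: N-head surface points facing the ring interior (where the
    # cartwheel inner densities abut the heads)
    sites = []
    for sign in (1.0, -1.0):
        center = np.array([0.0, sign * r_n, 0.0])
        u = hub_center - center
        u = u / np.linalg.norm(u)
        sites.append(center + r_n * u)
    charge_sites = np.array(sites)

    return HomodimerModel(
        beads=tuple(beads),
        patches=patches,
        charge_sites=charge_sites,
        params=params,
        hub_center=hub_center,
        hub_radius=r_hub,
    )


# ---------------------------------------------------------------------------
# clusters


@dataclass
class Cluster:
    """Rigid oligomer of homodimers.

    ``member_poses`` are the rigid placements of each homodimer body frame in
    the cluster frame; they never change after formation (rigid-body
    constraint).  ``bonds`` is a graph over member indices whose edges carry
    the donor member index.
    """

    model: HomodimerModel
    member_poses: list[RigidTransform]
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    bonds: nx.Graph = field(default_factory=nx.Graph)
    id: int = 0

    def __post_init__(self):
        for i in range(len(self.member_poses)):
            if i not in self.bonds:
                self.bonds.add_node(i)

    @property
    def n_members(self) -> int:
        return len(self.member_poses)

    @property
    def is_ring(self) -> bool:
        n = self.n_members
        return (
            n >= 3
            and self.bonds.number_of_edges() == n
            and all(d == 2 for _, d in self.bonds.degree)
        )

    def member_world(self, i: int) -> RigidTransform:
        return self.pose.compose(self.member_poses[i])

    def world_beads(self) -> tuple[np.ndarray, np.ndarray]:
        """All bead centers (world frame) and radii."""
        offs = self.model.bead_offsets
        pts = np.concatenate([self.member_world(i).apply(offs) for i in range(self.n_members)])
        radii = np.tile(self.model.bead_radii, self.n_members)
        return pts, radii

    def world_n_term_centers(self) -> np.ndarray:
        offs = self.model.bead_offsets[self.model.n_term_indices]
        return np.concatenate(
            [self.member_world(i).apply(offs) for i in range(self.n_members)]
        )

    def world_charge_sites(self) -> np.ndarray:
        return np.concatenate(
            [self.member_world(i).apply(self.model.charge_sites) for i in range(self.n_members)]
        )

    def patch_is_free(self, member: int, polarity: str) -> bool:
        for _, _, data in self.bonds.edges(member, data=True):
            bonded_pol = "donor" if data["donor"] == member else "acceptor"
            if bonded_pol == polarity:
                return False
        return True

    def free_patches(self) -> list[tuple[int, str]]:
        out = []
        for i in range(self.n_members):
            for pol in ("donor", "acceptor"):
                if self.patch_is_free(i, pol):
                    out.append((i, pol))
        return out

    def world_patch(self, member: int, polarity: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(anchor, center-to-center, torsion) of a patch in the world frame."""
        patch = next(p for p in self.model.patches if p.polarity == polarity)
        frame = self.member_world(member)
        return (
            frame.apply(patch.anchor),
            frame.rotate(patch.center_to_center),
            frame.rotate(patch.torsion),
        )


def compose_bound_configuration(
    cluster_a: Cluster,
    patch_a: tuple[int, str],
    cluster_b: Cluster,
    patch_b: tuple[int, str],
) -> RigidTransform:
    """Rigid transform placing cluster b's frame relative to cluster a's frame
    so that the two patches are in the snapped bound configuration.

    The bound configuration aligns the patch anchors and matches the
    center-to-center and torsion vectors; it is fully determined by the local
    bonding rules and therefore deterministic.
    """
    (mem_a, pol_a), (mem_b, pol_b) = patch_a, patch_b
    if pol_a == pol_b:
        raise IncompatiblePatchError(f"cannot bind {pol_a} to {pol_b}")
    for cluster, mem, pol in ((cluster_a, mem_a, pol_a), (cluster_b, mem_b, pol_b)):
        if not cluster.patch_is_free(mem, pol):
            raise IncompatiblePatchError("patch is not free")
    step = cluster_a.model.bound_step()
    if pol_a == "acceptor":
        step = step.inverse()
    # member_b frame (in a-cluster coords) = member_a frame ∘ step
    target_b = cluster_a.member_poses[mem_a].compose(step)
    return target_b.compose(cluster_b.member_poses[mem_b].inverse())


def merge_clusters(
    cluster_a: Cluster,
    patch_a: tuple[int, str],
    cluster_b: Cluster,
    patch_b: tuple[int, str],
) -> Cluster:
    """Snap cluster b onto cluster a and return the merged rigid cluster.

    Cluster a keeps its pose; b's members are re-indexed after a's.
    """
    g = compose_bound_configuration(cluster_a, patch_a, cluster_b, patch_b)
    n_a = cluster_a.n_members
    poses = list(cluster_a.member_poses) + [
        g.compose(p) for p in cluster_b.member_poses
    ]
    bonds = nx.Graph()
    bonds.add_nodes_from(range(len(poses)))
    for u, v, data in cluster_a.bonds.edges(data=True):
        bonds.add_edge(u, v, donor=data["donor"])
    for u, v, data in cluster_b.bonds.edges(data=True):
        bonds.add_edge(u + n_a, v + n_a, donor=data["donor"] + n_a)
    donor_member = patch_a[0] if patch_a[1] == "donor" else patch_b[0] + n_a
    u = patch_a[0]
    v = patch_b[0] + n_a
    bonds.add_edge(u, v, donor=donor_member)
    return Cluster(cluster_a.model, poses, cluster_a.pose, bonds, cluster_a.id)


def assemble_ideal_chain(n: int, model: HomodimerModel | None = None) -> Cluster:
    """Open chain of n homodimers in the ideal bound geometry."""
    model = model or build_homodimer()
    if n < 1:
        raise InvalidParameterError("chain length must be >= 1")
    step = model.bound_step()
    poses = [RigidTransform.identity()]
    for _ in range(n - 1):
        poses.append(poses[-1].compose(step))
    bonds = nx.Graph()
    bonds.add_nodes_from(range(n))
    for k in range(n - 1):
        bonds.add_edge(k, k + 1, donor=k)
    return Cluster(model, poses, bonds=bonds)


def assemble_ideal_ring(n: int = 9, model: HomodimerModel | None = None) -> Cluster:
    """Closed planar ring of n homodimers.

    Raises :class:`GeometryClosureError` unless n equals the ring size of the
    bonding rule (9 by default): for any other n the chain of bound
    configurations does not return to its starting pose.
    """
    model = model or build_homodimer()
    rule = model.rule
    if n != rule.ring_size:
        chain = assemble_ideal_chain(max(n, 1), model)
        closure = chain.member_poses[-1].compose(model.bound_step())
        dt, da = closure.deviation_from_identity()
        raise GeometryClosureError(
            f"a chain of {n} does not close under the {rule.ring_size}-fold rule "
            f"(closure residual {dt:.3f} nm / {math.degrees(da):.1f} deg)"
        )
    cluster = assemble_ideal_chain(n, model)
    cluster.bonds.add_edge(n - 1, 0, donor=n - 1)
    return cluster


# ---------------------------------------------------------------------------
# ring detection and overlap


def detect_rings(bonds: nx.Graph) -> list[set]:
    """Connected components of a bond graph that are closed rings.

    A component is a ring iff its bond count equals its member count and
    every member has exactly two neighbors.  Any component whose bond count
    equals its member count *without* all degrees being two is impossible
    under the two-patch valence rule and raises :class:`ConsistencyError`.
    """
    rings = []
    for comp in nx.connected_components(bonds):
        sub = bonds.subgraph(comp)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        if e == n and n >= 3:
            if all(d == 2 for _, d in sub.degree):
                rings.append(set(comp))
            else:
                raise ConsistencyError(
                    "component with bond count == member count but degree != 2"
                )
    return rings


def check_overlap(
    cluster_a: Cluster, cluster_b: Cluster, tol: float = 0.0
) -> list[tuple[int, int, float]]:
    """Overlapping bead pairs between two clusters.

    Returns (bead index in a, bead index in b, penetration depth) for every
    pair whose center distance is below the sum of radii minus ``tol``.
    The report is symmetric: swapping the arguments swaps the index columns.
    """
    pts_a, rad_a = cluster_a.world_beads()
    pts_b, rad_b = cluster_b.world_beads()
    diff = pts_a[:, None, :] - pts_b[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    touch = rad_a[:, None] + rad_b[None, :]
    ia, ib = np.nonzero(dist < touch - tol)
    return [(int(i), int(j), float(touch[i, j] - dist[i, j])) for i, j in zip(ia, ib)]


def hub_diameter(ring: Cluster) -> float:
    """Diameter of the circle through the N-terminal bead centers of a ring."""
    pts = ring.world_n_term_centers()
    center = pts.mean(axis=0)
    return 2.0 * float(np.mean(np.linalg.norm(pts - center, axis=1)))
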