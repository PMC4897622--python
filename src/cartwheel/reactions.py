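"""Two-step reversible patch–patch reaction kinetics.

Association is a two-step process: clusters diffuse until two complementary
free patches form an *encounter* — their anchors closer than a distance
tolerance and their center-to-center and torsion vectors aligned within
angular tolerances — and from the encounter the bond forms stochastically
with probability ``1 - exp(-k_a Δt)`` per step.  A formed bond snaps the
partners into the exact bound configuration.  Every bond dissociates with
probability ``1 - exp(-k_d Δt)`` per step, after which the fragments are
re-placed by drawing the relative configuration uniformly from the
encounter window, which together with the rate calibration below satisfies
detailed balance.

The last bond of a ring is special: a rigid 9-chain holds its two free ends
permanently in the bound geometry, so closure does not require a diffusional
encounter and proceeds at the enhanced rate ``k_ring``.  The associated ring
stabilization free energy is ``E = -k_BT ln(k_ring / k_a)`` (E ≤ 0).

Calibration: for one donor–acceptor pair the stationary bound:unbound odds
in a volume V are (p_a/p_d)·(v_b/V), where ``v_b`` is the configuration
volume of the encounter window.  Requiring the two-state equilibrium to
reproduce a measured dissociation constant K_D fixes

    p_d = p_a · K_D · N_A · v_b        (p = 1 - exp(-k Δt))

per bond.  The probability (rather than rate) form keeps the calibration
exact at finite Δt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry as geo
from .units import PER_NM3_PER_UM


class CalibrationError(ValueError):
    """Encounter window volume is degenerate or affinity unphysical."""


# ---------------------------------------------------------------------------
# encounter window


@dataclass(frozen=True)
class EncounterWindow:
    """Range of relative patch configurations that counts as an encounter.

    ``max_anchor_dist``: maximum distance between the two patch anchors (the
    anchors coincide in the bound configuration, so this is the tolerance
    beyond bonding distance).  ``max_align_deg``: maximum angle between the
    donor center-to-center vector and the negated acceptor center-to-center
    vector.  ``max_torsion_deg``: maximum angle between the torsion vectors.
    """

    max_anchor_dist: float = 3.0  # nm
    max_align_deg: float = 75.0
    max_torsion_deg: float = 75.0

    def __post_init__(self):
        if self.max_anchor_dist <= 0 or self.max_align_deg <= 0 or self.max_torsion_deg <= 0:
            raise CalibrationError("window tolerances must be positive")

    def contains(self, anchor_dist: float, align_deg: float, torsion_deg: float) -> bool:
        return (
            anchor_dist <= self.max_anchor_dist
            and align_deg <= self.max_align_deg
            and torsion_deg <= self.max_torsion_deg
        )

    def rotation_fraction(self, n_samples: int = 200_000, seed: int = 2024) -> float:
        """Fraction of uniformly random relative orientations inside the
        angular part of the window (Monte Carlo, deterministic for a seed)."""
        rng = np.random.default_rng(seed)
        # random rotations via normalized quaternions
        q = rng.normal(size=(n_samples, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        w, x, y, z = q.T
        # rotated -c2c target: R @ e_c where e_c is the partner c2c vector; by
        # symmetry we may take the target axes as e_x (alignment) and e_z
        # (torsion) and ask for R e_x within the alignment cone of e_x and
        # R e_z within the torsion cone of e_z.
        r_xx = 1.0 - 2.0 * (y * y + z * z)
        r_zz = 1.0 - 2.0 * (x * x + y * y)
        cos_align = math.cos(math.radians(self.max_align_deg))
        cos_tors = math.cos(math.radians(self.max_torsion_deg))
        inside = (r_xx >= cos_align) & (r_zz >= cos_tors)
        return float(inside.mean())

    def volume(self, n_samples: int = 200_000, seed: int = 2024) -> float:
        """Configuration-space volume v_b of the window in nm³.

        The translational and orientational constraints factorize exactly:
        for any admissible orientation the partner origin may lie anywhere in
        a ball of radius ``max_anchor_dist`` around the anchor-coincident
        position.
        """
        ball = 4.0 / 3.0 * math.pi * self.max_anchor_dist**3
        return ball * self.rotation_fraction(n_samples, seed)

    def effective_molarity(self, **kw) -> float:
        """1/(N_A v_b) in μM: the effective concentration a tethered partner
        held inside the window presents to its patch (the ring-closure
        effective molarity)."""
        return 1.0 / (self.volume(**kw) * PER_NM3_PER_UM)


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ReactionParameters:
    """Microscopic rates (1/ns), time step (ns) and encounter window."""

    k_a: float
    k_d: float
    delta_t: float = 1.0
    ring_energy: float = 0.0  # E in k_BT, <= 0
    window: EncounterWindow = field(default_factory=EncounterWindow)

    def __post_init__(self):
        if self.k_a < 0 or self.k_d < 0:
            raise CalibrationError("rates must be non-negative")
        if self.delta_t <= 0:
            raise CalibrationError("time step must be positive")
        if self.ring_energy > 0:
            raise CalibrationError("ring stabilization energy must be <= 0")

    @property
    def k_ring(self) -> float:
        """Last-bond association rate, k_ring = k_a exp(-E) with E <= 0."""
        return self.k_a * math.exp(-self.ring_energy)

    @property
    def p_assoc(self) -> float:
        return -math.expm1(-self.k_a * self.delta_t)

    @property
    def p_dissoc(self) -> float:
        return -math.expm1(-self.k_d * self.delta_t)

    @property
    def p_ring(self) -> float:
        return -math.expm1(-min(self.k_ring * self.delta_t, 700.0))

    def with_ring_energy(self, energy: float) -> "ReactionParameters":
        return replace(self, ring_energy=energy)


@dataclass(frozen=True)
class AffinityCalibration:
    """Measured equilibrium dissociation constants (μM).

    ``kd_nn`` is the N-term/N-term affinity that calibrates the patch bond;
    ``kd_cc`` (coiled-coil homodimerization) is informational only, since
    homodimers are the smallest assembly unit.
    """

    kd_nn: float = 60.0
    kd_cc: float = 1.0

    def __post_init__(self):
        if self.kd_nn <= 0 or self.kd_cc <= 0:
            raise CalibrationError("dissociation constants must be positive")


def calibrate_rates(
    calibration: AffinityCalibration | float = AffinityCalibration(),
    window: EncounterWindow | None = None,
    k_a: float = 1.0,
    delta_t: float = 1.0,
    ring_energy: float = 0.0,
    window_volume: float | None = None,
) -> ReactionParameters:
    """Choose (k_a, k_d) reproducing the measured N-term affinity.

    ``k_a`` sets the speed of the bound-state transition from the encounter
    (chosen large so association is diffusion-limited); ``k_d`` follows from
    the per-bond two-state equilibrium over the encounter window,

        (1 - exp(-k_d Δt)) = (1 - exp(-k_a Δt)) · K_D · N_A · v_b.
    """
    kd_um = calibration.kd_nn if isinstance(calibration, AffinityCalibration) else float(calibration)
    window = window or EncounterWindow()
    v_b = window.volume() if window_volume is None else window_volume
    if v_b <= 0:
        raise CalibrationError("encounter window volume must be positive")
    p_a = -math.expm1(-k_a * delta_t)
    p_d = p_a * kd_um * PER_NM3_PER_UM * v_b
    if p_d >= 1.0:
        raise CalibrationError(
            "calibration requires p_dissoc >= 1; reduce k_a, Δt or the window"
        )
    k_d = -math.log1p(-p_d) / delta_t
    return ReactionParameters(
        k_a=k_a, k_d=k_d, delta_t=delta_t, ring_energy=ring_energy, window=window
    )


#: named parameter presets: set 1 (bulk assembly; calibration anchored to the
#: measured N-term affinity and the diffusion-limited regime) and set 2
#: (scaffold scenarios; a larger encounter range and coarser step trade
#: kinetic resolution for speed — equilibria stay pinned by the calibration)
PARAMETER_SETS: dict[str, dict] = {
    "set1": dict(window=EncounterWindow(3.0, 75.0, 75.0), k_a=1.0, delta_t=1.0),
    "set2": dict(window=EncounterWindow(3.5, 85.0, 85.0), k_a=1.0, delta_t=2.0),
}


def parameter_set(
    name: str = "set1", ring_energy: float = 0.0, kd_nn: float = 60.0
) -> ReactionParameters:
    """Calibrated :class:`ReactionParameters` for a named preset."""
    if name not in PARAMETER_SETS:
        raise CalibrationError(f"unknown parameter set {name!r}")
    preset = PARAMETER_SETS[name]
    return calibrate_rates(
        AffinityCalibration(kd_nn=kd_nn),
        preset["window"],
        k_a=preset["k_a"],
        delta_t=preset["delta_t"],
        ring_energy=ring_energy,
    )


# ---------------------------------------------------------------------------
# encounters over explicit clusters (reference implementation; the
# performance engine in cartwheel.engine uses the same rules on packed arrays)


@dataclass
class EncounterPair:
    cluster_a: "geo.Cluster"
    patch_a: tuple[int, str]  # donor
    cluster_b: "geo.Cluster"
    patch_b: tuple[int, str]  # acceptor
    anchor_dist: float
    align_deg: float
    torsion_deg: float
    is_ring_closing: bool


def _patch_geometry(cluster_a, patch_a, cluster_b, patch_b):
    an_a, c2c_a, tor_a = cluster_a.world_patch(*patch_a)
    an_b, c2c_b, tor_b = cluster_b.world_patch(*patch_b)
    dist = float(np.linalg.norm(an_a - an_b))
    align = math.degrees(math.acos(np.clip(-np.dot(c2c_a, c2c_b), -1.0, 1.0)))
    torsion = math.degrees(math.acos(np.clip(np.dot(tor_a, tor_b), -1.0, 1.0)))
    return dist, align, torsion


def find_encounters(
    clusters: list, params: ReactionParameters
) -> list[EncounterPair]:
    """All complementary free patch pairs currently inside the window.

    Pairs whose binding closes a ring (the two patches belong to the same
    open chain of the full ring size) are flagged ``is_ring_closing``.
    """
    window = params.window
    out = []
    # free patches per cluster
    free = [
        (c, [(m, pol) for (m, pol) in c.free_patches()]) for c in clusters
    ]
    for idx_a, (ca, patches_a) in enumerate(free):
        donors = [p for p in patches_a if p[1] == "donor"]
        for idx_b, (cb, patches_b) in enumerate(free):
            acceptors = [p for p in patches_b if p[1] == "acceptor"]
            for pa in donors:
                for pb in acceptors:
                    same = ca is cb
                    if same and (pa[0] == pb[0] or ca.n_members != ca.model.rule.ring_size):
                        continue
                    dist, align, torsion = _patch_geometry(ca, pa, cb, pb)
                    if window.contains(dist, align, torsion):
                        out.append(
                            EncounterPair(ca, pa, cb, pb, dist, align, torsion, same)
                        )
    return out


def attempt_association(
    pair: EncounterPair,
    params: ReactionParameters,
    rng: np.random.Generator,
    others: list | None = None,
):
    """Stochastic association attempt; returns the merged cluster or None.

    Uses ``p_ring`` for ring-closing pairs.  If the snapped configuration
    overlaps itself or any cluster in ``others``, the attempt is rejected and
    the system keeps its previous configuration.
    """
    p = params.p_ring if pair.is_ring_closing else params.p_assoc
    if rng.random() >= p:
        return None
    if pair.is_ring_closing:
        cluster = pair.cluster_a
        closed = geo.Cluster(
            cluster.model,
            list(cluster.member_poses),
            cluster.pose,
            cluster.bonds.copy(),
            cluster.id,
        )
        closed.bonds.add_edge(pair.patch_a[0], pair.patch_b[0], donor=pair.patch_a[0])
        return closed
    merged = geo.merge_clusters(pair.cluster_a, pair.patch_a, pair.cluster_b, pair.patch_b)
    for other in others or []:
        if other is pair.cluster_a or other is pair.cluster_b:
            continue
        if geo.check_overlap(merged, other, tol=1e-9):
            return None
    if _self_overlap(merged):
        return None
    return merged


def _self_overlap(cluster: "geo.Cluster") -> bool:
    """Overlap between beads of non-adjacent members of one cluster."""
    pts, radii = cluster.world_beads()
    nb = len(cluster.model.beads)
    n = cluster.n_members
    for i in range(n):
        for j in range(i + 1, n):
            if cluster.bonds.has_edge(i, j):
                continue
            d = pts[i * nb : (i + 1) * nb, None, :] - pts[None, j * nb : (j + 1) * nb, :]
            dist = np.sqrt((d**2).sum(axis=2))
            touch = radii[i * nb : (i + 1) * nb, None] + radii[None, j * nb : (j + 1) * nb]
            if np.any(dist < touch - 1e-9):
                return True
    return False


def sample_window_placement(
    window: EncounterWindow, rng: np.random.Generator, max_tries: int = 100_000
) -> geo.RigidTransform:
    """Uniform draw from the encounter window, as a perturbation of the bound
    configuration applied about the patch anchor.

    Orientations are rejection-sampled from the uniform measure on SO(3)
    restricted to the angular window; the anchor offset is uniform in the
    tolerance ball.  Used by dissociation re-placement (detailed balance).
    """
    cos_align = math.cos(math.radians(window.max_align_deg))
    cos_tors = math.cos(math.radians(window.max_torsion_deg))
    for _ in range(max_tries):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        if 1.0 - 2.0 * (y * y + z * z) < cos_align:
            continue
        if 1.0 - 2.0 * (x * x + y * y) < cos_tors:
            continue
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        break
    else:  # pragma: no cover
        raise RuntimeError("window rejection sampling failed")
    while True:
        off = rng.uniform(-1.0, 1.0, size=3) * window.max_anchor_dist
        if np.dot(off, off) <= window.max_anchor_dist**2:
            break
    return geo.RigidTransform(rot, off)


def attempt_dissociation(
    cluster: "geo.Cluster",
    bond: tuple[int, int],
    params: ReactionParameters,
    rng: np.random.Generator,
) -> list | None:
    """Stochastic dissociation of one bond; returns the fragment list or None.

    Breaking a non-ring bond splits the cluster in two; the donor-side
    fragment is re-placed by a uniform draw from the encounter window.
    Opening one bond of a ring leaves a single connected 9-chain (two bonds
    must open for a ring to fragment), so the cluster merely loses its ring
    status and keeps its geometry.
    """
    if rng.random() >= params.p_dissoc:
        return None
    u, v = bond
    data = cluster.bonds.edges[u, v]
    bonds = cluster.bonds.copy()
    bonds.remove_edge(u, v)
    if nx_is_connected(bonds):
        opened = geo.Cluster(
            cluster.model, list(cluster.member_poses), cluster.pose, bonds, cluster.id
        )
        return [opened]
    donor_member = data["donor"]
    acceptor_member = v if donor_member == u else u
    import networkx as nx

    comp_acc = nx.node_connected_component(bonds, acceptor_member)
    comp_don = nx.node_connected_component(bonds, donor_member)

    def extract(members):
        members = sorted(members)
        remap = {m: i for i, m in enumerate(members)}
        sub = nx.Graph()
        sub.add_nodes_from(range(len(members)))
        for a, b, d in bonds.subgraph(members).edges(data=True):
            sub.add_edge(remap[a], remap[b], donor=remap[d["donor"]])
        poses = [cluster.member_poses[m] for m in members]
        return geo.Cluster(cluster.model, poses, cluster.pose, sub), remap

    frag_a, _ = extract(comp_acc)
    frag_d, remap_d = extract(comp_don)
    # re-place the donor fragment: perturb about the (previously bonded)
    # donor patch anchor by a uniform window draw
    patch = next(p for p in cluster.model.patches if p.polarity == "donor")
    anchor_world = cluster.member_world(donor_member).apply(patch.anchor)
    pert = sample_window_placement(params.window, rng)
    # conjugate the canonical window rotation (axes: e_x = center-to-center,
    # e_z = torsion) into the actual patch frame, then rotate the donor
    # fragment about the anchor and offset it within the tolerance ball
    _, c_w, t_w = frag_d.world_patch(remap_d[donor_member], "donor")
    axes = np.column_stack([c_w, np.cross(t_w, c_w), t_w])
    rot_world = axes @ pert.rotation @ axes.T
    move_world = geo.RigidTransform(
        rot_world, anchor_world - rot_world @ anchor_world + pert.translation
    )
    # fold into the fragment's pose (fragment keeps parent pose)
    frag_d.pose = move_world.compose(frag_d.pose)
    return [frag_a, frag_d]


def nx_is_connected(g) -> bool:
    import networkx as nx

    return nx.is_connected(g) if g.number_of_nodes() > 0 else True
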