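"""Cylindrical, spherical and semi-spherical scaffolds.

A scaffold is a rigid body with a steep soft-core repulsion starting at the
core radius ``R_s`` — steep enough to act as an effective hard core while
keeping the dynamics well-behaved — surrounded by an attractive layer of
width ``ΔR_s`` that exerts a constant radial force on the homodimer charge
sites.  The layer potential is piecewise linear: a site crossing the full
layer gains ``l·k_BT``, with the dimensionless parameter ``l`` setting the
interaction strength.  The semi-sphere is embedded in a planar wall at
z = 0 and attracts only in the upper half-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Cluster, InvalidParameterError

SHAPES = ("cylinder", "sphere", "semisphere")


@dataclass(frozen=True)
class Scaffold:
    """Scaffold geometry and interaction strength.

    ``center``: sphere center or a point on the cylinder axis (the cylinder
    axis is parallel to z, matching the periodic direction).  ``strength``
    is the dimensionless interaction parameter l (total layer depth in k_BT
    per charge site); ``k_rep`` the soft-core stiffness in k_BT/nm².  The
    default stiffness is the largest value keeping the overdamped Euler
    update of the most mobile cluster stable at nanosecond time steps
    (mobility × stiffness × Δt < 1); equilibrium penetration is then a few
    tenths of a nm, small against the layer width.
    """

    shape: str = "cylinder"
    r_s: float = 9.0
    dr_s: float = 3.0
    strength: float = 2.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    k_rep: float = 2.0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise InvalidParameterError(f"unknown scaffold shape {self.shape!r}")
        if self.r_s <= 0 or self.dr_s <= 0 or self.strength < 0:
            raise InvalidParameterError("require R_s > 0, ΔR_s > 0, l >= 0")

    @property
    def outer_radius(self) -> float:
        return self.r_s + self.dr_s

    def radial(self, site: np.ndarray) -> tuple[float, np.ndarray]:
        """Distance from the core axis/center and the outward unit vector."""
        site = np.asarray(site, float)
        d = site - self.center
        if self.shape == "cylinder":
            d = np.array([d[0], d[1], 0.0])
        r = float(np.linalg.norm(d))
        if r < 1e-12:
            return 0.0, np.zeros(3)
        return r, d / r


def scaffold_force(site: np.ndarray, scaffold: Scaffold, attract: bool = True) -> np.ndarray:
    """Force (k_BT/nm) on a point site.

    Inside the core: steep outward harmonic repulsion.  In the layer
    (R_s ≤ r < R_s + ΔR_s): constant inward force of magnitude l·k_BT/ΔR_s
    if ``attract`` (charge sites; plain beads only feel the core).  Outside:
    zero.  The semi-sphere exerts no attraction below the wall plane.
    """
    r, u = scaffold.radial(site)
    if r <= 0.0:
        return np.zeros(3)
    if r < scaffold.r_s:
        return scaffold.k_rep * (scaffold.r_s - r) * u
    if attract and r < scaffold.outer_radius:
        if scaffold.shape == "semisphere" and np.asarray(site, float)[2] <= 0.0:
            return np.zeros(3)
        return -(scaffold.strength / scaffold.dr_s) * u
    return np.zeros(3)


def cluster_scaffold_drift(cluster: Cluster, scaffold: Scaffold) -> tuple[np.ndarray, np.ndarray]:
    """Net force and torque (about the cluster frame origin) on a cluster.

    Sums the layer force over all charge sites of all members plus the core
    repulsion over all beads; the net attraction scales with member count,
    which is the basis of the size-dependent retention (local cooperativity).
    """
    force = np.zeros(3)
    torque = np.zeros(3)
    origin = cluster.pose.translation
    for site in cluster.world_charge_sites():
        f = scaffold_force(site, scaffold, attract=True)
        force += f
        torque += np.cross(site - origin, f)
    pts, _ = cluster.world_beads()
    for p in pts:
        f = scaffold_force(p, scaffold, attract=False)
        force += f
        torque += np.cross(p - origin, f)
    return force, torque


def wall_force(position: np.ndarray, radius: float, k_wall: float = 2.0) -> np.ndarray:
    """Harmonic repulsion from the planar wall at z = 0 on a bead.

    Nonzero only when the bead penetrates the half-space z < radius.
    """
    pen = radius - float(np.asarray(position, float)[2])
    if pen <= 0.0:
        return np.zeros(3)
    return np.array([0.0, 0.0, k_wall * pen])


def layer_binding_energy(scaffold: Scaffold, n_quad: int = 10_001) -> float:
    """Numerical check of the layer depth: ∫ F·dr across the layer (k_BT)."""
    rs = np.linspace(scaffold.r_s, scaffold.outer_radius, n_quad)
    mag = np.array(
        [
            np.linalg.norm(scaffold_force(scaffold.center + np.array([r, 0.0, 1e-9]), scaffold))
            for r in rs
        ]
    )
    return float(np.trapezoid(mag, rs))
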