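"""Rigid bead-model hydrodynamics.

Anisotropic translational and rotational diffusion tensors of rigid bead
assemblies are computed with a Kirkwood–Riseman-type calculation: the grand
mobility matrix of all beads is built from Rotne–Prager–Yamakawa pair
mobilities (generalized to unequal radii), inverted to a friction matrix,
contracted onto rigid-body motion, and supplemented with the standard
rotational volume correction so that a single bead recovers the
Stokes–Einstein–Debye limit exactly.  Tensors are reported at the center of
diffusion, the point at which the translation–rotation coupling of the
diffusion matrix is symmetric.

Units: lengths nm, time ns, energy k_BT (see :mod:`cartwheel.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import VISCOSITY_WATER


class SingularHydrodynamicsError(ValueError):
    """Bead set is hydrodynamically degenerate (e.g. coincident beads)."""


def _cross_matrix(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def rpy_grand_mobility(points: np.ndarray, radii: np.ndarray, eta: float) -> np.ndarray:
    """3N×3N translational grand mobility (Rotne–Prager level, unequal radii)."""
    points = np.asarray(points, float)
    radii = np.asarray(radii, float)
    n = len(points)
    m = np.zeros((3 * n, 3 * n))
    eye = np.eye(3)
    for i in range(n):
        m[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = eye / (6.0 * math.pi * eta * radii[i])
    for i in range(n):
        for j in range(i + 1, n):
            rij = points[i] - points[j]
            r = np.linalg.norm(rij)
            if r < 1e-9:
                raise SingularHydrodynamicsError("coincident beads")
            rhat = np.outer(rij, rij) / (r * r)
            a2 = radii[i] ** 2 + radii[j] ** 2
            block = (
                (1.0 + a2 / (3.0 * r * r)) * eye + (1.0 - a2 / (r * r)) * rhat
            ) / (8.0 * math.pi * eta * r)
            m[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            m[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
    return m


def _rigid_resistance(
    friction: np.ndarray, points: np.ndarray, radii: np.ndarray, eta: float, origin: np.ndarray
) -> np.ndarray:
    """6×6 rigid-body resistance about ``origin`` from the bead friction matrix."""
    n = len(points)
    rel = points - origin
    xi_tt = np.zeros((3, 3))
    xi_rt = np.zeros((3, 3))
    xi_tw = np.zeros((3, 3))
    xi_rr = np.zeros((3, 3))
    cross = [_cross_matrix(r) for r in rel]
    for i in range(n):
        for j in range(n):
            z = friction[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
            xi_tt += z
            xi_rt += cross[i] @ z
            xi_tw += -z @ cross[j]
            xi_rr += -cross[i] @ z @ cross[j]
    # rotational volume correction (exact single-sphere rotational friction)
    xi_rr += 8.0 * math.pi * eta * float(np.sum(radii**3)) * np.eye(3)
    top = np.hstack([xi_tt, xi_tw])
    bot = np.hstack([xi_rt, xi_rr])
    return np.vstack([top, bot])


def _center_of_diffusion_shift(mob6: np.ndarray) -> np.ndarray:
    """Shift a from the current origin to the center of diffusion.

    Solves [a]x M_rr + M_rr [a]x = M_tr - M_tr^T for a (equivalently
    (tr(M_rr) I - M_rr) a = vec of the antisymmetric part of M_tr).
    """
    m_tr = mob6[:3, 3:]
    m_rr = mob6[3:, 3:]
    s = m_tr - m_tr.T

    def antisym_vec(mat):
        return np.array([mat[2, 1] - mat[1, 2], mat[0, 2] - mat[2, 0], mat[1, 0] - mat[0, 1]]) / 2.0

    basis = np.eye(3)
    cols = []
    for e in basis:
        f = _cross_matrix(e) @ m_rr + m_rr @ _cross_matrix(e)
        cols.append(antisym_vec(f))
    a_mat = np.column_stack(cols)
    # least squares: for isotropic bodies the system is degenerate and any
    # point is a center of diffusion; pick the minimum-norm shift
    shift, *_ = np.linalg.lstsq(a_mat, antisym_vec(s), rcond=None)
    return shift


@dataclass(frozen=True)
class DiffusionProperties:
    """Rigid-body diffusion of a bead assembly, body frame, about the center
    of diffusion.

    ``mobility`` maps (force, torque) in units of k_BT/nm to (velocity,
    angular velocity); ``diffusion`` = k_BT × mobility has nm²/ns and
    rad²/ns diagonals.
    """

    mobility: np.ndarray  # 6x6
    diffusion: np.ndarray  # 6x6
    center_of_diffusion: np.ndarray  # (3,) body frame

    @property
    def translational(self) -> np.ndarray:
        return self.diffusion[:3, :3]

    @property
    def rotational(self) -> np.ndarray:
        return self.diffusion[3:, 3:]

    @property
    def coupling(self) -> np.ndarray:
        return self.diffusion[:3, 3:]

    @property
    def d_trans_mean(self) -> float:
        """Orientation-averaged translational diffusion coefficient (nm²/ns)."""
        return float(np.trace(self.translational)) / 3.0


def compute_diffusion_properties(
    points: np.ndarray,
    radii: np.ndarray,
    eta: float = VISCOSITY_WATER,
    kt: float = 1.0,
) -> DiffusionProperties:
    """Diffusion properties of a rigid bead assembly.

    ``points``/``radii`` are the bead centers (body frame, nm) and radii.
    Raises :class:`SingularHydrodynamicsError` for degenerate bead sets.
    """
    points = np.atleast_2d(np.asarray(points, float))
    radii = np.atleast_1d(np.asarray(radii, float))
    if len(points) == 0:
        raise SingularHydrodynamicsError("empty bead set")
    grand = rpy_grand_mobility(points, radii, eta)
    friction = np.linalg.inv(grand)
    origin = points.mean(axis=0)
    xi = _rigid_resistance(friction, points, radii, eta, origin)
    mob = np.linalg.inv(xi)
    shift = _center_of_diffusion_shift(mob)
    center = origin + shift
    xi_cd = _rigid_resistance(friction, points, radii, eta, center)
    mob_cd = np.linalg.inv(xi_cd)
    mob_cd = 0.5 * (mob_cd + mob_cd.T)
    return DiffusionProperties(
        mobility=mob_cd, diffusion=kt * mob_cd, center_of_diffusion=center
    )


def cluster_diffusion_properties(cluster, eta: float = VISCOSITY_WATER, kt: float = 1.0):
    """Diffusion properties of a :class:`~cartwheel.geometry.Cluster`.

    Evaluated in the cluster's own frame (the world pose is irrelevant to
    the body-frame tensors).  For the canonical chain/ring species prefer
    the cached tables in :mod:`cartwheel.species`.
    """
    offs = cluster.model.bead_offsets
    pts = np.concatenate([p.apply(offs) for p in cluster.member_poses])
    radii = np.tile(cluster.model.bead_radii, cluster.n_members)
    return compute_diffusion_properties(pts, radii, eta=eta, kt=kt)
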