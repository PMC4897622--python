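"""Canonical cluster species: rigid chains of 1–9 homodimers and the ring.

Because bound configurations snap to the exact local geometry and clusters
are rigid, every oligomer of a given size has one and the same shape: an arc
of the ideal ring.  The open 9-chain and the closed ring share identical
bead geometry; they differ only in bond count.  This module precomputes, per
species, the member placements, bead/charge-site coordinates and the rigid
body diffusion tensors in a canonical body frame centered at the center of
diffusion.  The Brownian-dynamics engine works entirely on these tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import ModelParams, RigidTransform, build_homodimer
from .hydrodynamics import DiffusionProperties, compute_diffusion_properties
from .units import VISCOSITY_WATER

#: species indices: 0..8 are open chains of size 1..9, RING_SPECIES is the ring
RING_SPECIES = 9
N_SPECIES = 10


def species_size(species: int) -> int:
    return 9 if species == RING_SPECIES else species + 1


def species_is_ring(species: int) -> bool:
    return species == RING_SPECIES


@dataclass(frozen=True)
class SpeciesGeometry:
    """One rigid species in its canonical (center-of-diffusion) frame."""

    species: int
    size: int
    is_ring: bool
    member_quat: np.ndarray  # (size, 4) scalar-first quaternions
    member_pos: np.ndarray  # (size, 3)
    beads: np.ndarray  # (n_beads, 3)
    bead_radii: np.ndarray  # (n_beads,)
    charge_sites: np.ndarray  # (2*size, 3)
    diffusion: DiffusionProperties
    # free-end patches; None for the ring
    donor_anchor: np.ndarray | None = None
    donor_c2c: np.ndarray | None = None
    donor_torsion: np.ndarray | None = None
    acceptor_anchor: np.ndarray | None = None
    acceptor_c2c: np.ndarray | None = None
    acceptor_torsion: np.ndarray | None = None


def _quat_from_matrix(m: np.ndarray) -> np.ndarray:
    q = Rotation.from_matrix(m).as_quat()  # x, y, z, w
    return np.array([q[3], q[0], q[1], q[2]])


@lru_cache(maxsize=8)
def build_species_tables(
    params: ModelParams | None = None, eta: float = VISCOSITY_WATER
) -> tuple[SpeciesGeometry, ...]:
    """All ten species for a homodimer model (cached per parameter set)."""
    params = params or ModelParams()
    model = build_homodimer(params)
    step = model.bound_step()
    offs = model.bead_offsets
    radii1 = model.bead_radii
    donor = next(p for p in model.patches if p.polarity == "donor")
    acceptor = next(p for p in model.patches if p.polarity == "acceptor")

    out = []
    for species in range(N_SPECIES):
        size = species_size(species)
        is_ring = species_is_ring(species)
        poses = [RigidTransform.identity()]
        for _ in range(size - 1):
            poses.append(poses[-1].compose(step))
        beads = np.concatenate([p.apply(offs) for p in poses])
        radii = np.tile(radii1, size)
        charges = np.concatenate([p.apply(model.charge_sites) for p in poses])
        dp = compute_diffusion_properties(beads, radii, eta=eta)
        cd = dp.center_of_diffusion
        member_pos = np.array([p.translation - cd for p in poses])
        member_quat = np.array([_quat_from_matrix(p.rotation) for p in poses])
        kw = {}
        if not is_ring:
            last = poses[-1]
            first = poses[0]
            kw = dict(
                donor_anchor=last.apply(donor.anchor) - cd,
                donor_c2c=last.rotate(donor.center_to_center),
                donor_torsion=last.rotate(donor.torsion),
                acceptor_anchor=first.apply(acceptor.anchor) - cd,
                acceptor_c2c=first.rotate(acceptor.center_to_center),
                acceptor_torsion=first.rotate(acceptor.torsion),
            )
        out.append(
            SpeciesGeometry(
                species=species,
                size=size,
                is_ring=is_ring,
                member_quat=member_quat,
                member_pos=member_pos,
                beads=beads - cd,
                bead_radii=radii,
                charge_sites=charges - cd,
                diffusion=dp,
                **kw,
            )
        )
    return tuple(out)


def mean_translational_diffusion(params: ModelParams | None = None) -> np.ndarray:
    """Orientation-averaged translational D (nm²/ns) for chain sizes 1..9."""
    tables = build_species_tables(params)
    return np.array([tables[s].diffusion.d_trans_mean for s in range(9)])
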