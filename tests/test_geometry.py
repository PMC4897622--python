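"""Homodimer construction, ring closure geometry, ring detection, overlap."""

import math

import networkx as nx
import numpy as np
import pytest

from cartwheel.geometry import (
    Cluster,
    GeometryClosureError,
    IncompatiblePatchError,
    InvalidParameterError,
    ModelParams,
    RigidTransform,
    assemble_ideal_chain,
    assemble_ideal_ring,
    build_homodimer,
    check_overlap,
    compose_bound_configuration,
    detect_rings,
    hub_diameter,
    merge_clusters,
)


class TestHomodimer:
    def test_default_bead_layout(self, model):
        assert len(model.beads) == 5
        radii = [b.radius for b in model.beads]
        kinds = [b.kind for b in model.beads]
        assert radii[:2] == [1.979, 1.979] and kinds[:2] == ["N-term"] * 2
        assert radii[2:] == [1.182] * 3 and kinds[2:] == ["coiled-coil"] * 3

    def test_two_patches_two_charge_sites(self, model):
        assert len(model.patches) == 2
        assert {p.polarity for p in model.patches} == {"donor", "acceptor"}
        assert model.charge_sites.shape == (2, 3)
        # charge sites sit on the N-head surfaces facing the ring axis
        for site, bead in zip(model.charge_sites, model.beads[:2]):
            assert np.linalg.norm(site - bead.offset) == pytest.approx(bead.radius)
            assert np.linalg.norm(site - model.hub_center) == pytest.approx(
                model.hub_radius - bead.radius
            )

    def test_patch_vectors_unit_and_orthogonal(self, model):
        for p in model.patches:
            assert np.linalg.norm(p.center_to_center) == pytest.approx(1.0)
            assert np.linalg.norm(p.torsion) == pytest.approx(1.0)
            assert abs(np.dot(p.center_to_center, p.torsion)) < 1e-12

    def test_coiled_coil_extension_spans_native_length(self):
        # native SAS-6 coiled-coil is ~50 nm; extension adds spheres only
        extra = 18
        model = build_homodimer(ModelParams(extra_cc_beads=extra))
        assert len(model.beads) == 5 + extra
        cc_x = [b.offset[0] for b in model.beads if b.kind == "coiled-coil"]
        span = max(cc_x) - min(cc_x) + 2 * 1.182
        assert span == pytest.approx(50.0, abs=5.0)
        assert len(model.patches) == 2  # patches unchanged

    @pytest.mark.parametrize("bad", [dict(r_n=-1.0), dict(r_cc=0.0), dict(extra_cc_beads=-1)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            build_homodimer(ModelParams(**bad))


class TestBoundConfiguration:
    def test_nine_fold_composition_is_identity(self, model):
        step = model.bound_step()
        t = RigidTransform.identity()
        for _ in range(9):
            t = t.compose(step)
        d_trans, d_rot = t.deviation_from_identity()
        assert d_trans < 1e-6
        assert d_rot < 1e-6

    @pytest.mark.parametrize("n", [5, 8, 10])
    def test_other_lengths_leave_residual(self, model, n):
        step = model.bound_step()
        t = RigidTransform.identity()
        for _ in range(n):
            t = t.compose(step)
        d_trans, d_rot = t.deviation_from_identity()
        assert d_trans > 1.0 or d_rot > 0.1

    def test_bound_pair_spoke_angle_and_plane(self, model):
        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)
        g = compose_bound_configuration(a, (0, "donor"), b, (0, "acceptor"))
        spoke_a = np.array([1.0, 0.0, 0.0])
        spoke_b = g.rotate(spoke_a)
        angle = math.degrees(math.acos(np.clip(np.dot(spoke_a, spoke_b), -1, 1)))
        assert angle == pytest.approx(40.0, abs=1e-6)
        # N-term hubs lie in a common plane
        b_placed = Cluster(model, [g])
        pts = np.vstack([a.world_n_term_centers(), b_placed.world_n_term_centers()])
        assert np.ptp(pts[:, 2]) < 1e-9

    def test_bound_pair_anchors_coincide(self, model):
        a = assemble_ideal_chain(1)
        b = Cluster(
            model,
            [compose_bound_configuration(a, (0, "donor"), assemble_ideal_chain(1), (0, "acceptor"))],
        )
        an_a, c2c_a, tor_a = a.world_patch(0, "donor")
        an_b, c2c_b, tor_b = b.world_patch(0, "acceptor")
        assert np.linalg.norm(an_a - an_b) < 1e-9
        assert np.dot(c2c_a, c2c_b) == pytest.approx(-1.0)
        assert np.dot(tor_a, tor_b) == pytest.approx(1.0)

    def test_like_polarity_refused(self):
        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)
        with pytest.raises(IncompatiblePatchError):
            compose_bound_configuration(a, (0, "donor"), b, (0, "donor"))

    def test_bonded_patch_refused(self, model):
        chain = assemble_ideal_chain(2)
        other = assemble_ideal_chain(1)
        with pytest.raises(IncompatiblePatchError):
            compose_bound_configuration(chain, (0, "donor"), other, (0, "acceptor"))


class TestIdealRing:
    def test_ring_topology(self, ring):
        assert ring.n_members == 9
        assert ring.bonds.number_of_edges() == 9
        assert all(d == 2 for _, d in ring.bonds.degree)
        assert ring.is_ring

    def test_ring_planarity(self, ring):
        pts = ring.world_n_term_centers()
        assert np.ptp(pts[:, 2]) < 1e-6

    def test_hub_diameter_near_23_nm(self, ring):
        assert hub_diameter(ring) == pytest.approx(23.0, abs=2.0)

    @pytest.mark.parametrize("n", [8, 10])
    def test_wrong_size_raises_closure_error(self, n):
        with pytest.raises(GeometryClosureError):
            assemble_ideal_ring(n)

    def test_no_self_overlap_in_ring(self, ring, model):
        pts, radii = ring.world_beads()
        nb = len(model.beads)
        for i in range(9):
            for j in range(i + 1, 9):
                d = pts[i * nb : (i + 1) * nb, None, :] - pts[None, j * nb : (j + 1) * nb, :]
                dist = np.sqrt((d**2).sum(axis=2))
                touch = radii[i * nb : (i + 1) * nb, None] + radii[None, j * nb : (j + 1) * nb]
                assert (dist > touch - 1e-9).all()


def brute_force_rings(graph: nx.Graph) -> list[set]:
    """Oracle: a component is a ring iff some simple cycle visits all nodes."""
    out = []
    for comp in nx.connected_components(graph):
        if len(comp) < 3:
            continue
        sub = nx.Graph(graph.subgraph(comp))
        for cycle in nx.simple_cycles(sub):
            if len(cycle) == len(comp):
                out.append(set(comp))
                break
    return out


class TestRingDetection:
    def test_ideal_ring_and_chain(self, ring):
        assert detect_rings(ring.bonds) == [set(range(9))]
        assert detect_rings(assemble_ideal_chain(8).bonds) == []

    def test_two_disjoint_rings(self):
        g = nx.Graph()
        for base in (0, 9):
            for k in range(9):
                g.add_edge(base + k, base + (k + 1) % 9, donor=base + k)
        rings = detect_rings(g)
        assert sorted(map(sorted, rings)) == [list(range(9)), list(range(9, 18))]

    def test_matches_brute_force_on_random_valence2_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            # random edges respecting the two-patch (degree <= 2) rule
            for _ in range(int(rng.integers(0, 2 * n))):
                u, v = rng.integers(0, n, size=2)
                if u != v and g.degree(u) < 2 and g.degree(v) < 2 and not g.has_edge(u, v):
                    g.add_edge(int(u), int(v))
            got = sorted(map(sorted, detect_rings(g)))
            want = sorted(map(sorted, brute_force_rings(g)))
            assert got == want


class TestOverlap:
    def test_far_apart_no_overlap(self, model):
        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)
        b.pose = RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
        assert check_overlap(a, b) == []

    def test_identical_poses_full_overlap(self, model):
        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)
        report = check_overlap(a, b)
        diag = [(i, j, d) for i, j, d in report if i == j]
        assert len(diag) == 5
        for i, _, depth in diag:
            assert depth == pytest.approx(2 * model.beads[i].radius)

    def test_symmetry(self, model):
        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)
        b.pose = RigidTransform(np.eye(3), np.array([2.5, 0.5, 0.0]))
        ab = {(i, j) for i, j, _ in check_overlap(a, b)}
        ba = {(j, i) for i, j, _ in check_overlap(b, a)}
        assert ab == ba

    def test_bound_pair_from_compose_is_overlap_free(self, model):
        a = assemble_ideal_chain(1)
        g = compose_bound_configuration(a, (0, "donor"), assemble_ideal_chain(1), (0, "acceptor"))
        b = Cluster(model, [g])
        assert check_overlap(a, b, tol=1e-9) == []


class TestRigidity:
    def test_merge_preserves_internal_coordinates(self, model):
        a = assemble_ideal_chain(3)
        b = assemble_ideal_chain(2)
        pts_a0, _ = a.world_beads()
        merged = merge_clusters(a, (2, "donor"), b, (0, "acceptor"))
        pts_m, _ = merged.world_beads()
        # a's beads are unchanged; the merged cluster matches the ideal chain
        assert np.allclose(pts_m[: len(pts_a0)], pts_a0, atol=1e-12)
        ideal = assemble_ideal_chain(5)
        pts_i, _ = ideal.world_beads()
        d_m = np.linalg.norm(pts_m[:, None] - pts_m[None, :], axis=2)
        d_i = np.linalg.norm(pts_i[:, None] - pts_i[None, :], axis=2)
        assert np.allclose(d_m, d_i, atol=1e-9)
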