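"""Brownian-dynamics engine: diffusion statistics, reversibility, rigidity."""

import numpy as np
import pytest
from scipy import stats

from cartwheel.reactions import ReactionParameters, calibrate_rates
from cartwheel.scaffolds import Scaffold
from cartwheel.simulate import RelaxationFailure, Simulation, resolve_overlaps


def _free_sim(box=(200.0, 200.0, 200.0), seed=1, dt=1.0, species=0, capacity=4):
    rp = ReactionParameters(k_a=0.0, k_d=0.0, delta_t=dt)
    sim = Simulation(rp, box, reactions_on=False, capacity=capacity, seed=seed)
    sim.add_cluster(species, np.asarray(box) / 2)
    return sim


class TestFreeDiffusion:
    def test_msd_matches_tensor_prediction(self, species_tables):
        # E|Δx|² = 2 tr(D) t for a rigid anisotropic body, at all lag times
        sim = _free_sim(seed=2)
        steps, reps = 100, 1500
        disp = np.empty((reps, 3))
        box = sim.box
        for k in range(reps):
            p0 = sim.pos[0].copy()
            sim.run(steps, record_every=steps)
            d = sim.pos[0] - p0
            disp[k] = d - box * np.round(d / box)
        msd = (disp**2).sum(axis=1)
        expected = 6.0 * species_tables[0].diffusion.d_trans_mean * steps
        se = msd.std() / np.sqrt(reps)
        assert abs(msd.mean() - expected) < 3 * se
        assert abs(disp.mean(axis=0)).max() < 3 * np.sqrt(msd.mean() / 3 / reps)

    def test_ring_diffuses_more_slowly_than_monomer(self, species_tables):
        msds = []
        for sp in (0, 9):
            sim = _free_sim(seed=3, species=sp)
            disp = []
            for _ in range(400):
                p0 = sim.pos[0].copy()
                sim.run(200, record_every=200)
                d = sim.pos[0] - p0
                disp.append(d - sim.box * np.round(d / sim.box))
            msds.append((np.array(disp) ** 2).sum(axis=1).mean())
        assert msds[1] < 0.6 * msds[0]

    def test_orientation_stays_normalized(self):
        sim = _free_sim(seed=4)
        sim.run(200_000, record_every=200_000)
        assert abs(np.linalg.norm(sim.quat[0]) - 1.0) < 1e-9

    def test_uniform_spatial_distribution(self):
        # pure dynamics in a periodic box: Kolmogorov–Smirnov on positions
        sim = _free_sim(box=(60.0, 60.0, 60.0), seed=5)
        xs = []
        sim.run(50_000, record_every=50_000)
        for _ in range(8000):
            sim.run(250, record_every=250)
            xs.append(sim.pos[0].copy())
        xs = np.asarray(xs)
        # thin to roughly independent samples (crossing time ~ box²/6D)
        thin = xs[::12]
        for ax in range(3):
            p = stats.kstest(thin[:, ax] / 60.0, "uniform").pvalue
            assert p > 0.01


class TestReversibleKinetics:
    def test_two_state_detailed_balance(self):
        # a weakly bound pair: stationary bound probability equals the
        # two-state prediction from the calibrated probabilities and the
        # encounter-window volume
        rp = calibrate_rates(6000.0, k_a=1.0, delta_t=1.0)
        v = 30.0**3
        vb = rp.window.volume()
        odds = 2 * (rp.p_assoc / rp.p_dissoc) * vb / v
        pred = odds / (1 + odds)
        means = []
        for seed in (30, 31):
            sim = Simulation(rp, (30.0, 30.0, 30.0), seed=seed, capacity=4)
            sim.place_random_homodimers(2)
            sim.run(20_000, record_every=20_000)
            sim.records.clear()
            sim.run(1_500_000, record_every=25)
            _, counts, _ = sim.record_arrays()
            means.append((counts[:, 1] > 0).mean())
        measured = np.mean(means)
        # the two binding channels overlap slightly at wide windows, so the
        # additive prediction is a few percent high; 12% covers 3σ + bias
        assert measured == pytest.approx(pred, rel=0.12)

    def test_time_step_convergence(self):
        fractions = []
        for dt in (1.0, 0.5):
            rp = calibrate_rates(6000.0, k_a=1.0, delta_t=dt)
            sim = Simulation(rp, (30.0, 30.0, 30.0), seed=77, capacity=4)
            sim.place_random_homodimers(2)
            sim.run(int(20_000 / dt), record_every=int(20_000 / dt))
            sim.records.clear()
            sim.run(int(1_200_000 / dt), record_every=25)
            _, counts, _ = sim.record_arrays()
            fractions.append((counts[:, 1] > 0).mean())
        assert fractions[0] == pytest.approx(fractions[1], rel=0.15)

    def test_ring_opening_yields_connected_nine_chain(self):
        # k_a = 0: an opened ring cannot re-close; a single connected
        # 9-chain remains until a second bond opens
        rp = ReactionParameters(k_a=0.0, k_d=1e-4, delta_t=1.0)
        sim = Simulation(rp, (100.0, 100.0, 100.0), seed=6, capacity=16)
        sim.add_cluster(9, [50.0, 50.0, 50.0])
        seen_nine_chain = False
        for _ in range(200):
            sim.run(500, record_every=500)
            counts = sim.species_counts()
            if counts[8] == 1 and sim.n_active() == 1:
                seen_nine_chain = True
                break
        assert seen_nine_chain

    def test_zero_dissociation_conserves_bonds(self):
        rp = ReactionParameters(k_a=0.0, k_d=0.0, delta_t=1.0)
        sim = Simulation(rp, (80.0, 80.0, 80.0), seed=8, capacity=8)
        sim.add_cluster(9, [40.0, 40.0, 40.0])
        sim.add_cluster(4, [20.0, 20.0, 20.0])
        sim.run(100_000, record_every=1000)
        _, counts, _ = sim.record_arrays()
        assert (counts[:, 9] == 1).all()
        assert (counts[:, 4] == 1).all()


class TestDeterminism:
    def test_same_seed_same_trajectory(self):
        runs = []
        for _ in range(2):
            rp = calibrate_rates(k_a=1.0, delta_t=1.0)
            sim = Simulation(rp, (60.0, 60.0, 60.0), seed=99, capacity=16)
            sim.place_random_homodimers(10)
            sim.run(30_000, record_every=500)
            _, counts, _ = sim.record_arrays()
            runs.append((counts.copy(), sim.pos.copy(), sim.species.copy()))
        assert (runs[0][0] == runs[1][0]).all()
        assert (runs[0][2] == runs[1][2]).all()
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_zero_ring_energy_equals_equal_rates(self):
        # E = 0 means k_ring = k_a exactly; the same seed gives the
        # bit-identical trajectory
        base = calibrate_rates(k_a=1.0, delta_t=1.0, ring_energy=0.0)
        assert base.k_ring == base.k_a
        runs = []
        for _ in range(2):
            sim = Simulation(base, (50.0, 50.0, 50.0), seed=13, capacity=16)
            sim.place_random_homodimers(9)
            sim.run(20_000, record_every=500)
            runs.append(sim.record_arrays()[1])
        assert (runs[0] == runs[1]).all()


class TestRigidity:
    def test_intra_cluster_geometry_preserved_under_forces(self, species_tables):
        sc = Scaffold("cylinder", strength=4.0, center=np.array([40.0, 40.0, 0.0]))
        rp = ReactionParameters(k_a=0.0, k_d=0.0, delta_t=1.0)
        sim = Simulation(rp, (80.0, 80.0, 40.0), scaffold=sc, reactions_on=False, capacity=4, seed=10)
        sim.add_cluster(9, [52.0, 40.0, 20.0])
        sim.run(100_000, record_every=100_000)
        (cluster,) = sim.clusters()
        pts, _ = cluster.world_beads()
        ref = species_tables[9].beads
        d_now = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
        assert np.allclose(d_now, d_ref, atol=1e-9)


class TestOverlapResolution:
    def test_interpenetrating_pair_separated(self):
        from cartwheel.geometry import RigidTransform, assemble_ideal_chain, check_overlap

        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)
        b.pose = RigidTransform(np.eye(3), np.array([1.0, 0.3, 0.2]))
        assert check_overlap(a, b)
        resolved = resolve_overlaps([a, b], flagged=[1], max_iter=400)
        assert check_overlap(resolved[0], resolved[1]) == []
        # only the flagged cluster moved
        assert np.allclose(resolved[0].pose.translation, 0.0)
        assert not np.allclose(resolved[1].pose.translation, b.pose.translation if False else [1.0, 0.3, 0.2])

    def test_wall_penetration_pushed_inside(self):
        from cartwheel.geometry import assemble_ideal_chain, RigidTransform

        c = assemble_ideal_chain(1)
        c.pose = RigidTransform(np.eye(3), np.array([10.0, 10.0, -1.0]))
        (resolved,) = resolve_overlaps(
            [c], flagged=[0], box=np.array([40.0, 40.0, 40.0]), wall_z=True, max_iter=500
        )
        pts, radii = resolved.world_beads()
        assert (pts[:, 2] >= radii - 1e-6).all()

    def test_unresolvable_overlap_raises(self):
        from cartwheel.geometry import assemble_ideal_chain

        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)  # exactly coincident: zero net force
        with pytest.raises(RelaxationFailure):
            resolve_overlaps([a, b], flagged=[1], max_iter=5)


class TestReferencePropagate:
    def test_cluster_route_matches_species_tables(self, species_tables):
        from cartwheel.geometry import assemble_ideal_chain
        from cartwheel.hydrodynamics import cluster_diffusion_properties

        dp = cluster_diffusion_properties(assemble_ideal_chain(3))
        ref = species_tables[2].diffusion
        assert np.allclose(np.sort(np.linalg.eigvalsh(dp.translational)),
                           np.sort(np.linalg.eigvalsh(ref.translational)), rtol=1e-9)

    def test_drift_obeys_einstein_relation(self):
        # constant force: mean displacement per step = mobility · F · Δt
        from cartwheel.geometry import assemble_ideal_chain
        from cartwheel.hydrodynamics import cluster_diffusion_properties
        from cartwheel.simulate import propagate

        c = assemble_ideal_chain(1)
        dp = cluster_diffusion_properties(c)
        rng = np.random.default_rng(3)
        f = np.array([0.8, 0.0, 0.0])
        xs = np.array([
            propagate(c, dp, 1.0, rng, force=f).pose.translation[0] for _ in range(4000)
        ])
        expect = (dp.mobility[:3, :3] @ f)[0]
        se = xs.std() / np.sqrt(len(xs))
        assert abs(xs.mean() - expect) < 3 * se

    def test_nonfinite_force_rejected(self):
        from cartwheel.geometry import assemble_ideal_chain
        from cartwheel.hydrodynamics import cluster_diffusion_properties
        from cartwheel.simulate import propagate

        c = assemble_ideal_chain(1)
        dp = cluster_diffusion_properties(c)
        with pytest.raises(ValueError, match="finite"):
            propagate(c, dp, 1.0, np.random.default_rng(0), force=[np.inf, 0, 0])
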