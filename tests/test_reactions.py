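"""Encounter window, rate calibration, association/dissociation rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cartwheel.geometry import Cluster, RigidTransform, assemble_ideal_chain
from cartwheel.reactions import (
    AffinityCalibration,
    CalibrationError,
    EncounterWindow,
    ReactionParameters,
    attempt_association,
    attempt_dissociation,
    calibrate_rates,
    find_encounters,
    parameter_set,
    sample_window_placement,
)
from cartwheel.units import PER_NM3_PER_UM


class TestWindow:
    def test_volume_factorizes(self):
        w = EncounterWindow(2.0, 180.0, 180.0)
        # fully open angular window: v_b is the bare tolerance ball
        assert w.volume() == pytest.approx(4.0 / 3.0 * math.pi * 8.0, rel=1e-6)

    def test_rotation_fraction_monotone_in_tolerances(self):
        fracs = [EncounterWindow(1.0, a, a).rotation_fraction(50_000) for a in (20, 45, 75, 120)]
        assert all(f1 < f2 for f1, f2 in zip(fracs, fracs[1:]))

    def test_effective_molarity_default_window(self):
        # ring-closure effective molarity of the default window is ~0.1 M
        assert EncounterWindow().effective_molarity() * 1e-6 == pytest.approx(0.10, abs=0.03)

    def test_invalid_tolerances(self):
        with pytest.raises(CalibrationError):
            EncounterWindow(max_anchor_dist=0.0)


class TestCalibration:
    def test_doubling_ka_doubles_kd(self):
        w = EncounterWindow()
        p1 = calibrate_rates(AffinityCalibration(), w, k_a=0.01, delta_t=0.01)
        p2 = calibrate_rates(AffinityCalibration(), w, k_a=0.02, delta_t=0.01)
        # small-Δt regime: the probability-form calibration reduces to the
        # rate form, so the equilibrium ratio is preserved
        assert p2.k_d / p1.k_d == pytest.approx(2.0, rel=1e-3)
        assert p2.k_a / p2.k_d == pytest.approx(p1.k_a / p1.k_d, rel=1e-3)

    def test_probability_form_equilibrium_exact(self):
        w = EncounterWindow()
        p = calibrate_rates(AffinityCalibration(kd_nn=60.0), w, k_a=1.0, delta_t=1.0)
        ratio = p.p_assoc / p.p_dissoc
        assert ratio == pytest.approx(1.0 / (60.0 * PER_NM3_PER_UM * w.volume()), rel=1e-9)

    def test_ring_rate_from_energy(self):
        p = parameter_set("set1", ring_energy=-9.2)
        assert p.k_ring / p.k_a == pytest.approx(math.exp(9.2), rel=1e-12)
        assert p.ring_energy == -9.2

    def test_zero_window_volume_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_rates(window_volume=0.0)

    def test_positive_ring_energy_rejected(self):
        with pytest.raises(CalibrationError):
            ReactionParameters(k_a=1.0, k_d=0.1, ring_energy=0.5)


class TestEncounters:
    def _params(self, **kw):
        return calibrate_rates(k_a=kw.pop("k_a", 1.0), delta_t=1.0, **kw)

    def test_distant_pair_no_encounter(self):
        a = assemble_ideal_chain(1)
        b = assemble_ideal_chain(1)
        b.pose = RigidTransform(np.eye(3), np.array([50.0, 0.0, 0.0]))
        assert find_encounters([a, b], self._params()) == []

    def test_bound_configuration_is_inside_window(self, model):
        a = assemble_ideal_chain(1)
        from cartwheel.geometry import compose_bound_configuration

        g = compose_bound_configuration(a, (0, "donor"), assemble_ideal_chain(1), (0, "acceptor"))
        b = Cluster(model, [RigidTransform.identity()], pose=g)
        enc = find_encounters([a, b], self._params())
        assert len(enc) >= 1
        assert not enc[0].is_ring_closing

    def test_open_nine_chain_flags_ring_closure(self):
        chain9 = assemble_ideal_chain(9)
        enc = find_encounters([chain9], self._params())
        assert len(enc) == 1
        assert enc[0].is_ring_closing
        # shorter chains cannot reach around
        assert find_encounters([assemble_ideal_chain(8)], self._params()) == []

    def test_association_probability_bernoulli(self, rng):
        # k_a Δt = 0.1 -> acceptance 1 - e^{-0.1} over repeated trials
        chain9 = assemble_ideal_chain(9)
        params = ReactionParameters(k_a=0.1, k_d=0.0, delta_t=1.0)
        enc = find_encounters([chain9], params)[0]
        n = 30_000
        hits = sum(
            attempt_association(enc, params, rng) is not None for _ in range(n)
        )
        p = 1.0 - math.exp(-0.1)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_zero_rate_never_binds(self, rng):
        chain9 = assemble_ideal_chain(9)
        params = ReactionParameters(k_a=0.0, k_d=0.0, delta_t=1.0)
        enc = find_encounters([chain9], ReactionParameters(k_a=1.0, k_d=0.0))[0]
        assert all(attempt_association(enc, params, rng) is None for _ in range(200))

    def test_ring_closure_produces_ring(self, rng):
        chain9 = assemble_ideal_chain(9)
        params = ReactionParameters(k_a=50.0, k_d=0.0, delta_t=1.0)
        enc = find_encounters([chain9], params)[0]
        closed = attempt_association(enc, params, rng)
        assert closed is not None and closed.is_ring


class TestDissociation:
    def test_middle_bond_split_sizes(self, rng):
        chain = assemble_ideal_chain(3)
        params = ReactionParameters(k_a=1.0, k_d=50.0, delta_t=1.0)
        frags = attempt_dissociation(chain, (1, 2), params, rng)
        assert frags is not None
        assert sorted(f.n_members for f in frags) == [1, 2]

    def test_replacement_lands_inside_window(self, rng):
        params = ReactionParameters(k_a=1.0, k_d=50.0, delta_t=1.0)
        for _ in range(50):
            frags = attempt_dissociation(assemble_ideal_chain(2), (0, 1), params, rng)
            enc = find_encounters(frags, params)
            assert len(enc) >= 1  # still within the encounter window

    def test_ring_opening_keeps_single_fragment(self, ring, rng):
        params = ReactionParameters(k_a=1.0, k_d=50.0, delta_t=1.0)
        frags = attempt_dissociation(ring, (0, 1), params, rng)
        assert frags is not None and len(frags) == 1
        opened = frags[0]
        assert opened.n_members == 9
        assert not opened.is_ring
        # geometry untouched: two simultaneous openings are needed to break up
        assert np.allclose(opened.world_beads()[0], ring.world_beads()[0])

    def test_zero_kd_never_fires(self, ring, rng):
        params = ReactionParameters(k_a=1.0, k_d=0.0, delta_t=1.0)
        assert all(
            attempt_dissociation(ring, (0, 1), params, rng) is None for _ in range(200)
        )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_window_sampling_respects_bounds(seed):
    w = EncounterWindow(2.5, 40.0, 55.0)
    rng = np.random.default_rng(seed)
    t = sample_window_placement(w, rng)
    assert np.linalg.norm(t.translation) <= w.max_anchor_dist
    # rotation angle constraints in the canonical axes
    ex = t.rotation @ np.array([1.0, 0, 0])
    ez = t.rotation @ np.array([0.0, 0, 1.0])
    assert math.degrees(math.acos(np.clip(ex[0], -1, 1))) <= w.max_align_deg + 1e-9
    assert math.degrees(math.acos(np.clip(ez[2], -1, 1))) <= w.max_torsion_deg + 1e-9
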