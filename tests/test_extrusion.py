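"""Loop-extrusion mechanics: sliding, blocking, anchors, turnover."""

import numpy as np
import pytest

from chrom4d.extrusion import (
    BIDIRECTIONAL,
    FORWARD,
    REVERSE,
    AnchorSet,
    ExtruderSystem,
    ExtrusionParams,
    anchors_from_signal,
    seed_extruders,
)


def make_system(n_beads, n_extruders=None, separation_kb=None, k_off=0.0,
                anchors=None, g_bp=5000.0, seed=0):
    params = ExtrusionParams(n_extruders=n_extruders, separation_kb=separation_kb,
                             k_off=k_off)
    return ExtruderSystem(params, n_beads, anchors, g_bp, np.random.default_rng(seed))


class TestSeeding:
    def test_separation_arithmetic(self):
        # N * g / separation: 1200 beads at 5 kb with 600 kb separation -> 10
        params = ExtrusionParams(separation_kb=600.0)
        assert params.resolve_n(1200, 5000.0) == 10

    def test_exact_count_and_adjacent_disjoint_legs(self):
        rng = np.random.default_rng(1)
        ext = seed_extruders(20, 100, rng)
        assert len(ext) == 20
        occupied = []
        for e in ext:
            assert e.j == e.i + 1
            occupied += [e.i, e.j]
        assert len(set(occupied)) == 40

    def test_zero_extruders_is_valid(self):
        sys = make_system(50, n_extruders=0)
        i, j = sys.spring_arrays()
        assert i.size == 0 and j.size == 0

    def test_overfull_polymer_rejected(self):
        with pytest.raises(ValueError):
            seed_extruders(51, 100, np.random.default_rng(0))


class TestSliding:
    def test_free_extruder_moves_both_legs_outward(self):
        sys = make_system(100, n_extruders=1)
        e = sys.extruders[0]
        e.i, e.j = 10, 20
        sys.extrusion_step()
        assert (e.i, e.j) == (9, 21)

    def test_polymer_end_halts_leg(self):
        sys = make_system(30, n_extruders=1)
        e = sys.extruders[0]
        e.i, e.j = 0, 28
        sys.extrusion_step()
        assert e.halted_left and e.i == 0
        sys.extrusion_step()
        assert e.halted_right and e.j == 29

    def test_no_pass_through_exhaustive_small_case(self):
        """Two extruders converging on one contested bead: exactly one ends
        up occupying it, legs never cross, for every update order (checked
        over many rng streams)."""
        for seed in range(40):
            sys = make_system(40, n_extruders=2, seed=seed)
            a, b = sys.extruders
            a.i, a.j = 5, 10
            b.i, b.j = 12, 20
            for _ in range(30):
                sys.extrusion_step()
                i1, j1 = sys.extruders[0].i, sys.extruders[0].j
                i2, j2 = sys.extruders[1].i, sys.extruders[1].j
                assert len({i1, j1, i2, j2}) == 4  # no shared bead
                assert not (i1 < i2 < j1 < j2) and not (i2 < i1 < j2 < j1)
            # the contested bead 11 belongs to exactly one extruder
            assert (sys.extruders[0].j == 11) != (sys.extruders[1].i == 11)

    def test_crossing_never_occurs_with_many_extruders(self):
        rng_seeds = range(5)
        for seed in rng_seeds:
            sys = make_system(200, n_extruders=20, k_off=0.05, seed=seed)
            for _ in range(100):
                sys.update()
                legs = sorted((e.i, e.j) for e in sys.extruders)
                flat = [b for pair in legs for b in pair]
                assert len(set(flat)) == 40
                for (i1, j1), (i2, j2) in zip(legs, legs[1:]):
                    assert not (i1 < i2 < j1 < j2)
                assert len(sys.extruders) == 20  # count invariant


class TestAnchors:
    def test_engaged_anchor_halts_leg_permanently(self):
        anchors = AnchorSet(np.array([0]), np.array([BIDIRECTIONAL]), np.array([1.0]))
        sys = make_system(50, n_extruders=1, anchors=anchors)
        e = sys.extruders[0]
        e.i, e.j = 3, 45
        for _ in range(10):
            sys.extrusion_step()
        assert e.halted_left and e.i == 0

    def test_transparent_anchor_at_p_zero(self):
        anchors = AnchorSet(np.array([10]), np.array([BIDIRECTIONAL]), np.array([0.0]))
        sys = make_system(50, n_extruders=1, anchors=anchors)
        e = sys.extruders[0]
        e.i, e.j = 12, 20
        for _ in range(5):
            sys.extrusion_step()
        assert e.i == 7 and not e.halted_left

    def test_orientation_convention_convergent_pair_encloses(self):
        """A forward anchor blocks leftward travel, a reverse anchor blocks
        rightward travel; a convergent (+ ... -) pair pins both legs."""
        anchors = AnchorSet(np.array([10, 30]), np.array([FORWARD, REVERSE]),
                            np.array([1.0, 1.0]))
        sys = make_system(60, n_extruders=1, anchors=anchors)
        e = sys.extruders[0]
        e.i, e.j = 19, 21
        for _ in range(30):
            sys.extrusion_step()
        assert (e.i, e.j) == (10, 30)
        assert e.halted_left and e.halted_right

    def test_anchor_opposing_direction_only(self):
        # a forward anchor does not block a rightward-travelling leg
        anchors = AnchorSet(np.array([30]), np.array([FORWARD]), np.array([1.0]))
        sys = make_system(60, n_extruders=1, anchors=anchors)
        e = sys.extruders[0]
        e.i, e.j = 25, 28
        for _ in range(5):
            sys.extrusion_step()
        assert e.j == 33 and not e.halted_right


class TestTurnover:
    def test_no_detachment_at_zero_rate(self):
        sys = make_system(100, n_extruders=5, k_off=0.0)
        before = [(e.i, e.j) for e in sys.extruders]
        assert sys.detach_rebind() == []
        assert [(e.i, e.j) for e in sys.extruders] == before

    def test_count_conserved_under_turnover(self):
        sys = make_system(100, n_extruders=10, k_off=0.5, seed=3)
        for _ in range(50):
            sys.update()
            assert len(sys.extruders) == 10

    def test_mean_loop_length_matches_processivity(self):
        """Monte-Carlo oracle: for one unobstructed extruder the mean loop
        length at detachment is 1 + 2/p beads (geometric lifetime times the
        two-leg extrusion speed), i.e. ~ proc = 2g/k_off.  Checked within
        10% over >= 500 detachment events."""
        k_off = 0.05
        sys = make_system(5000, n_extruders=1, k_off=k_off, seed=7)
        loops = []
        while len(loops) < 500:
            sys.extrusion_step()
            loops.extend(sys.detach_rebind())
        p = 1.0 - np.exp(-k_off)
        expected_beads = 1.0 + 2.0 / p
        proc_beads = 2.0 / k_off
        got = np.mean(loops)
        assert got == pytest.approx(expected_beads, rel=0.10)
        assert got == pytest.approx(proc_beads, rel=0.12)

    def test_halted_flags_reset_on_rebirth(self):
        anchors = AnchorSet(np.array([0]), np.array([BIDIRECTIONAL]), np.array([1.0]))
        sys = make_system(50, n_extruders=1, k_off=2.0, anchors=anchors, seed=5)
        e = sys.extruders[0]
        e.i, e.j = 1, 40
        sys.extrusion_step()
        assert sys.extruders[0].halted_left
        for _ in range(20):
            sys.detach_rebind()
            if not sys.extruders[0].halted_left:
                break
        assert not sys.extruders[0].halted_left


class TestAnchorsFromSignal:
    def test_zero_signal_empty_with_warning(self):
        with pytest.warns(UserWarning):
            a = anchors_from_signal(np.zeros(10))
        assert len(a) == 0

    def test_max_normalisation(self):
        a = anchors_from_signal(np.array([0.0, 2.0, 4.0]))
        np.testing.assert_array_equal(a.beads, [1, 2])
        np.testing.assert_allclose(a.probabilities, [0.5, 1.0])

    def test_orientation_passthrough(self):
        a = anchors_from_signal(np.array([0.0, 3.0, 1.0]),
                                orientations=[".", "+", "-"])
        assert a.orientations[0] == FORWARD
        assert a.orientations[1] == REVERSE

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            AnchorSet(np.array([1]), np.array([0]), np.array([1.5]))
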