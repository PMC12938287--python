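"""Agent rules: activation gates, synthesis gates, movement, epithelium."""

import numpy as np
import pytest

from inflamnet.agents import (
    FIBROBLAST,
    MACROPHAGE,
    EpithelialLattice,
    MotileCell,
    Slot,
    chemotaxis_move,
    lifecycle_and_repopulate,
    synthesise_tgf,
    synthesise_tnf,
    try_activate_fibroblast,
    try_activate_macrophage,
    update_epithelium,
)
from inflamnet.params import aging_preset


def mk_cell(kind=MACROPHAGE, row=5, col=5, lifespan=20):
    return MotileCell(kind=kind, slot_id=0, row=row, col=col, lifespan=lifespan)


class TestActivation:
    def test_zero_stimulus_zero_tnf_never_activates(self, rng):
        for _ in range(1000):
            cell = mk_cell()
            try_activate_macrophage(cell, 0.0, 0.0, rng, iteration=0)
            assert not cell.activated
            try_activate_macrophage(cell, 0.0, 0.0, rng, iteration=7)
            assert not cell.activated

    def test_full_stimulus_activates_with_certainty(self, rng):
        for _ in range(100):
            cell = mk_cell()
            try_activate_macrophage(cell, 1.0, 0.0, rng, iteration=0)
            assert cell.activated and cell.mobile

    def test_initial_activation_rate_matches_stimulus(self, rng):
        n, s = 10_000, 0.4
        hits = 0
        for _ in range(n):
            cell = mk_cell()
            try_activate_macrophage(cell, s, 0.0, rng, iteration=0)
            hits += cell.activated
        se = np.sqrt(s * (1 - s) / n)
        assert abs(hits / n - s) < 3 * se

    def test_fibroblast_activation_immobilises_and_shortens_life(self, rng):
        cell = mk_cell(kind=FIBROBLAST, lifespan=20)
        try_activate_fibroblast(cell, 2.0, rng)  # clamped probability 1
        assert cell.activated and not cell.mobile
        assert cell.lifespan == 5  # remaining 20 -> floor(0.25 * 20)

    def test_fibroblast_without_tnf_never_activates(self, rng):
        for _ in range(1000):
            cell = mk_cell(kind=FIBROBLAST)
            try_activate_fibroblast(cell, 0.0, rng)
            assert not cell.activated


class TestSynthesisGates:
    def test_tnf_gate_limits(self, rng):
        aging = aging_preset("N")
        cell = mk_cell()
        assert all(synthesise_tnf(cell, 0.0, aging, rng) == 1.0 for _ in range(500))
        assert all(synthesise_tnf(cell, 1.0, aging, rng) == 0.0 for _ in range(500))

    def test_tgf_gate_limits(self, rng):
        aging = aging_preset("N")
        cell = mk_cell(kind=FIBROBLAST)
        assert all(synthesise_tgf(cell, 0.0, aging, rng) == 0.0 for _ in range(500))
        assert all(synthesise_tgf(cell, 1.0, aging, rng) == 1.0 for _ in range(500))

    def test_tnf_gate_frequency_matches_beta_survival(self, rng):
        """N preset: P(Beta(1,3) >= 0.5) = (1 - 0.5)^3 = 0.125."""
        aging = aging_preset("N")
        cell = mk_cell()
        n = 10_000
        freq = sum(synthesise_tnf(cell, 0.5, aging, rng) for _ in range(n)) / n
        se = np.sqrt(0.125 * 0.875 / n)
        assert abs(freq - 0.125) < 3 * se

    def test_tgf_gate_frequency_matches_beta_cdf(self, rng):
        """P(Beta(2,1) <= 0.5) = 0.5^2 = 0.25."""
        aging = aging_preset("N")
        cell = mk_cell(kind=FIBROBLAST)
        n = 10_000
        freq = sum(synthesise_tgf(cell, 0.5, aging, rng) for _ in range(n)) / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(freq - 0.25) < 3 * se

    def test_gate_monotonicity_in_local_concentration(self, rng):
        """TNF output non-increasing in TGF; TGF output non-decreasing in TNF."""
        aging = aging_preset("A2")
        n = 20_000
        tnf_freqs = []
        tgf_freqs = []
        for level in (0.2, 0.5, 0.8):
            tnf_freqs.append(sum(synthesise_tnf(mk_cell(), level, aging, rng)
                                 for _ in range(n)) / n)
            tgf_freqs.append(sum(synthesise_tgf(mk_cell(FIBROBLAST), level, aging, rng)
                                 for _ in range(n)) / n)
        assert tnf_freqs[0] > tnf_freqs[1] > tnf_freqs[2]
        assert tgf_freqs[0] < tgf_freqs[1] < tgf_freqs[2]


class TestChemotaxis:
    def test_zero_field_gives_uniform_single_step(self, rng):
        """On a flat field one sub-step is a uniform draw over 9 candidates."""
        field = np.zeros((5, 5))
        counts = {}
        n = 18_000
        for _ in range(n):
            occupied = np.zeros((5, 5), dtype=bool)
            occupied[2, 2] = True
            cell = mk_cell(row=2, col=2)
            chemotaxis_move(cell, field, occupied, velocity=1, rng=rng)
            counts[(cell.row, cell.col)] = counts.get((cell.row, cell.col), 0) + 1
        assert len(counts) == 9
        expected = n / 9
        sd = np.sqrt(n * (1 / 9) * (8 / 9))
        for c in counts.values():
            assert abs(c - expected) < 5 * sd

    def test_strong_gradient_dominates_choice(self, rng):
        field = np.zeros((5, 5))
        field[1, 2] = 10.0
        hits = 0
        n = 2000
        for _ in range(n):
            occupied = np.zeros((5, 5), dtype=bool)
            occupied[2, 2] = True
            cell = mk_cell(row=2, col=2)
            chemotaxis_move(cell, field, occupied, velocity=1, rng=rng)
            hits += (cell.row, cell.col) == (1, 2)
        assert hits / n > 0.9

    def test_fully_enclosed_cell_stays_put(self, rng):
        occupied = np.ones((3, 3), dtype=bool)
        cell = mk_cell(row=1, col=1)
        chemotaxis_move(cell, np.zeros((3, 3)), occupied, velocity=3, rng=rng)
        assert (cell.row, cell.col) == (1, 1)

    def test_never_lands_on_occupied_site(self, rng):
        field = np.zeros((4, 4))
        blocked = {(0, 1), (1, 0), (2, 2)}
        for _ in range(500):
            occupied = np.zeros((4, 4), dtype=bool)
            for r, c in blocked:
                occupied[r, c] = True
            cell = mk_cell(row=1, col=1)
            occupied[1, 1] = True
            chemotaxis_move(cell, field, occupied, velocity=3, rng=rng)
            assert (cell.row, cell.col) not in blocked


class TestEpithelium:
    def test_apoptosis_threshold_is_preset_dependent(self, rng):
        tnf = np.full((8, 8), 0.5)
        tgf = np.zeros((8, 8))
        lat = EpithelialLattice.all_alive((8, 8))
        update_epithelium(lat, tnf, tgf, aging_preset("A2"), rng)  # threshold 0.4
        assert (lat.state == 0).all()
        lat2 = EpithelialLattice.all_alive((8, 8))
        update_epithelium(lat2, tnf, tgf, aging_preset("N"), rng)  # threshold 0.8
        assert (lat2.state == 1).all()

    def test_dead_cell_without_tgf_never_heals(self, rng):
        lat = EpithelialLattice.all_alive((5, 5))
        lat.state[:] = 0
        for _ in range(200):
            update_epithelium(lat, np.zeros((5, 5)), np.zeros((5, 5)),
                              aging_preset("N"), rng)
        assert (lat.state == 0).all()
        assert (lat.healing_clock == 0).all()

    def test_healing_requires_elapsed_clock_and_seeds_fibrosis(self, rng):
        aging = aging_preset("N").model_copy(
            update={"mitosis_prob": 1.0, "healing_time": 3})
        lat = EpithelialLattice.all_alive((5, 5))
        lat.state[2, 2] = 0
        tgf = np.zeros((5, 5))
        tgf[2, 2] = 1.0
        tnf = np.zeros((5, 5))
        for k in range(1, 3):
            update_epithelium(lat, tnf, tgf, aging, rng)
            assert lat.state[2, 2] == 0 and lat.healing_clock[2, 2] == k
        update_epithelium(lat, tnf, tgf, aging, rng)  # clock reaches th -> heals
        assert lat.state[2, 2] == 1
        assert lat.healing_clock[2, 2] == 0
        assert (lat.fibrosis > 0).sum() == 1  # one fibrosis site in the Moore ring

    def test_saturated_fibrosis_block_kills_centre(self, rng):
        lat = EpithelialLattice.all_alive((5, 5))
        lat.fibrosis[1:4, 1:4] = 10  # Nc = 9 for the centre -> death probability 1
        update_epithelium(lat, np.zeros((5, 5)), np.zeros((5, 5)),
                          aging_preset("N"), rng)
        assert lat.state[2, 2] == 0
        assert lat.fibrosis[2, 2] == 9  # counters decrement each iteration

    def test_shape_mismatch_rejected(self, rng):
        lat = EpithelialLattice.all_alive((4, 4))
        with pytest.raises(ValueError):
            update_epithelium(lat, np.zeros((5, 5)), np.zeros((4, 4)),
                              aging_preset("N"), rng)


class TestLifecycle:
    def mk_slots(self, n=4, lifespan=20):
        occupied = np.zeros((10, 10), dtype=bool)
        slots = []
        for i in range(n):
            cell = MotileCell(kind=MACROPHAGE, slot_id=i, row=i, col=i,
                              lifespan=lifespan)
            occupied[i, i] = True
            slots.append(Slot(kind=MACROPHAGE, slot_id=i, cell=cell))
        return slots, occupied

    def test_cell_removed_when_age_reaches_lifespan(self, rng):
        slots, occupied = self.mk_slots(1, lifespan=3)
        for it in (1, 2):
            lifecycle_and_repopulate(slots, 100, it, occupied, rng, 3)
            assert slots[0].cell is not None
        lifecycle_and_repopulate(slots, 100, 3, occupied, rng, 3)
        assert slots[0].cell is None
        assert not occupied.any()

    def test_refill_only_on_interval_multiples(self, rng):
        slots, occupied = self.mk_slots(4, lifespan=5)
        for it in range(1, 8):
            lifecycle_and_repopulate(slots, 5, it, occupied, rng, 5)
            alive = sum(s.cell is not None for s in slots)
            if it < 5:
                assert alive == 4
            elif it in (5, 6):  # removed at 5; iteration 5 is a multiple -> refilled
                assert alive == 4
            elif it == 7:
                assert alive == 4
        # fresh cells start a new lifetime segment
        assert all(s.segment == 1 for s in slots)

    def test_refill_deferred_when_grid_is_full(self, rng):
        slots = [Slot(kind=MACROPHAGE, slot_id=0, cell=None)]
        occupied = np.ones((3, 3), dtype=bool)  # no free site: refill must wait
        lifecycle_and_repopulate(slots, 1, 1, occupied, rng, 5)
        assert slots[0].cell is None
        occupied[:] = False
        lifecycle_and_repopulate(slots, 1, 2, occupied, rng, 5)
        assert slots[0].cell is not None
        assert occupied[slots[0].cell.row, slots[0].cell.col]
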