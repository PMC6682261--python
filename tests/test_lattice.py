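"""Lattice simulation: geometry, local rules, update dynamics, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from somasim.lattice import (
    EMPTY,
    SOMATIC,
    STEM,
    LatticeState,
    SimConfig,
    colony_stats,
    effective_exposure,
    effective_resource,
    grid_from_text,
    grid_to_text,
    high_lethality_occupancy,
    init_grid,
    lethality_field,
    run,
    step,
    sweep_protection,
)


def make_state(occ, uniform_b=None):
    occ = np.asarray(occ, dtype=np.int8)
    leth = (
        np.full(occ.shape[1], uniform_b)
        if uniform_b is not None
        else lethality_field(occ.shape[1])
    )
    return LatticeState(occ, leth)


class TestGeometry:
    def test_lethality_field_endpoints_and_spacing(self):
        b = lethality_field(60)
        assert b[0] == 0.0 and b[-1] == 1.0
        assert len(b) == 60
        np.testing.assert_allclose(np.diff(b), 1 / 59)
        assert b[30] == pytest.approx(30 / 59)
        assert b[30] > 0.5  # first column of the high-lethality half
        np.testing.assert_array_equal(lethality_field(2), [0.0, 1.0])
        with pytest.raises(ValueError):
            lethality_field(1)

    def test_default_grid_size(self):
        state = init_grid(SimConfig(rng_seed=0))
        assert state.occupancy.size == 1800
        assert state.occupancy.shape == (30, 60)

    def test_high_lethality_half_denominator(self):
        occ = np.zeros((30, 60), dtype=np.int8)
        occ[:, 30:] = STEM  # exactly the columns with b > 0.5
        state = make_state(occ)
        assert high_lethality_occupancy(state) == 1.0
        occ2 = np.zeros((30, 60), dtype=np.int8)
        occ2[:, :30] = STEM
        assert high_lethality_occupancy(make_state(occ2)) == 0.0


class TestSeeding:
    def test_extreme_densities(self):
        empty = init_grid(SimConfig(seed_density=0.0, rng_seed=1))
        assert (empty.occupancy == EMPTY).all()
        full = init_grid(SimConfig(seed_density=1.0, rng_seed=1))
        assert (full.occupancy == STEM).all()

    def test_density_within_binomial_interval(self):
        counts = [
            (init_grid(SimConfig(rng_seed=s)).occupancy == STEM).sum()
            for s in range(20)
        ]
        total = sum(counts)
        n = 20 * 1800
        lo, hi = stats.binom.interval(0.99, n, 0.05)
        assert lo <= total <= hi
        assert not any(
            (init_grid(SimConfig(rng_seed=s)).occupancy == SOMATIC).any()
            for s in range(3)
        )


class TestLocalRules:
    def test_exposure_multiplies_per_somatic_neighbor(self):
        cfg = SimConfig(beta_soma=0.5)
        occ = np.zeros((3, 3), dtype=np.int8)
        occ[1, 1] = STEM
        assert effective_exposure(make_state(occ), (1, 1), cfg) == 1.0
        occ[0, 0] = SOMATIC
        assert effective_exposure(make_state(occ), (1, 1), cfg) == 0.5
        occ[0, 1] = SOMATIC
        assert effective_exposure(make_state(occ), (1, 1), cfg) == 0.25
        # One fully protective neighbor suffices.
        cfg0 = SimConfig(beta_soma=0.0)
        assert effective_exposure(make_state(occ), (1, 1), cfg0) == 0.0

    def test_resource_modifiers(self):
        occ = np.zeros((3, 3), dtype=np.int8)
        occ[1, 1] = STEM
        state = make_state(occ)
        assert effective_resource(state, (1, 1), SimConfig(a=1.0)) == 1.0
        occ[1, 0] = STEM
        assert effective_resource(make_state(occ), (1, 1), SimConfig(a=1.0)) == pytest.approx(0.8)
        occ2 = np.zeros((3, 3), dtype=np.int8)
        occ2[1, 1] = STEM
        occ2[1, 2] = SOMATIC
        assert effective_resource(make_state(occ2), (1, 1), SimConfig(a=0.8)) == pytest.approx(0.96)
        # Boost cannot push the division probability above 1.
        occ2[0, 1] = SOMATIC
        occ2[2, 1] = SOMATIC
        assert effective_resource(make_state(occ2), (1, 1), SimConfig(a=1.0)) == 1.0

    def test_additive_dialect(self):
        occ = np.zeros((3, 5), dtype=np.int8)
        occ[1, 2] = STEM
        occ[1, 1] = STEM
        occ[1, 3] = STEM
        cfg = SimConfig(a=1.0, modifier_mode="additive")
        assert effective_resource(make_state(occ), (1, 2), cfg) == pytest.approx(0.6)
        cfg_mult = SimConfig(a=1.0)
        assert effective_resource(make_state(occ), (1, 2), cfg_mult) == pytest.approx(0.64)

    def test_von_neumann_ignores_diagonals(self):
        occ = np.zeros((3, 3), dtype=np.int8)
        occ[1, 1] = STEM
        occ[0, 0] = SOMATIC
        cfg = SimConfig(beta_soma=0.5, neighborhood="von_neumann")
        assert effective_exposure(make_state(occ), (1, 1), cfg) == 1.0


class TestStep:
    def test_empty_grid_is_fixed_point(self):
        cfg = SimConfig(rows=5, cols=6)
        state = make_state(np.zeros((5, 6)))
        out = step(state, cfg, np.random.default_rng(0))
        assert (out.occupancy == EMPTY).all()

    def test_certain_division_in_benign_column(self):
        cfg = SimConfig(rows=5, cols=6, a=1.0, p_somatic=0.0)
        occ = np.zeros((5, 6), dtype=np.int8)
        occ[2, 0] = STEM  # b = 0 column, isolated: divides with certainty
        out = step(make_state(occ), cfg, np.random.default_rng(3))
        assert (out.occupancy == STEM).sum() == 2
        assert out.occupancy[2, 0] == STEM

    def test_certain_death_in_lethal_column(self):
        cfg = SimConfig(rows=5, cols=6)
        occ = np.zeros((5, 6), dtype=np.int8)
        occ[2, 5] = STEM  # b = 1, unprotected
        out = step(make_state(occ), cfg, np.random.default_rng(3))
        assert (out.occupancy == EMPTY).all()

    def test_full_protection_prevents_death(self):
        cfg = SimConfig(rows=3, cols=4, beta_soma=0.0, soma_resistance=1.0)
        occ = np.zeros((3, 4), dtype=np.int8)
        occ[1, 3] = STEM  # b = 1 but shielded by a somatic neighbor
        occ[0, 3] = SOMATIC
        out = step(make_state(occ), cfg, np.random.default_rng(5))
        assert out.occupancy[1, 3] == STEM
        assert out.occupancy[0, 3] == SOMATIC

    def test_no_division_without_open_neighbor(self):
        cfg = SimConfig(rows=3, cols=3, uniform_lethality=0.0, a=1.0)
        occ = np.full((3, 3), STEM, dtype=np.int8)
        out = step(make_state(occ, uniform_b=0.0), cfg, np.random.default_rng(0))
        assert (out.occupancy == STEM).all()  # saturated grid cannot grow

    def test_somatic_cells_never_divide(self):
        cfg = SimConfig(rows=6, cols=6, uniform_lethality=0.0, p_somatic=0.0)
        occ = np.zeros((6, 6), dtype=np.int8)
        occ[0, 0] = SOMATIC
        state = make_state(occ, uniform_b=0.0)
        rng = np.random.default_rng(9)
        for _ in range(10):
            state = step(state, cfg, rng)
        assert (state.occupancy == SOMATIC).sum() == 1
        assert (state.occupancy == STEM).sum() == 0

    def test_no_somatic_daughters_when_disabled(self):
        cfg = SimConfig(p_somatic=0.0, cycles=30, rng_seed=4)
        result = run(cfg)
        assert (result.counts["n_somatic"] == 0).all()


class TestRun:
    def test_zero_cycles_returns_initial_grid(self):
        cfg = SimConfig(cycles=0, rng_seed=2)
        result = run(cfg)
        np.testing.assert_array_equal(
            result.final_state.occupancy, init_grid(cfg).occupancy
        )
        assert list(result.counts["cycle"]) == [0]

    def test_bitwise_determinism(self):
        cfg = SimConfig(p_somatic=0.3, beta_soma=0.2, cycles=25, rng_seed=42)
        r1, r2 = run(cfg), run(cfg)
        np.testing.assert_array_equal(r1.final_state.occupancy, r2.final_state.occupancy)
        assert r1.counts.equals(r2.counts)
        r3 = run(cfg.replace(rng_seed=43))
        assert not np.array_equal(r1.final_state.occupancy, r3.final_state.occupancy)

    def test_occupancy_bounded_by_grid(self):
        cfg = SimConfig(a=1.0, uniform_lethality=0.0, cycles=40, rng_seed=0)
        result = run(cfg)
        totals = result.counts["n_stem"] + result.counts["n_somatic"]
        assert (totals <= 1800).all()
        assert totals.iloc[-1] == 1800  # benign uniform environment saturates


class TestSweep:
    def test_sweep_table_deterministic(self):
        cfg = SimConfig(a=0.8, p_somatic=0.5, cycles=10, rng_seed=7)
        t1 = sweep_protection(cfg, [0.0, 1.0], runs_per_value=2)
        t2 = sweep_protection(cfg, [0.0, 1.0], runs_per_value=2)
        assert t1.equals(t2)
        assert list(t1.columns) == [
            "protection",
            "run",
            "seed",
            "occupancy_high_b",
            "n_stem",
            "n_somatic",
        ]
        assert len(t1) == 4


class TestColonies:
    def test_empty_and_singleton(self):
        assert len(colony_stats(make_state(np.zeros((4, 4))))) == 0
        occ = np.zeros((4, 4), dtype=np.int8)
        occ[1, 1] = STEM
        df = colony_stats(make_state(occ))
        assert len(df) == 1
        assert df.iloc[0].to_dict() == {"size": 1, "n_stem": 1, "n_somatic": 0}

    def test_block_and_diagonal_adjacency(self):
        occ = np.zeros((5, 5), dtype=np.int8)
        occ[1:3, 1:3] = STEM
        occ[3, 3] = SOMATIC  # diagonal touch: same colony under Moore
        df = colony_stats(make_state(occ), "moore")
        assert len(df) == 1
        assert df.iloc[0]["size"] == 5
        assert df.iloc[0]["n_somatic"] == 1
        df_vn = colony_stats(make_state(occ), "von_neumann")
        assert len(df_vn) == 2


class TestSnapshots:
    def test_text_round_trip(self):
        state = init_grid(SimConfig(p_somatic=0.5, rng_seed=5))
        state.occupancy[0, 0] = SOMATIC
        text = grid_to_text(state)
        assert set(text) <= {".", "S", "O", "\n"}
        back = grid_from_text(text)
        np.testing.assert_array_equal(back.occupancy, state.occupancy)
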