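"""Corrosion engine: mass budget, CA/CP, Monte Carlo selection, stepping."""

import logging

import numpy as np
import pytest

import mgpit as m
from mgpit.engine import step_mass_budget
from conftest import A, ME, RHO


class TestConfig:
    def test_defaults_are_the_reference_conditions(self):
        cfg = m.CorrosionConfig()
        assert cfg.ml_rate == pytest.approx(3.0e-5)
        assert cfg.ml_rate_per_mm2 == pytest.approx(3.0e-5)
        assert cfg.dt == 25.0
        assert cfg.n_steps == 20
        assert cfg.total_time == 500.0
        assert cfg.surface_mode == "current"
        assert cfg.removal_mode == "exact_count"

    def test_explicit_cm2_units(self):
        cfg = m.CorrosionConfig(ml_rate=0.003, ml_rate_units="mg_per_cm2_h")
        assert cfg.ml_rate_per_mm2 == pytest.approx(3.0e-5)

    @pytest.mark.parametrize("kwargs", [
        {"ml_rate": -1.0}, {"dt": 0}, {"n_steps": 0},
        {"ml_rate_units": "g_per_m2_h"}, {"surface_mode": "both"},
        {"removal_mode": "quantum"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            m.CorrosionConfig(**kwargs)

    def test_dict_round_trip(self):
        cfg = m.CorrosionConfig(n_steps=7, rng_seed=3,
                                oxide=m.OxideConfig(n_seeds=4))
        assert m.config_from_dict(m.config_to_dict(cfg)) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            m.config_from_dict({"ml_rte": 1.0})


class TestMassBudget:
    def test_reference_first_step(self):
        cfg = m.CorrosionConfig()
        ml, n, carry = step_mass_budget(cfg, 570.0, 0.0, ME)
        assert ml == pytest.approx(0.4275)
        assert n == 128
        assert carry == pytest.approx(0.4275 - 128 * ME)
        assert carry == pytest.approx(2.5e-3)

    def test_zero_surface(self):
        ml, n, carry = step_mass_budget(m.CorrosionConfig(), 0.0, 0.0, ME)
        assert (ml, n, carry) == (0.0, 0, 0.0)

    def test_carry_conserves_budget_over_many_steps(self):
        """Sum of removed masses tracks the exact cumulative budget within Me."""
        cfg = m.CorrosionConfig()
        carry, removed_mass = 0.0, 0.0
        for _ in range(20):
            ml, n, carry = step_mass_budget(cfg, 570.0, carry, ME)
            removed_mass += n * ME
        assert abs(removed_mass - 20 * 0.4275) < ME


class TestAttributesAndProbabilities:
    def test_ca_is_ea_times_oa(self, toy_grid):
        toy_grid.oa[:] = 0.07
        ca = m.corrosion_attributes(toy_grid)
        assert ca[0, 2, 0] == pytest.approx(2 * 0.07)   # edge element
        assert ca[2, 2, 2] == 0.0                        # shielded interior
        toy_grid.oa[2, 2, 4] = 1.0
        assert m.corrosion_attributes(toy_grid)[2, 2, 4] == pytest.approx(1.0)

    def test_ca_zero_for_void(self, toy_grid):
        m.apply_removals(toy_grid, [(2, 2, 4)])
        assert m.corrosion_attributes(toy_grid)[2, 2, 4] == 0.0

    def test_two_element_normalisation(self, two_weight_grid):
        cp = m.corrosion_probabilities(two_weight_grid, 1)
        np.testing.assert_allclose(
            cp.ravel(), [0.07 / 1.07, 1.0 / 1.07], rtol=1e-12)
        assert cp.ravel()[1] == pytest.approx(0.9346, abs=5e-5)

    def test_uniform_ca_gives_symmetric_cp(self, toy_grid):
        toy_grid.oa[:] = 0.1
        ca = m.corrosion_attributes(toy_grid)
        cp = m.corrosion_probabilities(toy_grid, 3)
        surface = ca > 0
        # not literally uniform (edges vs faces), but sums to n_remove
        assert cp[surface].sum() == pytest.approx(3.0)
        g = m.build_specimen(3 * A, 3 * A, A, A, RHO)   # all elements EA>0
        g.oa[:] = 0.5
        cp = m.corrosion_probabilities(g, 2)
        # corners/edges/centre differ in EA; each same-EA class is uniform
        np.testing.assert_allclose(cp[g.ea == 4], cp[0, 0, 0])
        np.testing.assert_allclose(cp[g.ea == 2], cp[1, 1, 0])

    def test_sum_cp_equals_n_remove_pre_clip(self, two_weight_grid):
        ca = m.corrosion_attributes(two_weight_grid)
        for n in (0, 1, 2):
            assert (n * ca / ca.sum()).sum() == pytest.approx(float(n))
        # the public function matches wherever no clipping is needed
        assert m.corrosion_probabilities(two_weight_grid, 1).sum() == \
            pytest.approx(1.0)

    def test_no_corrodible_surface_is_an_error(self):
        g = m.build_specimen(A, A, A, A, RHO)
        m.apply_removals(g, [(0, 0, 0)])
        with pytest.raises(ValueError, match="no corrodible surface"):
            m.corrosion_probabilities(g, 1)

    def test_clipping_logs_warning(self, two_weight_grid, caplog):
        with caplog.at_level(logging.WARNING, logger="mgpit"):
            cp = m.corrosion_probabilities(two_weight_grid, 2)
        assert cp.max() == 1.0
        assert any("clipping" in r.message for r in caplog.records)


class TestSelection:
    def test_zero_removals(self, two_weight_grid):
        out = m.select_elements(two_weight_grid, 0,
                                rng=np.random.default_rng(0))
        assert out.shape == (0, 3)

    def test_exact_count_frequencies_match_multinomial(self, two_weight_grid):
        """10^4 single draws on CA = {0.07, 1.0}: the fast element is picked
        with probability 1/1.07 = 0.9346 (3-sigma binomial band)."""
        rng = np.random.default_rng(1)
        p = 1.0 / 1.07
        hits = sum(
            m.select_elements(two_weight_grid, 1, rng=rng)[0, 0] == 1
            for _ in range(10_000)
        )
        sigma = np.sqrt(10_000 * p * (1 - p))
        assert abs(hits - 10_000 * p) < 3 * sigma

    def test_bernoulli_mean_count(self, default_grid):
        """Bernoulli-mode removal count has mean n_remove (Poisson binomial)."""
        g = default_grid.copy()
        g.oa[:] = 0.07
        rng = np.random.default_rng(2)
        n_remove, reps = 64, 300
        counts = [
            m.select_elements(g, n_remove, mode="bernoulli", rng=rng).shape[0]
            for _ in range(reps)
        ]
        cp = m.corrosion_probabilities(g, n_remove)
        var = (cp * (1 - cp)).sum()
        sigma_mean = np.sqrt(var / reps)
        assert abs(np.mean(counts) - n_remove) < 3 * sigma_mean

    def test_infeasible_count_capped_with_warning(self, two_weight_grid, caplog):
        with caplog.at_level(logging.WARNING, logger="mgpit"):
            out = m.select_elements(two_weight_grid, 5,
                                    rng=np.random.default_rng(0))
        assert out.shape[0] == 2
        assert any("corrodible population" in r.message for r in caplog.records)

    def test_porous_seed_preference(self):
        """A porous spot (OA 0.5) is picked over a control oxide element in the
        exact CA ratio 0.5 : 0.07 (multinomial oracle, 3-sigma)."""
        g = m.build_specimen(6 * A, 6 * A, 2 * A, A, RHO)
        m.assign_oxide_layer(g, m.OxideConfig())
        seed_coord, control = (2, 2, 1), (3, 3, 1)
        g.oa[seed_coord] = 0.5
        ca = m.corrosion_attributes(g)
        total = ca.sum()
        rng = np.random.default_rng(3)
        reps = 10_000
        seed_hits = control_hits = 0
        for _ in range(reps):
            picked = m.select_elements(g, 1, rng=rng, ca=ca)
            if tuple(picked[0]) == seed_coord:
                seed_hits += 1
            elif tuple(picked[0]) == control:
                control_hits += 1
        for hits, coord in ((seed_hits, seed_coord), (control_hits, control)):
            p = ca[coord] / total
            sigma = np.sqrt(reps * p * (1 - p))
            assert abs(hits - reps * p) < 3 * sigma


class TestAdvanceAndRun:
    def test_first_step_of_reference_run(self):
        cfg = m.CorrosionConfig(rng_seed=1)
        _, hist = m.run_simulation(m.CorrosionConfig(rng_seed=1, n_steps=1))
        rec = hist.records[0]
        assert rec.n_remove == rec.removed == 128
        assert rec.mass_remaining == pytest.approx(765.0 - 128 * ME)
        assert rec.surface == pytest.approx(570.0)

    def test_initial_surface_mode_constant_budget(self):
        cfg = m.CorrosionConfig(rng_seed=2, surface_mode="initial")
        _, hist = m.run_simulation(cfg)
        n_removes = {r.n_remove for r in hist.records}
        assert max(n_removes) - min(n_removes) <= 1    # carry rounding only

    def test_zero_rate_changes_nothing(self):
        grid, hist = m.run_simulation(m.CorrosionConfig(ml_rate=0.0, n_steps=3,
                                                        rng_seed=0))
        assert all(r.removed == 0 for r in hist.records)
        assert m.total_mass(grid) == pytest.approx(765.0)

    def test_run_times_and_lengths(self):
        cfg = m.CorrosionConfig(length=1.0, width=1.0, thickness=0.5,
                                oxide=m.OxideConfig(n_seeds=2), rng_seed=0)
        _, hist = m.run_simulation(cfg)
        assert len(hist.records) == 20
        assert hist.records[-1].time == 500.0
        np.testing.assert_allclose(hist.times(), 25.0 * np.arange(1, 21))

    def test_determinism_bit_identical(self):
        cfg = m.CorrosionConfig(length=2.0, width=2.0, thickness=0.5,
                                rng_seed=77, oxide=m.OxideConfig(n_seeds=5))
        g1, h1 = m.run_simulation(cfg)
        g2, h2 = m.run_simulation(cfg)
        assert g1.checksum() == g2.checksum() == h1.grid_checksum
        assert h1.records == h2.records

    def test_mass_ledger_every_step(self):
        cfg = m.CorrosionConfig(length=2.0, width=2.0, thickness=0.5,
                                rng_seed=5, oxide=m.OxideConfig(n_seeds=3))
        _, hist = m.run_simulation(cfg)
        m_o = (16 * 16 * 4) * ME
        removed_cum = 0
        for rec in hist.records:
            removed_cum += rec.removed
            assert m_o - rec.mass_remaining == pytest.approx(removed_cum * ME)
            assert rec.mlpa == pytest.approx((m_o - rec.mass_remaining)
                                             / (2 * 4 + 4 * 2 * 0.5))

    def test_early_termination_when_consumed(self):
        """An absurdly high rate consumes the specimen; the history is
        truncated and flagged rather than erroring."""
        cfg = m.CorrosionConfig(length=0.5, width=0.5, thickness=0.25,
                                ml_rate=10.0, n_steps=50, rng_seed=0,
                                oxide=m.OxideConfig(n_seeds=0))
        grid, hist = m.run_simulation(cfg)
        assert hist.truncated
        assert len(hist.records) < 50
        assert not grid.solid_mask.any()

    def test_explicit_seed_map_is_used(self):
        g_probe = m.build_specimen(2.0, 2.0, 0.5, A, RHO)
        m.assign_oxide_layer(g_probe, m.OxideConfig())
        sm = m.PorousSeedMap([(m.ElementCoord(8, 8, 3), 0.55)])
        cfg = m.CorrosionConfig(length=2.0, width=2.0, thickness=0.5,
                                rng_seed=1, n_steps=1, ml_rate=0.0)
        grid, hist = m.run_simulation(cfg, seed_map=sm)
        assert grid.oa[8, 8, 3] == 0.55
        assert hist.seed_map is sm
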