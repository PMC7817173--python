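"""Lattice clone-growth simulator and synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from clonedyn import fate_stats as fs
from clonedyn import simulator as sim
from clonedyn.errors import InvalidInputError, LatticeBoundaryError

EDGE = sim.DEFAULT_TRIPLETS["edge"]
WT = sim.DEFAULT_TRIPLETS["wt_distant"]


class TestConfigAndParams:
    def test_event_sampling_validity_enforced(self):
        with pytest.raises(InvalidInputError):
            sim.SimConfig(seed=0, division_rate_per_day=3.0, dt_days=0.05)

    def test_triplets_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            sim.FateParams({"edge": (0.5, 0.5, 0.5)})

    def test_default_triplets_reproduce_measured_rates(self):
        fp = sim.FateParams()
        assert fp.renewal_rate("wt_distant") == pytest.approx(0.51)
        assert fp.renewal_rate("wt_adjacent") == pytest.approx(0.41)
        assert fp.renewal_rate("edge") == pytest.approx(0.69)
        assert fp.renewal_rate("inner") < 0.5


class TestFateProbabilities:
    @staticmethod
    def _state_with_neighbors(n_mutant_nbrs: int, wt_fill: bool = False):
        state = sim.SimState()
        center = state.new_cell("HrasG12V", "clone1", "edge")
        state.occupancy[(0, 0)] = center
        for i, d in enumerate(sim.HEX_NEIGHBORS):
            if i < n_mutant_nbrs:
                state.occupancy[d] = state.new_cell("HrasG12V", "clone1", "edge")
            elif wt_fill:
                state.occupancy[d] = state.new_cell("WT", None, "wt_distant")
        return state, center

    def test_fully_surrounded_mutant_is_inner(self):
        cfg = sim.SimConfig(seed=0, homotypic_threshold=0.99)
        state, center = self._state_with_neighbors(6)
        triplet, ctx = sim.fate_probabilities(center, (0, 0), state, cfg)
        assert ctx == "clone_inner"
        assert triplet == sim.DEFAULT_TRIPLETS["inner"]

    def test_isolated_mutant_uses_edge_triplet(self):
        cfg = sim.SimConfig(seed=0)
        state, center = self._state_with_neighbors(0)
        triplet, ctx = sim.fate_probabilities(center, (0, 0), state, cfg)
        assert ctx == "clone_edge" and triplet == EDGE
        assert 0.69 == pytest.approx(triplet[0] + triplet[1] / 2)

    @pytest.mark.parametrize("threshold", [1 / 6, 0.5, 5 / 6, 1.0])
    def test_context_flips_exactly_at_threshold(self, threshold):
        cfg = sim.SimConfig(seed=0, homotypic_threshold=threshold)
        for m in range(7):
            state, center = self._state_with_neighbors(m)
            _, ctx = sim.fate_probabilities(center, (0, 0), state, cfg)
            expected = "clone_inner" if m / 6 >= threshold else "clone_edge"
            assert ctx == expected, f"m={m}"

    def test_wt_adjacent_rule_and_switch(self):
        cfg_on = sim.SimConfig(seed=0, wt_adjacent_rule=True)
        cfg_off = sim.SimConfig(seed=0, wt_adjacent_rule=False)
        state = sim.SimState()
        wt = state.new_cell("WT", None, "wt_distant")
        state.occupancy[(0, 0)] = wt
        state.occupancy[(1, 0)] = state.new_cell("HrasG12V", "clone1", "edge")
        _, ctx_on = sim.fate_probabilities(wt, (0, 0), state, cfg_on)
        _, ctx_off = sim.fate_probabilities(wt, (0, 0), state, cfg_off)
        assert ctx_on == "wt_adjacent" and ctx_off == "wt_distant"

    def test_fixed_mode_uses_static_label(self):
        cfg = sim.SimConfig(seed=0, neighborhood_mode="fixed_probabilities")
        state, center = self._state_with_neighbors(6)
        triplet, _ = sim.fate_probabilities(center, (0, 0), state, cfg)
        assert triplet == EDGE  # static label, not neighbourhood


class TestStep:
    def test_zero_division_rate_only_advances_time(self):
        cfg = sim.SimConfig(seed=0, division_rate_per_day=0.0, init="mutant_rosette")
        rng = np.random.default_rng(0)
        state = sim.initialize_state(cfg, rng)
        before = dict(state.occupancy)
        sim.step(state, cfg, rng)
        assert state.occupancy == before
        assert state.time_days == pytest.approx(cfg.dt_days)

    def test_pure_differentiation_extinguishes_single_cell(self):
        cfg = sim.SimConfig(
            seed=1, duration_days=60.0,
            neighborhood_mode="fixed_probabilities",
            fate_params=sim.FateParams({"edge": (0.0, 0.0, 1.0)}),
        )
        traj, cells, events = sim.run(cfg)
        assert traj["n_basal"].iloc[-1] == 0
        assert len(events) == 1 and events["division_type"].iloc[0] == "SD"

    def test_conservation_of_basal_count_and_delaminations(self):
        cfg = sim.SimConfig(seed=4, duration_days=40.0, init="mutant_rosette")
        traj, cells, events = sim.run(cfg)
        n_sr = (events["division_type"] == "SR").sum()
        n_ad = (events["division_type"] == "AD").sum()
        n_sd = (events["division_type"] == "SD").sum()
        assert traj["n_basal"].iloc[-1] == 7 + n_sr - n_sd
        assert traj["n_delaminations"].iloc[-1] == n_ad + 2 * n_sd
        # the cell table retains delaminated cells as suprabasal K10+
        supra = cells[cells["layer"] == "suprabasal"]
        assert len(supra) == n_ad + 2 * n_sd
        assert (supra["k10"] == 1).all()

    def test_lattice_overflow_raises_boundary_error(self):
        cfg = sim.SimConfig(
            seed=0, duration_days=400.0, grid_radius=3,
            neighborhood_mode="fixed_probabilities",
            fate_params=sim.FateParams({"edge": (1.0, 0.0, 0.0)}),
        )
        with pytest.raises(LatticeBoundaryError):
            sim.run(cfg)


class TestRun:
    def test_seeded_determinism_byte_identical(self):
        cfg = sim.SimConfig(seed=42, duration_days=21.0, init="mutant_rosette")
        out1 = sim.run(cfg)
        out2 = sim.run(cfg)
        for a, b in zip(out1, out2):
            assert a.to_csv() == b.to_csv()

    def test_neutral_martingale(self):
        # r = 0.5 exactly: expected basal count is conserved
        finals = []
        for seed in range(200):
            cfg = sim.SimConfig(
                seed=seed, duration_days=28.0,
                neighborhood_mode="fixed_probabilities",
                fate_params=sim.FateParams({"edge": (0.28, 0.44, 0.28)}),
            )
            traj, _, _ = sim.run(cfg)
            finals.append(traj["n_basal"].iloc[-1])
        finals = np.asarray(finals, dtype=float)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 1.0) < 3 * se

    def test_emitted_tables_feed_downstream_modules(self):
        from clonedyn import io as cio
        from clonedyn import morphometry as mm

        cfg = sim.SimConfig(seed=3, duration_days=30.0, init="mutant_rosette")
        traj, cells, events = sim.run(cfg)
        cells_v = cio.validate_table(cells, "cells")
        events_v = cio.validate_table(events, "events")
        f = fs.estimate_fate_fractions(events_v)
        assert f.n_events == len(events)
        labels = mm.classify_edge_inner(
            cells_v.assign(clone_id=cells_v["clone_id"].replace("", pd.NA)),
            "clone1", mode="alpha_boundary",
        )
        assert len(labels) == traj["n_basal"].iloc[-1]

    def test_realized_renewal_decays_toward_homeostasis(self):
        # whole-clone renewal starts at the single-cell/edge rate and
        # falls toward ~0.5 as an inner compartment forms
        rates = []
        for seed in range(5):
            cfg = sim.SimConfig(
                seed=seed, duration_days=112.0, init="mutant_rosette",
                grid_radius=40,
            )
            traj, _, _ = sim.run(cfg)
            early = traj["renewal_rate"].iloc[14]
            late = traj["renewal_rate"].iloc[-1]
            rates.append((early, late))
        early_med = np.median([e for e, _ in rates])
        late_med = np.median([l for _, l in rates])
        assert early_med > 0.60
        assert 0.5 <= late_med < early_med


class TestExpectedGrowth:
    def test_closed_forms(self):
        assert sim.expected_growth(5, 1.0, 0.5, 100.0) == pytest.approx(5.0)
        assert sim.expected_growth(1, 1.0, 1.0, np.log(2)) == pytest.approx(2.0)
        assert sim.expected_growth(2, 0.0, 0.9, 50.0) == pytest.approx(2.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(InvalidInputError):
            sim.expected_growth(1, 1.0, 1.5, 1.0)

    def test_monte_carlo_agreement_r069(self):
        finals = []
        days = 14.0
        for seed in range(400):
            cfg = sim.SimConfig(
                seed=seed, duration_days=days,
                neighborhood_mode="fixed_probabilities",
                fate_params=sim.FateParams({"edge": EDGE}),
            )
            traj, _, _ = sim.run(cfg)
            finals.append(traj["n_basal"].iloc[-1])
        finals = np.asarray(finals, dtype=float)
        expected = sim.expected_growth(1, 0.2, 0.69, days)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se


class TestCfiSampling:
    def test_pure_renewal_gives_basal_basal_doublets(self):
        ev = sim.sample_cfi_dataset((1.0, 0.0, 0.0), 50, seed=0)
        assert (ev["daughter1_layer"] == "basal").all()
        assert (ev["daughter2_layer"] == "basal").all()

    def test_large_sample_recovers_fractions(self):
        ev = sim.sample_cfi_dataset((0.29, 0.44, 0.27), 10_000, seed=1)
        f = fs.estimate_fate_fractions(ev)
        for got, true_p in zip(f.as_tuple(), (0.29, 0.44, 0.27)):
            se = np.sqrt(true_p * (1 - true_p) / 10_000)
            assert abs(got - true_p) < 3 * se

    def test_round_trip_renewal_recovery(self):
        ev = sim.sample_cfi_dataset(EDGE, 8_000, seed=2)
        est = fs.renewal_rate_from_fractions(fs.estimate_fate_fractions(ev))
        assert est.rate == pytest.approx(0.69, abs=0.02)

    def test_division_and_population_estimators_agree_at_scale(self):
        # the population estimator applied to the daughters converges to
        # f_SR + f_AD/2 (here 0.51) as n grows
        ev, cells = sim.sample_cfi_dataset(
            WT, 10_000, seed=3, return_cells=True
        )
        doublets = cells[(cells["edu"] == 1) & (cells["brdu"] == 0)]
        est = fs.renewal_rate_population(doublets)
        se = np.sqrt(0.51 * 0.49 / (2 * 10_000))
        assert abs(est.rate - 0.51) < 3 * se

    def test_pre_divided_singles_emitted_at_assay_proportion(self):
        ev, cells = sim.sample_cfi_dataset(WT, 2_000, seed=4, return_cells=True)
        singles = cells[(cells["edu"] == 1) & (cells["brdu"] == 1)]
        labelled = len(cells)
        assert len(singles) / labelled == pytest.approx(0.15, abs=0.01)

    def test_animals_split_evenly(self):
        ev = sim.sample_cfi_dataset(WT, 225, n_animals=3, seed=5)
        assert ev["animal_id"].value_counts().tolist() == [75, 75, 75]

    def test_seeded_determinism(self):
        a = sim.sample_cfi_dataset(WT, 100, seed=6)
        b = sim.sample_cfi_dataset(WT, 100, seed=6)
        assert a.equals(b)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(InvalidInputError):
            sim.sample_cfi_dataset((0.5, 0.5, 0.5), 10, seed=0)


class TestScreenSimulation:
    def test_seeded_determinism(self):
        d = sim.ScreenDesign()
        assert sim.simulate_screen_counts(d, seed=7).equals(
            sim.simulate_screen_counts(d, seed=7)
        )

    def test_default_pool_size(self):
        counts = sim.simulate_screen_counts(sim.ScreenDesign(), seed=0)
        assert counts["shrna_id"].nunique() == 135  # 27 genes x 5 hairpins
        assert set(counts["compartment"]) == {"basal", "suprabasal"}

    def test_null_log_ratios_center_on_zero(self):
        d = sim.ScreenDesign(n_replicates=2, dispersion=0.0, library_size=1e7)
        counts = sim.simulate_screen_counts(d, seed=8)
        wide = counts.pivot_table(
            index="shrna_id", columns="compartment", values="count", aggfunc="mean"
        )
        lr = np.log2((wide["basal"] + 0.5) / (wide["suprabasal"] + 0.5))
        assert abs(lr.mean()) < 0.02

    def test_planted_twofold_enrichment_recovered(self):
        d = sim.ScreenDesign(
            effects={"gene01": 1.0}, dispersion=0.01, library_size=1e7,
            n_replicates=8,
        )
        counts = sim.simulate_screen_counts(d, seed=9)
        g = counts[counts["gene"] == "gene01"]
        wide = g.pivot_table(
            index="shrna_id", columns="compartment", values="count", aggfunc="mean"
        )
        lr = np.log2(wide["basal"] / wide["suprabasal"])
        assert lr.mean() == pytest.approx(1.0, abs=0.15)

    def test_unknown_gene_effect_rejected(self):
        with pytest.raises(InvalidInputError):
            sim.simulate_screen_counts(
                sim.ScreenDesign(effects={"nope": 1.0}), seed=0
            )
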