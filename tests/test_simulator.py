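import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from memswitch.kinetics import (
    MEMORY_SWITCH,
    MODEL1,
    InductionProtocol,
    KineticParams,
    PromoterModelSpec,
    mean_production_rate,
    memory_fraction,
)
from memswitch.simulator import (
    PopulationState,
    apply_recovery_shortcut,
    simulate_locus,
    simulate_population,
)


class TestSimulateLocus:
    def test_zero_rates_produce_nothing(self, gene, memory_spec):
        params = KineticParams(k_polB=0, k_polL=0, k_polH=0)
        prot = InductionProtocol.single_induction(120.0)
        traj = simulate_locus(memory_spec, params, gene, prot, seed=1)
        assert all(len(p) == 0 for p in traj.polii_positions)
        assert traj.completed_mrna_count[-1] == 0

    def test_littles_law_occupancy(self, gene):
        # forced-active locus with negligible footprint: time-averaged
        # Pol II count = k_pol * L / v = 2 * 4500/1500 = 6
        spec = PromoterModelSpec(MODEL1, immediate_activation=True)
        params = KineticParams(k_pol=2.0, footprint_nt=1)
        prot = InductionProtocol.single_induction(10_000.0)
        times = np.arange(100.0, 10_000.0, 7.0)
        traj = simulate_locus(spec, params, gene, prot, seed=7,
                              sample_times=times)
        occ = np.array([len(p) for p in traj.polii_positions])
        se = occ.std(ddof=1) / math.sqrt(occ.size)
        # samples 7 min apart are weakly correlated (residence 3 min);
        # allow 3x the naive SE
        assert abs(occ.mean() - 6.0) < 3 * 3 * se + 0.05

    @pytest.mark.parametrize("engine", ["event", "fixed"])
    def test_footprint_exclusion(self, gene, engine):
        spec = PromoterModelSpec(MODEL1, immediate_activation=True)
        params = KineticParams(k_pol=8.0, footprint_nt=150)
        prot = InductionProtocol.single_induction(30.0)
        traj = simulate_locus(spec, params, gene, prot, seed=3,
                              sample_times=np.arange(1.0, 30.0), engine=engine)
        for pos in traj.polii_positions:
            if len(pos) > 1:
                assert np.min(np.diff(np.sort(pos))) >= params.footprint_nt
            # packing bound L/s
            assert len(pos) <= gene.transcript_length_nt // 150

    def test_completed_count_non_decreasing(self, gene, memory_spec):
        prot = InductionProtocol.standard()
        traj = simulate_locus(memory_spec, KineticParams(), gene, prot, seed=9)
        assert np.all(np.diff(traj.completed_mrna_count) >= 0)

    def test_state_labels(self, gene, memory_spec, model1_spec):
        prot = InductionProtocol.single_induction(60.0)
        t4 = simulate_locus(memory_spec, KineticParams(), gene, prot, seed=2)
        assert set(t4.promoter_state) <= {"UD", "UM", "ID", "IM"}
        t2 = simulate_locus(model1_spec, KineticParams(), gene, prot, seed=2)
        assert set(t2.promoter_state) <= {"inactive", "active"}


class TestSimulatePopulation:
    def test_requires_even_cells(self, gene, memory_spec, standard_protocol):
        with pytest.raises(ValueError):
            simulate_population(memory_spec, KineticParams(), gene,
                                standard_protocol, 11, [60.0], seed=0)

    def test_ploidy_split(self, gene, memory_spec):
        prot = InductionProtocol.single_induction(30.0)
        pop = simulate_population(memory_spec, KineticParams(), gene, prot,
                                  10, [30.0], seed=0)
        counts = pop.table.groupby("cell_id")["n_loci"].first()
        assert (counts == 4).sum() == 5
        assert (counts == 8).sum() == 5
        assert pop.locus_detail["cell_of_locus"].size == 60

    def test_uninduced_population(self, gene, memory_spec):
        params = KineticParams(k_polB=0.0)
        prot = InductionProtocol((
            # hormone-free protocol: only the Poisson mature pool exists
            *InductionProtocol.standard().segments[1:2],
        ))
        pop = simulate_population(memory_spec, params, gene, prot, 400,
                                  [10.0], seed=4, uninduced_mean_puncta=2.0,
                                  tau=1e9)
        assert np.all(pop.table["nascent_cu"] == 0.0)
        assert pop.table["mature_count"].mean() == pytest.approx(
            2.0, abs=3 * math.sqrt(2.0 / 400)
        )

    def test_mean_production_matches_analytic_rate(self, gene, memory_spec):
        # completed transcripts per locus over the first induction vs
        # the integral of the analytic mean production rate
        params = KineticParams(footprint_nt=1)
        dur = 240.0
        prot = InductionProtocol.single_induction(dur)
        pop = simulate_population(
            memory_spec, params, gene, prot, 5000, [dur], seed=21,
            tau=1e12, uninduced_mean_puncta=0.0,
        )
        per_cell = pop.table["mature_count"].to_numpy(float)
        total = per_cell.sum()
        n_loci = 6 * 5000
        ride = gene.transcript_length_nt / params.elongation_nt_per_min
        expected_per_locus, _ = integrate.quad(
            lambda t: mean_production_rate(memory_spec, params, t),
            0.0, dur - ride,
        )
        se = per_cell.std(ddof=1) * math.sqrt(5000) / n_loci
        assert abs(total / n_loci - expected_per_locus) < 3 * se

    def test_seeded_runs_are_bit_reproducible(self, gene, memory_spec,
                                              standard_protocol):
        kw = dict(n_cells=50, sample_times=[60.0, 1800.0], seed=123)
        a = simulate_population(memory_spec, KineticParams(), gene,
                                standard_protocol, **kw)
        b = simulate_population(memory_spec, KineticParams(), gene,
                                standard_protocol, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_engines_agree_on_population_mean(self, gene, model1_spec):
        params = KineticParams(k_A=0.017, k_pol=2.0)
        prot = InductionProtocol.single_induction(60.0)
        pop_f = simulate_population(model1_spec, params, gene, prot, 100,
                                    [60.0], seed=5, engine="fixed")
        pop_e = simulate_population(model1_spec, params, gene, prot, 400,
                                    [60.0], seed=6, engine="event")
        a = pop_f.table["nascent_cu"]
        b = pop_e.table["nascent_cu"]
        se = math.hypot(a.std() / math.sqrt(a.size),
                        b.std() / math.sqrt(b.size))
        assert abs(a.mean() - b.mean()) < 3 * se


class TestRecoveryShortcut:
    def _state(self, n_loci, n_cells, rng):
        return PopulationState(
            memory=np.zeros(n_loci, dtype=bool),
            active=np.ones(n_loci, dtype=bool),
            mature=rng.poisson(20, n_cells),
        )

    def test_memory_fraction_after_standard_recovery(self):
        rng = np.random.default_rng(0)
        state = self._state(20_000, 100, rng)
        out = apply_recovery_shortcut(state, 0.8e-3, 1440.0, 1680.0,
                                      False, 600.0, rng)
        frac = out.memory.mean()
        assert frac == pytest.approx(0.739, abs=3 * math.sqrt(0.74 * 0.26
                                                              / 20_000))
        assert not out.active.any()

    def test_nup98_depletion_erases_memory(self):
        rng = np.random.default_rng(1)
        state = self._state(5000, 100, rng)
        out = apply_recovery_shortcut(state, 0.8e-3, 1440.0, 1680.0,
                                      True, 600.0, rng)
        assert out.memory.sum() == 0

    def test_short_recovery_converts_fewer_loci(self):
        # 60-min induction + 6-hr recovery: 1 - exp(-0.0008*420) ~ 0.285
        rng = np.random.default_rng(2)
        state = self._state(50_000, 100, rng)
        out = apply_recovery_shortcut(state, 0.8e-3, 360.0, 420.0,
                                      False, 600.0, rng)
        expected = memory_fraction(0.8e-3, 420.0)
        assert expected == pytest.approx(0.285, abs=5e-3)
        assert out.memory.mean() == pytest.approx(expected, abs=0.01)
        assert out.memory.mean() < 0.739

    def test_mature_pool_decays(self):
        rng = np.random.default_rng(3)
        state = self._state(100, 2000, rng)
        out = apply_recovery_shortcut(state, 0.8e-3, 1440.0, 1680.0,
                                      False, 600.0, rng)
        ratio = out.mature.sum() / state.mature.sum()
        assert ratio == pytest.approx(math.exp(-1440 / 600), abs=0.02)
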