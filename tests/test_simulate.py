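import numpy as np
import pytest

from tibetscan.data_model import site_frequency_table
from tibetscan.simulate import (
    TABLE1,
    AdmixturePulse,
    ArchaicScenario,
    DemographicModel,
    SweepScenario,
    UnattainableSweepError,
    build_model,
    simulate_archaic,
    simulate_neutral,
    simulate_sweep,
    sweep_frequency_trajectory,
    sweep_grid,
)


class TestModel:
    def test_divergence_is_t2_plus_t3(self, model):
        assert model.divergence_time_years == pytest.approx(54_007.0)
        assert model.divergence_time_years == model.T2 + model.T3

    def test_fitted_point_estimates_are_defaults(self, model):
        assert model.nT1 == 2445 and model.nC2 == 75203
        assert model.m21 == pytest.approx(1.3e-11)  # post-split target->comparison flow

    def test_degenerate_symmetric_model_builds(self):
        m = build_model(
            nC1=1000, nC2=1000, nC3=1000, nT1=1000, nT2=1000, nT3=1000,
            m11=0, m12=0, m21=0, m22=0,
        )
        d = m.to_msprime()
        d.validate()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_model(nT1=-5)
        with pytest.raises(ValueError):
            build_model(T1=10_000, T3=9_419)  # epoch order violated
        with pytest.raises(ValueError):
            build_model(m11=1.5)

    def test_size_history_piecewise(self, model):
        t1, t3, tdiv = model.epoch_bounds_generations()
        sizes = model.population_size_at("TIB", np.array([0.0, t1 - 1, t3 - 1, tdiv + 1]))
        assert sizes[0] == model.nT3
        assert sizes[1] == model.nT3
        assert model.nT2 <= sizes[2] <= model.nT3
        assert sizes[3] == model.nA1


class TestNeutral:
    def test_seed_determinism(self, model):
        a = simulate_neutral(model, sequence_length=1e5, seed=5)
        b = simulate_neutral(model, sequence_length=1e5, seed=5)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)
        c = simulate_neutral(model, sequence_length=1e5, seed=6)
        assert not np.array_equal(a.positions, c.positions)

    def test_sample_sizes_and_phasing_structure(self, neutral_panel):
        assert neutral_panel.n_haplotypes == 2 * (27 + 62)
        assert len(neutral_panel.population_haplotypes("TIB")) == 54
        assert len(neutral_panel.population_haplotypes("HAN")) == 124

    def test_panmictic_diversity_matches_coalescent_expectation(self):
        # effectively panmictic: equal sizes, free interchange via a very
        # recent split; pairwise diversity should be ~4*N*mu per bp
        N = 10_000
        m = build_model(
            nA1=N, nC1=N, nC2=N, nC3=N, nT1=N, nT2=N, nT3=N,
            T1=50.0, T3=75.0, T2=25.0, m11=0, m12=0, m21=0, m22=0,
        )
        L, reps = 100_000, 8
        pis = []
        for r in range(reps):
            panel = simulate_neutral(m, {"TIB": 10}, L, seed=100 + r)
            counts = (panel.alleles == 1).sum(axis=0)
            n = panel.n_haplotypes
            pi = (2 * counts * (n - counts) / (n * (n - 1))).sum() / L
            pis.append(pi)
        expected = 4 * N * m.mutation_rate
        se = np.std(pis, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(pis) - expected) < 3 * se + 0.05 * expected


class TestSweep:
    def test_all_grid_cells_have_trajectories(self, model):
        rng = np.random.default_rng(1)
        assert len(sweep_grid()) == 60  # 3 s x 5 onsets x 4 end frequencies
        for scen in sweep_grid()[::7]:
            traj = sweep_frequency_trajectory(model, scen, rng)
            assert len(traj) == scen.onset_generations_ago + 1
            assert abs(traj[-1] - scen.end_frequency) <= scen.frequency_tolerance

    def test_seed_determinism(self, model):
        scen = SweepScenario(s=0.03, onset_generations_ago=200, end_frequency=0.6,
                             panel_size=200)
        a, ia = simulate_sweep(model, scen, sequence_length=1e5, seed=9)
        b, ib = simulate_sweep(model, scen, sequence_length=1e5, seed=9)
        assert np.array_equal(a.alleles, b.alleles)
        assert ia.realized_frequency == ib.realized_frequency

    def test_end_frequency_conditioning(self, model):
        scen = SweepScenario(s=0.04, onset_generations_ago=300, end_frequency=0.8,
                             panel_size=300)
        freqs = [
            simulate_sweep(model, scen, sequence_length=8e4, seed=300 + i)[1].realized_frequency
            for i in range(25)
        ]
        assert abs(np.mean(freqs) - 0.8) < 0.05

    def test_unattainable_de_novo_raises(self, model):
        scen = SweepScenario(s=0.02, onset_generations_ago=100, end_frequency=0.8,
                             de_novo=True)
        with pytest.raises(UnattainableSweepError):
            sweep_frequency_trajectory(model, scen, np.random.default_rng(0))

    def test_standing_variation_start_backsolved(self, model):
        scen = SweepScenario(s=0.02, onset_generations_ago=100, end_frequency=0.8,
                             panel_size=200)
        _, info = simulate_sweep(model, scen, sequence_length=8e4, seed=11)
        # logistic back-solve: 0.8 / (0.8 + 0.2*e^2) = 0.351
        assert info.start_frequency == pytest.approx(0.351, abs=0.01)

    def test_weak_selection_limit_matches_neutral_frequencies(self, model):
        # s -> 0: the focal site is a conditioned standing variant; allele
        # frequencies elsewhere should stay near their neutral values
        scen = SweepScenario(s=0.0, onset_generations_ago=100, end_frequency=0.5,
                             panel_size=300)
        pan, info = simulate_sweep(model, scen, sequence_length=8e4, seed=21)
        rows = pan.population_haplotypes("TIB")
        assert abs(info.realized_frequency - 0.5) < 0.2
        # neutral panel from the same seed shares no structure, but overall
        # site-frequency spectrum scale should be comparable
        neut = simulate_neutral(model, sequence_length=8e4, seed=21)
        f_sweep = (pan.alleles[rows] == 1).mean()
        f_neut = (neut.alleles[neut.population_haplotypes("TIB")] == 1).mean()
        assert abs(f_sweep - f_neut) < 0.05


class TestArchaic:
    def test_archaic_tracks_present(self, archaic_sim):
        panel, sft, tracts, scenario = archaic_sim
        assert "DEN" in sft.archaic and "NEA" in sft.archaic
        assert set(tracts.columns) == {"haplotype", "left", "right", "source"}

    def test_tract_fraction_matches_pulse(self, model):
        # 2% Denisovan-like pulse: mean introgressed fraction of the target
        # genomes across replicates within 3 SE of the pulse fraction
        scen = ArchaicScenario(pulses=[
            AdmixturePulse(40_000.0, "DENI", "TIB", 0.02),
            AdmixturePulse(40_000.0, "DENI", "HAN", 0.02),
        ])
        fracs = []
        for s in range(8):
            _, _, tr = simulate_archaic(model, scen, sequence_length=1e6, seed=700 + s)
            den = tr[(tr.source == "DENI") & tr.haplotype.str.startswith("TIB")]
            fracs.append((den.right - den.left).sum() / (54 * 1e6))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.02) < 3 * se + 0.002

    def test_seed_determinism(self, model):
        scen = ArchaicScenario()
        a = simulate_archaic(model, scen, sequence_length=2e5, seed=33)
        b = simulate_archaic(model, scen, sequence_length=2e5, seed=33)
        assert np.array_equal(a[0].alleles, b[0].alleles)
        assert a[2].equals(b[2])

    def test_no_admixture_gives_no_tracts(self, model):
        scen = ArchaicScenario(pulses=[AdmixturePulse(40_000.0, "DENI", "TIB", 0.0)])
        _, _, tracts = simulate_archaic(model, scen, sequence_length=3e5, seed=8)
        assert len(tracts) == 0

    def test_pulse_older_than_split_rejected(self, model):
        scen = ArchaicScenario(
            pulses=[AdmixturePulse(500_000.0, "DENI", "TIB", 0.01)]
        )
        with pytest.raises(ValueError):
            simulate_archaic(model, scen, sequence_length=1e5, seed=1)

    def test_with_fractions_rewrites_all_pulses(self):
        scen = ArchaicScenario().with_fractions(0.01, 0.03)
        for p in scen.pulses:
            assert p.fraction == (0.01 if p.source == "DENI" else 0.03)
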