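"""Simulator dynamics: growth, mutation supply, passages, reassignment."""

import numpy as np
import pytest

from dynevolve.env_schedule import parse_schedule
from dynevolve.evo_simulator import (
    SimulatedPopulation,
    SimulatorParameterError,
    SimulatorParams,
    init_library,
    run_experiment,
)

SMALL = dict(n_barcodes=300, saturation_size=256 * 3e4, read_depth=1e6)


def small_params(**kw):
    base = dict(SMALL)
    base.update(kw)
    return SimulatorParams(**base)


class TestParams:
    def test_sign_probabilities_must_sum_to_one(self):
        with pytest.raises(SimulatorParameterError, match="sum to 1"):
            SimulatorParams(p_neutral=0.5, p_deleterious=0.5, p_beneficial=0.5)

    def test_bottleneck_and_dfe_validation(self):
        with pytest.raises(SimulatorParameterError):
            SimulatorParams(bottleneck_factor=0)
        with pytest.raises(SimulatorParameterError):
            SimulatorParams(dfe_bounds={"G": (0.2, 0.1)})
        with pytest.raises(SimulatorParameterError):
            SimulatorParams(mu_env=-1e-5)
        with pytest.raises(SimulatorParameterError):
            SimulatorParams(saturation_size=0)


class TestInitLibrary:
    def test_no_prep_mutation_means_no_mutants(self):
        pop = init_library(small_params(prep_mutation_rate=0.0, seed=0))
        assert pop.n_rows == 300

    def test_lineage_count_matches_barcodes(self):
        pop = init_library(small_params(prep_mutation_rate=0.0, seed=0))
        assert pop.lineage_sizes().shape == (300,)

    def test_prep_mutant_count_matches_poisson_expectation(self):
        """Total pre-existing mutants ~ Poisson(sum sizes x prep gens x rate)."""
        total, expected = 0, 0.0
        for seed in range(3):
            p = small_params(prep_mutation_rate=1e-3, seed=seed)
            pop = init_library(p, first_env="G")
            founders = pop.size[:300].sum()  # held constant through prep
            expected += float(founders) * 16 * 1e-3
            total += pop.n_rows - 300
        assert abs(total - expected) < 4 * np.sqrt(expected)

    def test_prep_needs_first_env(self):
        with pytest.raises(SimulatorParameterError, match="first_env"):
            init_library(small_params(prep_mutation_rate=1e-3, seed=0))


class TestStepGeneration:
    def test_neutral_expected_doubling(self):
        p = small_params(prep_mutation_rate=0.0, mu_env=0.0, seed=3)
        pop = init_library(p)
        before = pop.total_size()
        pop.begin_environment("G")
        pop.step_generation("G")
        after = pop.total_size()
        # Poisson(2 x size): sd = sqrt(2 x before)
        assert abs(after - 2 * before) < 4 * np.sqrt(2 * before)

    def test_extinct_clone_stays_extinct(self):
        p = small_params(prep_mutation_rate=0.0, mu_env=0.0, seed=4, prune=False)
        pop = init_library(p)
        pop.size[pop.active] = 0
        pop.begin_environment("G")
        pop.step_generation("G")
        assert pop.total_size() == 0
        assert pop.n_rows == 300  # no mutants spawned from size-0 feeders

    def test_requires_environment_initialization(self):
        pop = init_library(small_params(prep_mutation_rate=0.0, seed=5))
        with pytest.raises(RuntimeError, match="assign_env_fitness"):
            pop.step_generation("G")

    def test_planted_clone_log_slope(self):
        """A clone planted at s = 0.05/gen gains ~ 8 x 0.05 in log frequency
        over one cycle relative to a neutral pool (deterministic oracle:
        exponential growth at rate s against a neutral background)."""
        deltas = []
        for seed in range(25):
            p = small_params(
                prep_mutation_rate=0.0, mu_env=0.0, seed=seed,
                planted_fitness={0: {"G": 0.05, "F": 0.05, "P": 0.05}},
            )
            pop = init_library(p)
            pop.begin_environment("G")
            f0 = pop.lineage_sizes()[0] / pop.total_size()
            for _ in range(8):
                pop.step_generation("G")
            f1 = pop.lineage_sizes()[0] / pop.total_size()
            deltas.append(np.log(f1 / f0))
        mean, se = np.mean(deltas), np.std(deltas) / np.sqrt(len(deltas))
        # expected slope 8 x 0.05 x (1 - f), f ~ 1/300
        assert abs(mean - 0.4 * (1 - 1 / 300)) < 3 * max(se, 1e-3)


class TestPassage:
    def test_population_returns_to_transfer_size(self):
        p = small_params(prep_mutation_rate=0.0, mu_env=0.0, seed=6)
        pop = init_library(p)
        pop.begin_environment("G")
        for _ in range(8):
            pop.step_generation("G")
        pop.passage()
        expected = p.transfer_size
        assert abs(pop.total_size() - expected) < 5 * np.sqrt(expected)

    def test_frequencies_preserved_in_expectation(self):
        """Mean post-passage frequencies match the pre-passage composition."""
        freqs_in = np.array([0.5, 0.3, 0.15, 0.05])
        means = np.zeros(4)
        n_rep = 60
        for seed in range(n_rep):
            p = SimulatorParams(
                n_barcodes=4, saturation_size=1e6, prep_mutation_rate=0.0,
                mu_env=0.0, seed=seed,
            )
            pop = init_library(p)
            pop.size[:4] = (freqs_in * 10000).astype(int)
            pop.active = np.arange(4)
            pop.passage()
            sizes = pop.lineage_sizes().astype(float)
            means += sizes / sizes.sum() / n_rep
        np.testing.assert_allclose(means, freqs_in, atol=0.02)


class TestAssignEnvFitness:
    def test_all_neutral_probability(self):
        p = small_params(
            prep_mutation_rate=0.05, seed=7,
            p_neutral=1.0, p_deleterious=0.0, p_beneficial=0.0,
        )
        pop = init_library(p, first_env="F")
        pop.begin_environment("G")
        mutants = slice(300, pop.n_rows)
        assert np.all(pop.own["G"][mutants] == 0.0)

    def test_degenerate_beneficial_dfe(self):
        p = small_params(
            prep_mutation_rate=0.05, seed=8,
            p_neutral=0.0, p_deleterious=0.0, p_beneficial=1.0,
            dfe_bounds={"F": (0.0, 0.125), "G": (0.07, 0.07), "P": (0.0, 0.125)},
        )
        pop = init_library(p, first_env="F")
        pop.begin_environment("G")
        np.testing.assert_allclose(pop.own["G"][300 : pop.n_rows], 0.07)

    def test_unbiased_sign_frequencies(self):
        """Pn = Pd = Pb = 1/3 within binomial error over >= 1e4 mutations."""
        p = SimulatorParams(
            n_barcodes=2000, saturation_size=256 * 2e5,
            prep_mutation_rate=0.05, seed=9,
        )
        pop = init_library(p, first_env="F")
        pop.begin_environment("G")
        eff = pop.own["G"][2000 : pop.n_rows]
        n = eff.size
        assert n >= 10_000
        for frac in ((eff == 0).mean(), (eff < 0).mean(), (eff > 0).mean()):
            assert abs(frac - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_unknown_environment_rejected(self):
        pop = init_library(small_params(prep_mutation_rate=0.0, seed=10))
        with pytest.raises(SimulatorParameterError, match="no DFE"):
            pop.begin_environment("X")


class TestSampleReads:
    def test_extinct_lineage_gets_zero(self):
        p = small_params(prep_mutation_rate=0.0, mu_env=0.0, seed=11)
        pop = init_library(p)
        pop.size[0] = 0
        pop.active = pop.active[pop.size[pop.active] > 0]
        counts = pop.sample_reads(1e6)
        assert counts[0] == 0

    def test_total_counts_match_depth(self):
        pop = init_library(small_params(prep_mutation_rate=0.0, seed=12))
        depth = 1e6
        total = pop.sample_reads(depth).sum()
        assert abs(total - depth) < 4 * np.sqrt(depth)

    def test_low_frequency_lineage_mean_count(self):
        """Frequency 1e-5 at depth 3e7 -> mean count 300."""
        p = SimulatorParams(n_barcodes=2, saturation_size=1e7,
                            prep_mutation_rate=0.0, mu_env=0.0, seed=13)
        pop = init_library(p)
        pop.size[0] = 10
        pop.size[1] = 10**6 - 10
        pop.active = np.arange(2)
        draws = np.array([pop.sample_reads(3e7)[0] for _ in range(60)])
        se = np.sqrt(300 / 60)
        assert abs(draws.mean() - 300) < 4 * se

    def test_depth_must_be_positive(self):
        pop = init_library(small_params(prep_mutation_rate=0.0, seed=14))
        with pytest.raises(ValueError):
            pop.sample_reads(0)


class TestRunExperiment:
    def test_counting_conservation(self):
        p = small_params(seed=15)
        res = run_experiment(parse_schedule("FGGG"), p)
        pop = res.population
        assert pop.lineage_sizes().sum() == pop.size[pop.active].sum()

    def test_neutral_run_keeps_mean_frequency(self):
        """With no mutation and no selection, lineage frequency is a
        martingale: the cross-seed mean of final frequencies stays at 1/n."""
        n = 200
        finals = []
        for seed in range(30):
            p = SimulatorParams(
                n_barcodes=n, saturation_size=256 * 2e4, read_depth=1e6,
                prep_mutation_rate=0.0, mu_env=0.0, seed=seed,
            )
            res = run_experiment(parse_schedule("GGG"), p)
            sizes = res.population.lineage_sizes().astype(float)
            finals.append(sizes[: n // 2].sum() / sizes.sum())
        mean = np.mean(finals)
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(mean - 0.5) < 3 * max(se, 1e-3)

    def test_pruning_never_changes_outputs(self):
        """Dropping extinct clones is exactly output-invariant, seed-paired."""
        sched = parse_schedule("FGGGFGGG")
        outs = {}
        for prune in (True, False):
            p = small_params(seed=16, prune=prune)
            outs[prune] = run_experiment(sched, p)
        assert np.array_equal(outs[True].dataset.counts, outs[False].dataset.counts)
        assert outs[True].final_richness == outs[False].final_richness

    def test_stronger_dfe_concentrates_population(self):
        """Raising the DFE upper bound (paired seeds) does not decrease the
        mean final top-100 lineage share."""
        from dynevolve.diversity_stats import top_n_share

        shares = {}
        for hi in (0.03, 0.125):
            vals = []
            for seed in range(5):
                p = small_params(
                    seed=seed,
                    dfe_bounds={e: (0.0, hi) for e in "FGP"},
                )
                res = run_experiment(parse_schedule("GGGGGGGG"), p)
                vals.append(top_n_share(res.dataset.counts[:, -1], 100))
            shares[hi] = np.mean(vals)
        assert shares[0.125] >= shares[0.03] - 0.02

    def test_truth_flags_planted_lineages(self):
        p = small_params(
            prep_mutation_rate=0.0, mu_env=0.0, seed=17,
            planted_fitness={5: {"G": 0.08, "F": 0.0, "P": 0.0}},
        )
        res = run_experiment(parse_schedule("GGG"), p)
        truth = res.lineage_truth
        assert not truth.loc[5, "neutral"]
        assert truth.loc[5, "max_fitness_G"] == pytest.approx(0.08)
        assert truth["neutral"].drop(5).all()

    def test_sample_cadence_validation(self):
        with pytest.raises(ValueError, match="multiple"):
            run_experiment(parse_schedule("GG"), small_params(seed=18), sample_every=5)
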