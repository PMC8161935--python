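"""Steady-state search: initialisation, variation operators, selection
pressure, determinism, and end-to-end runs."""

import numpy as np
import pytest
from scipy import stats

from lgpmine.evolution import (
    EvolutionConfig,
    crossover,
    evolve,
    fitness,
    init_population,
    macro_mutate,
    micro_mutate,
    run_experiment,
    single_run,
    tournament_select,
)
from lgpmine.exceptions import ConfigurationError, InvalidInputError
from lgpmine.program import (
    ASSIGNMENT,
    Program,
    RegisterFile,
    assign,
    classify_batch,
    const,
    reg,
)
from lgpmine.synthetic import PlantedSignalSpec, generate

SMALL = EvolutionConfig(
    population_size=30,
    n_generations=20,
    init_length_range=(5, 15),
    n_calculation_registers=4,
)


def separable_dataset(n=80, seed=0):
    """One informative feature already on the [-1, 1] scale; label = [x0 > 0]."""
    data_rng = np.random.default_rng(seed)
    X = data_rng.uniform(-1, 1, (n, 1))
    return X, (X[:, 0] > 0).astype(int)


class TestInitPopulation:
    def test_lengths_within_init_range(self, rng):
        cfg = EvolutionConfig(population_size=200, init_length_range=(10, 40))
        pop = init_population(cfg, n_features=8, rng=rng)
        assert len(pop) == 200
        assert all(10 <= len(p) <= 40 for p in pop)

    def test_fixed_seed_reproduces_population(self):
        cfg = EvolutionConfig(population_size=20)
        a = init_population(cfg, 5, np.random.default_rng(3))
        b = init_population(cfg, 5, np.random.default_rng(3))
        assert all(x.instructions == y.instructions for x, y in zip(a, b))

    def test_length_distribution_uniform(self):
        # chi-square GOF against the uniform law on [10, 40], alpha = 0.01
        cfg = EvolutionConfig(population_size=10_000, init_length_range=(10, 40))
        rng = np.random.default_rng(99)
        lengths = [len(p) for p in init_population(cfg, 4, rng)]
        observed = np.bincount(lengths, minlength=41)[10:41]
        _, p = stats.chisquare(observed)
        assert p > 0.01

    def test_invalid_config_rejected(self, rng):
        cfg = EvolutionConfig(init_length_range=(0, 40))
        with pytest.raises(ConfigurationError):
            init_population(cfg, 4, rng)


class TestFitness:
    def test_perfect_program_scores_one(self, rng):
        X, y = separable_dataset()
        rf = RegisterFile(4, 1)
        p = Program([assign(0, "add", reg(4), reg(4))], rf)  # r0 = 2 * x0
        cfg = EvolutionConfig(n_calculation_registers=4)
        assert fitness(p, X, y, cfg, rng) == 1.0

    def test_degenerate_bootstrap_interval_is_exact_accuracy(self, rng):
        X, y = separable_dataset(seed=1)
        rf = RegisterFile(4, 1)
        p = Program([assign(0, "add", reg(4), reg(4))], rf)
        cfg = EvolutionConfig(
            n_calculation_registers=4, bootstrap_fraction_range=(1.0, 1.0)
        )
        exact = np.mean(classify_batch(p, X) == y)
        assert fitness(p, X, y, cfg, rng) == exact

    def test_constant_program_near_half_on_balanced_data(self):
        X, y = separable_dataset(n=400, seed=2)
        rf = RegisterFile(4, 1)
        p = Program([assign(0, "add", const(5), const(5))], rf)  # always class 1
        cfg = EvolutionConfig(n_calculation_registers=4)
        rng = np.random.default_rng(0)
        vals = [fitness(p, X, y, cfg, rng) for _ in range(30)]
        assert abs(np.mean(vals) - 0.5) < 0.08

    def test_empty_training_set_rejected(self, rng):
        rf = RegisterFile(4, 1)
        p = Program([assign(0, "add", const(1), const(1))], rf)
        with pytest.raises(InvalidInputError):
            fitness(p, np.empty((0, 1)), np.empty(0), EvolutionConfig(), rng)


class TestTournament:
    def test_whole_population_tournament_returns_global_extremes(self, rng):
        fits = [0.1, 0.9, 0.5, 0.7, 0.2, 0.8]
        winners, losers = tournament_select([None] * 6, fits, 6, rng)
        assert set(winners) == {1, 5}
        assert set(losers) == {0, 4}

    def test_ties_break_by_lower_index_and_parents_survive(self, rng):
        winners, losers = tournament_select([None] * 8, [0.5] * 8, 8, rng)
        assert winners == (0, 1)
        assert losers == (2, 3)
        assert set(winners).isdisjoint(losers)

    def test_oversized_tournament_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            tournament_select([None] * 4, [0.5] * 4, 5, rng)

    def test_selection_frequency_increases_with_fitness_rank(self):
        rng = np.random.default_rng(11)
        fits = list(rng.permutation(100) / 100.0)
        wins = np.zeros(100)
        for _ in range(10_000):
            winners, _ = tournament_select([None] * 100, fits, 8, rng)
            wins[list(winners)] += 1
        ranks = np.argsort(fits)  # ascending fitness
        by_rank = wins[ranks]
        # strong positive association between rank and selection count
        rho = stats.spearmanr(np.arange(100), by_rank).statistic
        assert rho > 0.9
        assert by_rank[-20:].sum() > 10 * by_rank[:20].sum()


class TestCrossover:
    def make_pair(self, rng):
        from lgpmine.evolution import random_program

        cfg = EvolutionConfig(init_length_range=(5, 20), n_calculation_registers=4)
        rf = RegisterFile(4, 6)
        return random_program(rng, rf, cfg), random_program(rng, rf, cfg)

    def test_identical_parents_give_equivalent_offspring(self, rng):
        a, _ = self.make_pair(rng)
        b = a.copy()
        o1, o2 = crossover(a, b, 300, rng)
        combined = sorted(map(id, o1.instructions + o2.instructions))
        assert combined == sorted(map(id, a.instructions + b.instructions))

    def test_total_instruction_count_conserved(self, rng):
        for _ in range(200):
            a, b = self.make_pair(rng)
            o1, o2 = crossover(a, b, 300, rng)
            assert len(o1) + len(o2) == len(a) + len(b)

    def test_offspring_lengths_bounded_and_instructions_have_provenance(self, rng):
        for _ in range(500):
            a, b = self.make_pair(rng)
            parent_ids = set(map(id, a.instructions + b.instructions))
            o1, o2 = crossover(a, b, 30, rng)
            for o in (o1, o2):
                assert 1 <= len(o) <= 30
                assert set(map(id, o.instructions)) <= parent_ids


class TestMutation:
    def test_macro_changes_length_by_exactly_one(self, rng):
        cfg = EvolutionConfig(n_calculation_registers=4, init_length_range=(2, 50))
        rf = RegisterFile(4, 6)
        pop = init_population(
            EvolutionConfig(population_size=300, n_calculation_registers=4,
                            init_length_range=(2, 50)),
            6, rng,
        )
        for p in pop:
            q = macro_mutate(p, cfg, rng)
            assert abs(len(q) - len(p)) == 1

    def test_macro_at_boundaries(self, rng):
        cfg = EvolutionConfig(n_calculation_registers=4, max_program_length=5)
        rf = RegisterFile(4, 3)
        one = Program([assign(0, "add", const(1), const(1))], rf)
        assert len(macro_mutate(one, cfg, rng)) == 2  # can only insert
        full = Program([assign(0, "add", const(1), const(1))] * 5, rf)
        assert len(macro_mutate(full, cfg, rng)) == 4  # can only delete

    def test_micro_changes_exactly_one_instruction(self, rng):
        cfg = EvolutionConfig(n_calculation_registers=4)
        pop = init_population(
            EvolutionConfig(population_size=300, n_calculation_registers=4),
            6, rng,
        )
        for p in pop:
            q = micro_mutate(p, cfg, rng)
            assert len(q) == len(p)
            diffs = [
                i for i, (x, y) in enumerate(zip(p.instructions, q.instructions))
                if x != y
            ]
            assert len(diffs) == 1

    def test_micro_destinations_stay_calculation_registers(self, rng):
        cfg = EvolutionConfig(n_calculation_registers=4)
        pop = init_population(
            EvolutionConfig(population_size=500, n_calculation_registers=4),
            6, rng,
        )
        for p in pop:
            q = micro_mutate(p, cfg, rng)
            for ins in q.instructions:
                if ins.kind == ASSIGNMENT:
                    assert q.register_file.is_calculation(ins.destination)


class TestEvolve:
    def test_zero_generations_returns_best_of_initial_population(self):
        X, y = separable_dataset(seed=3)
        cfg = EvolutionConfig(
            population_size=20, n_generations=0, n_calculation_registers=4
        )
        m = evolve(cfg, X, y, np.random.default_rng(1))
        assert 0 <= m.fitness <= 1
        assert m.fitness_history == [m.fitness]

    def test_fixed_seed_reproduces_best_model(self):
        X, y = separable_dataset(seed=4)
        cfg = EvolutionConfig(population_size=25, n_generations=30,
                              n_calculation_registers=4)
        a = evolve(cfg, X, y, np.random.default_rng(7))
        b = evolve(cfg, X, y, np.random.default_rng(7))
        assert a.program.instructions == b.program.instructions
        assert a.fitness == b.fitness

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ConfigurationError):
            evolve(EvolutionConfig(), X, np.zeros(10), np.random.default_rng(0))

    def test_best_so_far_fitness_never_decreases(self):
        X, y = separable_dataset(seed=5)
        cfg = EvolutionConfig(population_size=30, n_generations=60,
                              n_calculation_registers=4)
        m = evolve(cfg, X, y, np.random.default_rng(2))
        hist = np.array(m.fitness_history)
        assert np.all(np.diff(hist) >= 0)

    def test_converges_on_separable_data(self):
        X, y = separable_dataset(n=100, seed=6)
        cfg = EvolutionConfig(population_size=100, n_generations=200,
                              n_calculation_registers=4)
        m = evolve(cfg, X, y, np.random.default_rng(3))
        train_acc = np.mean(classify_batch(m.simplified, X) == y)
        assert train_acc >= 0.9


@pytest.fixture(scope="module")
def planted():
    spec = PlantedSignalSpec(
        n_samples=60, n_features=5,
        interaction_pairs=(((1, 3), "additive_threshold", 1.0),), seed=8,
    )
    return generate(spec)[0]


class TestRunExperiment:
    def test_single_run_collection(self, planted):
        cfg = EvolutionConfig(population_size=20, n_generations=10,
                              n_calculation_registers=4)
        coll = run_experiment(cfg, planted, n_runs=1, base_seed=0)
        assert coll.n_runs == 1
        m = coll.models[0]
        for v in (m.fitness, m.test_accuracy, m.f1, m.auc):
            assert 0 <= v <= 1

    def test_same_base_seed_identical_collection(self, planted):
        cfg = EvolutionConfig(population_size=15, n_generations=10,
                              n_calculation_registers=4)
        a = run_experiment(cfg, planted, 3, base_seed=5)
        b = run_experiment(cfg, planted, 3, base_seed=5)
        for x, y in zip(a.models, b.models):
            assert x.program.instructions == y.program.instructions
            assert x.test_accuracy == y.test_accuracy

    def test_stored_metrics_self_consistent(self, planted):
        cfg = EvolutionConfig(population_size=20, n_generations=15,
                              n_calculation_registers=4)
        coll = run_experiment(cfg, planted, 5, base_seed=21)
        for m in coll.models:
            idx = np.array(m.split_record["test_indices"])
            preds = classify_batch(m.program, planted.features[idx])
            assert np.mean(preds == planted.labels[idx]) == pytest.approx(
                m.test_accuracy
            )

    def test_worker_count_does_not_change_results(self, planted):
        cfg = EvolutionConfig(population_size=15, n_generations=8,
                              n_calculation_registers=4)
        serial = run_experiment(cfg, planted, 4, base_seed=2, n_jobs=1)
        parallel = run_experiment(cfg, planted, 4, base_seed=2, n_jobs=2)
        for x, y in zip(serial.models, parallel.models):
            assert x.program.instructions == y.program.instructions
            assert x.fitness == y.fitness
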