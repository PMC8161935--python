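"""Steady-state evolutionary search over linear genetic programs.

Each tournament event draws a random subset of the population, copies the
two fittest contestants, recombines/mutates the copies, evaluates them on a
bootstrap subsample of the training set (accuracy fitness), and writes them
back over the two worst contestants. The best-fitness program ever observed
is the run's model. Repeating the whole procedure under many independent
seeds yields the model collection that all interpretability analysis
consumes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from . import dataio
from .exceptions import ConfigurationError, InvalidInputError
from .metrics import ConfusionCounts, accuracy, auc, f1_score
from .program import (
    ASSIGNMENT,
    BRANCH,
    COMPARISONS,
    OPERATORS,
    Instruction,
    Operand,
    Program,
    RegisterFile,
    assign,
    branch,
    classify_batch,
    const,
    effective_features,
    execute_batch,
    predict_proba_batch,
    reg,
    simplify,
)

#: probability that a freshly drawn operand is a constant rather than a register
P_CONSTANT_OPERAND = 0.25
#: bounded retries when crossover would violate the length bounds
CROSSOVER_RETRIES = 10


@dataclass(frozen=True)
class EvolutionConfig:
    """Search hyper-parameters.

    Defaults follow the published configuration: population 800 for 240
    generations, size-8 tournaments, crossover/macro/micro probabilities
    0.75/0.75/0.5, initial lengths uniform on [10, 40], a 300-instruction
    cap, integer constants 1-10, and bootstrap fitness subsampling of
    50-100% of the training set without replacement.
    """

    population_size: int = 800
    n_generations: int = 240
    tournament_size: int = 8
    p_crossover: float = 0.75
    p_micro_mutation: float = 0.5
    p_macro_mutation: float = 0.75
    init_length_range: tuple[int, int] = (10, 40)
    max_program_length: int = 300
    constant_range: tuple[int, int] = (1, 10)
    n_calculation_registers: int = 6  # r[0] plus five scratch registers
    bootstrap_fraction_range: tuple[float, float] = (0.5, 1.0)
    tournaments_per_generation: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_crossover", "p_micro_mutation", "p_macro_mutation"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        lo, hi = self.init_length_range
        if not 1 <= lo <= hi <= self.max_program_length:
            raise ConfigurationError("init_length_range outside [1, max length]")
        blo, bhi = self.bootstrap_fraction_range
        if not 0 < blo <= bhi <= 1:
            raise ConfigurationError("bootstrap fractions must lie in (0, 1]")
        if self.tournament_size < 4:
            raise ConfigurationError("tournament_size must be at least 4")
        if self.tournament_size > self.population_size:
            raise ConfigurationError("tournament larger than population")
        if self.n_calculation_registers < 2:
            raise ConfigurationError("need r[0] plus at least one scratch register")
        if self.n_generations < 0 or self.tournaments_per_generation < 1:
            raise ConfigurationError("invalid generation counts")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("init_length_range", "constant_range", "bootstrap_fraction_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvolutionConfig":
        kwargs = dict(d)
        for k in ("init_length_range", "constant_range", "bootstrap_fraction_range"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class EvolvedModel:
    """Best-of-run program with its provenance and held-out metrics."""

    program: Program
    fitness: float
    feature_names: list[str] = field(default_factory=list)
    effective_feature_names: set[str] = field(default_factory=set)
    test_accuracy: float | None = None
    f1: float | None = None
    auc: float | None = None
    run_seed: int | None = None
    config: EvolutionConfig | None = None
    split_record: dict | None = None
    dataset_fingerprint: str | None = None
    #: best-so-far fitness after initialisation and after each tournament
    #: event; non-decreasing by construction (not serialised in archives)
    fitness_history: list[float] | None = None

    @property
    def simplified(self) -> Program:
        return simplify(self.program)

    @property
    def n_effective_features(self) -> int:
        return len(self.effective_feature_names)


@dataclass
class RunCollection:
    """Best models from N independent runs; the substrate of all
    importance/synergy analysis."""

    models: list[EvolvedModel]
    dataset_fingerprint: str = ""

    @property
    def n_runs(self) -> int:
        return len(self.models)

    @property
    def feature_names(self) -> list[str]:
        return self.models[0].feature_names if self.models else []


def _random_operand(rng, n_total_registers: int, constant_range) -> Operand:
    if rng.random() < P_CONSTANT_OPERAND:
        return const(int(rng.integers(constant_range[0], constant_range[1] + 1)))
    return reg(int(rng.integers(0, n_total_registers)))


def random_instruction(rng, register_file: RegisterFile, config: EvolutionConfig) -> Instruction:
    a = _random_operand(rng, register_file.n_total, config.constant_range)
    b = _random_operand(rng, register_file.n_total, config.constant_range)
    if rng.random() < 0.5:
        dest = int(rng.integers(0, register_file.n_calculation))
        op = OPERATORS[rng.integers(0, len(OPERATORS))]
        return assign(dest, op, a, b)
    cmp = COMPARISONS[rng.integers(0, len(COMPARISONS))]
    return branch(cmp, a, b)


def random_program(rng, register_file: RegisterFile, config: EvolutionConfig) -> Program:
    lo, hi = config.init_length_range
    length = int(rng.integers(lo, hi + 1))
    return Program(
        [random_instruction(rng, register_file, config) for _ in range(length)],
        register_file,
    )


def init_population(config: EvolutionConfig, n_features: int, rng) -> list[Program]:
    """Random programs with lengths uniform on the initialisation range."""
    if n_features < 1:
        raise ConfigurationError("need at least one feature")
    config.validate()
    rf = RegisterFile(config.n_calculation_registers, n_features)
    return [random_program(rng, rf, config) for _ in range(config.population_size)]


def fitness(
    program: Program,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: EvolutionConfig,
    rng,
) -> float:
    """Accuracy on a bootstrap subsample (u ~ U[50%, 100%] of the training
    set by default, drawn without replacement)."""
    n = len(train_labels)
    if n == 0:
        raise InvalidInputError("empty training set")
    lo, hi = config.bootstrap_fraction_range
    u = rng.uniform(lo, hi)
    m = max(1, int(round(u * n)))
    idx = rng.choice(n, size=min(m, n), replace=False)
    # executing the intron-free form is semantics-preserving and much cheaper
    preds = classify_batch(simplify(program), train_features[idx])
    return accuracy(preds, train_labels[idx])


def tournament_select(population, fitnesses, size: int, rng):
    """Draw ``size`` distinct contestants; return (winners, losers) index
    pairs — the two best and two worst, ties broken by lower index."""
    if size > len(population):
        raise InvalidInputError("tournament larger than population")
    contestants = rng.choice(len(population), size=size, replace=False)
    by_best = sorted(contestants, key=lambda i: (-fitnesses[i], i))
    winners = (int(by_best[0]), int(by_best[1]))
    # losers come from the remaining contestants so that, under fitness
    # ties, parents are never displaced by their own offspring
    rest = by_best[2:]
    by_worst = sorted(rest, key=lambda i: (fitnesses[i], i))
    losers = (int(by_worst[0]), int(by_worst[1]))
    return winners, losers


def crossover(parent_a: Program, parent_b: Program, max_length: int, rng):
    """Two-point segment exchange.

    A contiguous (possibly empty) segment is cut from each parent and the
    segments are swapped. Cut pairs violating 1 <= length <= max_length are
    re-drawn a bounded number of times before falling back to parent copies.
    """
    a, b = parent_a.instructions, parent_b.instructions
    for _ in range(CROSSOVER_RETRIES):
        i1, i2 = sorted(rng.integers(0, len(a) + 1, size=2))
        j1, j2 = sorted(rng.integers(0, len(b) + 1, size=2))
        child_a = a[:i1] + b[j1:j2] + a[i2:]
        child_b = b[:j1] + a[i1:i2] + b[j2:]
        if 1 <= len(child_a) <= max_length and 1 <= len(child_b) <= max_length:
            return (
                Program(child_a, parent_a.register_file),
                Program(child_b, parent_b.register_file),
            )
    return parent_a.copy(), parent_b.copy()


def macro_mutate(program: Program, config: EvolutionConfig, rng) -> Program:
    """Insert or delete one whole instruction (equal odds), respecting the
    length bounds: never deletes to empty, never inserts past the cap."""
    ins = list(program.instructions)
    can_insert = len(ins) < config.max_program_length
    can_delete = len(ins) > 1
    do_insert = can_insert and (not can_delete or rng.random() < 0.5)
    if do_insert:
        pos = int(rng.integers(0, len(ins) + 1))
        ins.insert(pos, random_instruction(rng, program.register_file, config))
    elif can_delete:
        pos = int(rng.integers(0, len(ins)))
        del ins[pos]
    return Program(ins, program.register_file)


def micro_mutate(program: Program, config: EvolutionConfig, rng) -> Program:
    """Change exactly one component of one instruction: an operand, the
    destination register, or the operator/comparator."""
    ins = list(program.instructions)
    i = int(rng.integers(0, len(ins)))
    old = ins[i]
    rf = program.register_file
    if old.kind == ASSIGNMENT:
        fields = ("destination", "operator", "operand_a", "operand_b")
    else:
        fields = ("comparison", "operand_a", "operand_b")
    which = fields[rng.integers(0, len(fields))]
    if which == "destination":
        choices = [d for d in range(rf.n_calculation) if d != old.destination]
        new = assign(
            int(choices[rng.integers(0, len(choices))]),
            old.operator,
            old.operand_a,
            old.operand_b,
        )
    elif which == "operator":
        ops = [o for o in OPERATORS if o != old.operator]
        new = assign(
            old.destination,
            ops[rng.integers(0, len(ops))],
            old.operand_a,
            old.operand_b,
        )
    elif which == "comparison":
        cmp = "greater_than" if old.comparison == "less_than" else "less_than"
        new = branch(cmp, old.operand_a, old.operand_b)
    else:
        current = getattr(old, which)
        operand = current
        while operand == current:
            operand = _random_operand(rng, rf.n_total, config.constant_range)
        a = operand if which == "operand_a" else old.operand_a
        b = operand if which == "operand_b" else old.operand_b
        if old.kind == ASSIGNMENT:
            new = assign(old.destination, old.operator, a, b)
        else:
            new = branch(old.comparison, a, b)
    ins[i] = new
    return Program(ins, rf)


def evolve(
    config: EvolutionConfig,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    rng,
) -> EvolvedModel:
    """Run one steady-state evolutionary search; return the best-ever model.

    Per tournament event the two winners are copied; crossover is applied
    with ``p_crossover`` (otherwise the copies stay clones), then each
    offspring independently undergoes macro- and micro-mutation by coin
    flip, is evaluated once on a fresh bootstrap subsample, and replaces
    one of the two losers. Ties in best fitness keep the earliest model.
    """
    config.validate()
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training labels contain a single class")

    population = init_population(config, X.shape[1], rng)
    fitnesses = [fitness(p, X, y, config, rng) for p in population]

    best_i = int(np.argmax(fitnesses))  # argmax keeps the earliest on ties
    best_program = population[best_i].copy()
    best_fitness = fitnesses[best_i]
    history = [best_fitness]

    n_events = config.n_generations * config.tournaments_per_generation
    for _ in range(n_events):
        (w0, w1), (l0, l1) = tournament_select(
            population, fitnesses, config.tournament_size, rng
        )
        o0, o1 = population[w0].copy(), population[w1].copy()
        if rng.random() < config.p_crossover:
            o0, o1 = crossover(o0, o1, config.max_program_length, rng)
        offspring = []
        for o in (o0, o1):
            if rng.random() < config.p_macro_mutation:
                o = macro_mutate(o, config, rng)
            if rng.random() < config.p_micro_mutation:
                o = micro_mutate(o, config, rng)
            offspring.append(o)
        for o, loser in zip(offspring, (l0, l1)):
            f = fitness(o, X, y, config, rng)
            population[loser] = o
            fitnesses[loser] = f
            if f > best_fitness:
                best_fitness = f
                best_program = o.copy()
        history.append(best_fitness)

    return EvolvedModel(
        program=best_program,
        fitness=float(best_fitness),
        config=config,
        fitness_history=history,
    )


def evaluate_model(
    model: EvolvedModel, test_features: np.ndarray, test_labels: np.ndarray
) -> EvolvedModel:
    """Fill in held-out metrics (accuracy, F1 with class 1 positive, AUC on
    sigmoid probabilities) for an evolved model, in place."""
    program = model.simplified
    preds = classify_batch(program, test_features)
    probs = predict_proba_batch(program, test_features)
    model.test_accuracy = accuracy(preds, test_labels)
    model.f1 = f1_score(ConfusionCounts.from_predictions(preds, test_labels))
    model.auc = auc(probs, test_labels)
    return model


def single_run(
    config: EvolutionConfig, dataset: "dataio.Dataset", seed: int
) -> EvolvedModel:
    """One independent run: fresh 80/20 stratified split, evolve on the
    training portion, evaluate on the held-out portion."""
    train, test, record = dataio.split(dataset, test_fraction=0.2, seed=seed)
    rng = np.random.default_rng(seed)
    model = evolve(config, train.features, train.labels, rng)
    model.run_seed = int(seed)
    model.feature_names = list(dataset.feature_names)
    model.effective_feature_names = {
        dataset.feature_names[i] for i in effective_features(model.program)
    }
    model.split_record = record
    model.dataset_fingerprint = dataset.fingerprint()
    evaluate_model(model, test.features, test.labels)
    return model


def run_experiment(
    config: EvolutionConfig,
    dataset: "dataio.Dataset",
    n_runs: int,
    base_seed: int,
    n_jobs: int = 1,
) -> RunCollection:
    """``n_runs`` independent seeded runs (seed_i = base_seed + i); the
    result is identical for any worker count."""
    seeds = [base_seed + i for i in range(n_runs)]
    if n_jobs == 1:
        models = [single_run(config, dataset, s) for s in seeds]
    else:
        models = Parallel(n_jobs=n_jobs)(
            delayed(single_run)(config, dataset, s) for s in seeds
        )
    return RunCollection(models=list(models), dataset_fingerprint=dataset.fingerprint())
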