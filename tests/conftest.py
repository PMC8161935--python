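import numpy as np
import pytest

from lgpmine.evolution import EvolutionConfig, EvolvedModel, RunCollection, random_program
from lgpmine.program import Program, RegisterFile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_program(rng, n_instructions_max=30, n_calc=6, n_features=8) -> Program:
    """A random valid program of length 1..n_instructions_max."""
    cfg = EvolutionConfig(
        init_length_range=(1, n_instructions_max),
        n_calculation_registers=n_calc,
    )
    rf = RegisterFile(n_calc, n_features)
    return random_program(rng, rf, cfg)


def make_model(effective_names, test_accuracy=0.9, feature_names=None) -> EvolvedModel:
    """Minimal hand-built model for collection-level analysis tests."""
    rf = RegisterFile(2, 3)
    from lgpmine.program import assign, reg

    return EvolvedModel(
        program=Program([assign(0, "add", reg(0), reg(1))], rf),
        fitness=1.0,
        feature_names=feature_names or ["A", "B", "C"],
        effective_feature_names=set(effective_names),
        test_accuracy=test_accuracy,
        f1=test_accuracy,
        auc=test_accuracy,
        run_seed=0,
    )


def make_collection(effective_sets, accuracies=None, feature_names=None) -> RunCollection:
    accuracies = accuracies or [0.9] * len(effective_sets)
    models = [
        make_model(s, a, feature_names) for s, a in zip(effective_sets, accuracies)
    ]
    return RunCollection(models=models)
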