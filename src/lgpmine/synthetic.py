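"""Metabolomics-like synthetic datasets with known ground truth.

The generator emulates the shape of a plasma-metabolite case/control table
(by default ~170 samples x ~240 continuous features, balanced classes) and
plants signals of two kinds: additive main effects / additive pair rules
(class decided by a weighted sum crossing zero, the structure the evolved
two-feature models exhibit) and XOR-style pure interactions (class decided
by exactly one of a pair exceeding its median — zero marginal effect, so
only interaction-aware methods can find the pair). Everything is seeded
and the returned ground-truth record carries what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import Dataset, normalize
from .exceptions import GenerationError, InvalidInputError
from .program import (
    Program,
    RegisterFile,
    assign,
    branch,
    const,
    reg,
)

ADDITIVE = "additive_threshold"
XOR = "xor"

#: resampling attempts before declaring the class-balance target infeasible
BALANCE_RETRIES = 50
#: accepted deviation of the realised class-1 fraction from the target
BALANCE_TOL = 0.1


@dataclass(frozen=True)
class PlantedSignalSpec:
    """What to plant and at what scale.

    ``main_effect_features`` is a list of (feature index, effect size);
    ``interaction_pairs`` is a list of ((i, j), kind, strength) with kind
    ``additive_threshold`` or ``xor``. ``label_noise`` flips each label
    independently. Background features are i.i.d. Gaussian(0, noise_sd).
    """

    n_samples: int = 170
    n_features: int = 240
    main_effect_features: tuple = ()
    interaction_pairs: tuple = ()
    label_noise: float = 0.0
    class_balance: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise InvalidInputError("need at least 2 samples and 1 feature")
        planted = [i for i, _ in self.main_effect_features]
        for (i, j), kind, _ in self.interaction_pairs:
            if kind not in (ADDITIVE, XOR):
                raise InvalidInputError(f"unknown interaction kind {kind!r}")
            planted += [i, j]
        if len(planted) != len(set(planted)):
            raise InvalidInputError("planted feature indices must be distinct")
        if any(not 0 <= i < self.n_features for i in planted):
            raise InvalidInputError("planted feature index out of range")
        for p, name in ((self.label_noise, "label_noise"), (self.class_balance, "class_balance")):
            if not 0 <= p <= 1:
                raise InvalidInputError(f"{name} outside [0, 1]")


def _labels_for(spec: PlantedSignalSpec, X: np.ndarray, rng) -> np.ndarray:
    """Apply the planted rule to raw features; random labels when nothing
    is planted (null data)."""
    if not spec.main_effect_features and not spec.interaction_pairs:
        return rng.integers(0, 2, size=X.shape[0])
    score = np.zeros(X.shape[0])
    for i, effect in spec.main_effect_features:
        score += effect * X[:, i]
    for (i, j), kind, strength in spec.interaction_pairs:
        if kind == ADDITIVE:
            score += strength * (X[:, i] + X[:, j])
        else:  # XOR: exactly one of the pair above its median
            above_i = X[:, i] > np.median(X[:, i])
            above_j = X[:, j] > np.median(X[:, j])
            exactly_one = above_i ^ above_j
            score += strength * np.where(exactly_one, 1.0, -1.0)
    return (score > 0).astype(np.int64)


def generate(spec: PlantedSignalSpec) -> tuple[Dataset, dict]:
    """Draw a dataset satisfying the spec; returns it min-max normalised
    onto [-1, 1] together with a ground-truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    for _ in range(BALANCE_RETRIES):
        X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))
        clean = _labels_for(spec, X, rng)
        if abs(clean.mean() - spec.class_balance) <= BALANCE_TOL:
            break
    else:
        raise GenerationError(
            f"could not reach class balance {spec.class_balance} "
            f"within {BALANCE_RETRIES} draws"
        )
    flips = rng.random(spec.n_samples) < spec.label_noise
    labels = np.where(flips, 1 - clean, clean)
    names = [f"met_{i:03d}" for i in range(spec.n_features)]
    dataset = Dataset(
        features=X,
        labels=labels,
        feature_names=names,
        sample_ids=[f"s{i:03d}" for i in range(spec.n_samples)],
        label_mapping={"0": 0, "1": 1},
    )
    dataset = normalize(dataset)
    planted = sorted(
        {i for i, _ in spec.main_effect_features}
        | {i for (pair, _, _) in spec.interaction_pairs for i in pair}
    )
    # marginal point-biserial correlation of each planted feature with the label
    marginal_r = {
        int(i): float(np.corrcoef(X[:, i], labels)[0, 1]) for i in planted
    }
    truth = {
        "spec": {
            "n_samples": spec.n_samples,
            "n_features": spec.n_features,
            "main_effect_features": [list(m) for m in spec.main_effect_features],
            "interaction_pairs": [
                [list(pair), kind, strength]
                for pair, kind, strength in spec.interaction_pairs
            ],
            "label_noise": spec.label_noise,
            "class_balance": spec.class_balance,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
        "planted_features": [int(i) for i in planted],
        "planted_feature_names": [names[i] for i in planted],
        "clean_labels": clean.tolist(),
        "n_flipped": int(flips.sum()),
        "marginal_r": marginal_r,
    }
    return dataset, truth


def fixture_program(kind: str) -> Program:
    """Deterministic hand-authored programs used across the test suites.

    All use 6 calculation registers (``r[0]``-``r[5]``) and 5 input
    registers (``r[6]``-``r[10]`` holding features 0-4).

    - ``textbook_example``: seven instructions of which exactly two (lines 2 and 6,
      1-based) are non-effective; the input register ``r[7]`` appears only
      in those, so feature 1 is ineffective.
    - ``two_feature_sum``: two instructions comparing the sum of two
      feature concentrations against a constant — the archetypal compact
      evolved model.
    - ``dead_code_heavy``: eight instructions, exactly four of them
      structural introns, so simplify() halves the program.
    """
    rf = RegisterFile(n_calculation=6, n_input=5)
    if kind == "textbook_example":
        ins = [
            assign(1, "sub", reg(8), const(4)),       # 1: r1 = f2 - 4
            assign(2, "add", reg(7), const(1)),       # 2: intron (writes dead r2)
            branch("less_than", reg(6), reg(10)),     # 3: guards line 5 with 4
            branch("greater_than", reg(10), const(2)),# 4
            assign(0, "add", reg(1), reg(6)),         # 5: guarded write to r0
            assign(3, "mul", reg(7), reg(2)),         # 6: intron (writes dead r3)
            assign(0, "add", reg(0), reg(1)),         # 7
        ]
    elif kind == "two_feature_sum":
        ins = [
            assign(1, "add", reg(6), reg(7)),  # r1 = f0 + f1
            assign(0, "sub", reg(1), const(5)),  # class 1 iff f0 + f1 >= 5
        ]
    elif kind == "dead_code_heavy":
        ins = [
            assign(2, "mul", reg(8), const(3)),  # intron
            assign(1, "add", reg(6), const(1)),
            assign(3, "sub", reg(2), reg(9)),    # intron
            assign(4, "add", const(7), reg(10)), # intron
            assign(0, "mul", reg(1), reg(7)),
            assign(5, "add", reg(0), reg(0)),    # intron
            assign(0, "mul", reg(0), const(1)),
            assign(0, "add", reg(0), reg(1)),
        ]
    else:
        raise InvalidInputError(f"unknown fixture kind {kind!r}")
    return Program(ins, rf)
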