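"""Register-machine linear genetic programs.

A program is an ordered list of instructions operating on a register file.
Calculation registers (``r[0]`` .. ``r[n_calc-1]``, with ``r[0]`` the
designated output register) are read/write scratch space; input registers
(``r[n_calc]`` onward) are loaded from the feature vector and are read-only.
Instructions are either assignments (``r[d] = a <op> b``, where the
destination must be a calculation register so features are never
overwritten) or conditional branches (``if a < b:`` / ``if a > b:``).

Branch semantics: a branch guards the first non-branch instruction that
follows it. When the condition is false the guarded instruction is skipped,
together with any intervening branches; a chain of consecutive branches
therefore guards a single assignment and *all* conditions must hold for it
to execute. A branch at the end of a program guards nothing.

The final value of ``r[0]``, squashed through a sigmoid, yields a class
probability. Instructions whose execution cannot influence ``r[0]`` are
structural introns ("non-effective code"); :func:`effective_instructions`
detects them and :func:`simplify` removes them without changing semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exceptions import FormatError, InvalidInputError

REGISTER = "register"
CONSTANT = "constant"
ASSIGNMENT = "assignment"
BRANCH = "branch"

OPERATORS = ("add", "sub", "mul", "div", "exponent")
COMPARISONS = ("less_than", "greater_than")

OPERATOR_SYMBOLS = {"add": "+", "sub": "-", "mul": "*", "div": "/", "exponent": "^"}
COMPARISON_SYMBOLS = {"less_than": "<", "greater_than": ">"}
_SYMBOL_OPERATORS = {v: k for k, v in OPERATOR_SYMBOLS.items()}
_SYMBOL_COMPARISONS = {v: k for k, v in COMPARISON_SYMBOLS.items()}

#: |b| at or below this is treated as zero by protected division.
DIV_EPS = 1e-9
#: protected exponent clamps its result into [-EXP_CLAMP, EXP_CLAMP].
EXP_CLAMP = 1e6


@dataclass(frozen=True)
class Operand:
    """A register reference or an integer constant."""

    kind: str
    register_index: int | None = None
    constant_value: int | None = None

    def __post_init__(self):
        if self.kind == REGISTER:
            if self.register_index is None or self.register_index < 0:
                raise InvalidInputError("register operand needs a non-negative index")
        elif self.kind == CONSTANT:
            if self.constant_value is None:
                raise InvalidInputError("constant operand needs a value")
        else:
            raise InvalidInputError(f"unknown operand kind {self.kind!r}")


def reg(i: int) -> Operand:
    return Operand(REGISTER, register_index=i)


def const(v: int) -> Operand:
    return Operand(CONSTANT, constant_value=v)


@dataclass(frozen=True)
class Instruction:
    """One assignment or branch.

    ``destination``/``operator`` are set for assignments, ``comparison`` for
    branches; the other fields are ``None``.
    """

    kind: str
    operand_a: Operand
    operand_b: Operand
    destination: int | None = None
    operator: str | None = None
    comparison: str | None = None

    def __post_init__(self):
        if self.kind == ASSIGNMENT:
            if self.destination is None or self.operator not in OPERATORS:
                raise InvalidInputError("assignment needs destination and operator")
            if self.comparison is not None:
                raise InvalidInputError("assignment has no comparison")
        elif self.kind == BRANCH:
            if self.comparison not in COMPARISONS:
                raise InvalidInputError("branch needs a comparison")
            if self.destination is not None or self.operator is not None:
                raise InvalidInputError("branch has no destination/operator")
        else:
            raise InvalidInputError(f"unknown instruction kind {self.kind!r}")

    def register_operands(self) -> list[int]:
        return [
            op.register_index
            for op in (self.operand_a, self.operand_b)
            if op.kind == REGISTER
        ]


def assign(destination: int, operator: str, a: Operand, b: Operand) -> Instruction:
    return Instruction(ASSIGNMENT, a, b, destination=destination, operator=operator)


def branch(comparison: str, a: Operand, b: Operand) -> Instruction:
    return Instruction(BRANCH, a, b, comparison=comparison)


@dataclass(frozen=True)
class RegisterFile:
    """Register layout: calculation registers first, then input registers.

    ``r[0]`` is the output register. Input register ``r[n_calculation + j]``
    holds feature ``j``.
    """

    n_calculation: int
    n_input: int

    def __post_init__(self):
        if self.n_calculation < 1:
            raise InvalidInputError("need at least the output register r[0]")
        if self.n_input < 0:
            raise InvalidInputError("n_input must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_calculation + self.n_input

    def is_calculation(self, index: int) -> bool:
        return 0 <= index < self.n_calculation

    def is_input(self, index: int) -> bool:
        return self.n_calculation <= index < self.n_total

    def feature_of(self, index: int) -> int:
        if not self.is_input(index):
            raise InvalidInputError(f"r[{index}] is not an input register")
        return index - self.n_calculation


@dataclass
class Program:
    """An ordered instruction list bound to a register file."""

    instructions: list[Instruction]
    register_file: RegisterFile

    def __post_init__(self):
        self.validate()

    def __len__(self) -> int:
        return len(self.instructions)

    def validate(self) -> None:
        # evolution maintains length >= 1; an empty program (legal here) is
        # the fixed point of simplify() for pure-intron programs and outputs 0
        rf = self.register_file
        for i, ins in enumerate(self.instructions):
            if ins.kind == ASSIGNMENT and not rf.is_calculation(ins.destination):
                raise InvalidInputError(
                    f"instruction {i}: destination r[{ins.destination}] "
                    "is not a calculation register"
                )
            for r in ins.register_operands():
                if not (0 <= r < rf.n_total):
                    raise InvalidInputError(
                        f"instruction {i}: register r[{r}] out of range"
                    )

    def copy(self) -> "Program":
        # instructions are immutable, so a shallow list copy suffices
        return Program(list(self.instructions), self.register_file)


def apply_operator(operator: str, a: float, b: float) -> float:
    """Total, protected arithmetic.

    Division returns ``a`` when ``|b| <= 1e-9``; exponent computes
    ``|a| ** b`` with non-finite intermediates replaced by 1 and the result
    clamped into ``[-1e6, 1e6]``. Add/sub/mul are exact.
    """
    if operator == "add":
        return a + b
    if operator == "sub":
        return a - b
    if operator == "mul":
        return a * b
    if operator == "div":
        return a if abs(b) <= DIV_EPS else a / b
    if operator == "exponent":
        with np.errstate(all="ignore"):
            r = float(np.float_power(abs(a), b))
        if not np.isfinite(r):
            r = 1.0
        return float(np.clip(r, -EXP_CLAMP, EXP_CLAMP))
    raise InvalidInputError(f"unknown operator {operator!r}")


def _apply_vector(operator, a, b):
    """Vectorised protected arithmetic (same rules as :func:`apply_operator`)."""
    if operator == "add":
        return a + b
    if operator == "sub":
        return a - b
    if operator == "mul":
        return a * b
    if operator == "div":
        small = np.abs(b) <= DIV_EPS
        safe = np.where(small, 1.0, b)
        return np.where(small, a, a / safe)
    if operator == "exponent":
        r = np.float_power(np.abs(a), b)
        r = np.where(np.isfinite(r), r, 1.0)
        return np.clip(r, -EXP_CLAMP, EXP_CLAMP)
    raise InvalidInputError(f"unknown operator {operator!r}")


def execute_batch(program: Program, features: np.ndarray) -> np.ndarray:
    """Run ``program`` on every row of ``features`` at once.

    Parameters
    ----------
    features : array of shape (n_samples, n_input)

    Returns
    -------
    array of shape (n_samples,) — the final value of ``r[0]`` per sample.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != program.register_file.n_input:
        raise InvalidInputError(
            f"expected (n_samples, {program.register_file.n_input}) features, "
            f"got shape {X.shape}"
        )
    n = X.shape[0]
    n_calc = program.register_file.n_calculation
    calc = np.zeros((n_calc, n))  # calculation registers initialise to 0
    inputs = np.ascontiguousarray(X.T)

    def value(op: Operand):
        if op.kind == CONSTANT:
            return float(op.constant_value)
        i = op.register_index
        return calc[i] if i < n_calc else inputs[i - n_calc]

    guard = None  # accumulated condition mask of the pending branch chain
    with np.errstate(all="ignore"):
        for ins in program.instructions:
            a = value(ins.operand_a)
            b = value(ins.operand_b)
            if ins.kind == BRANCH:
                cond = np.less(a, b) if ins.comparison == "less_than" else np.greater(a, b)
                if np.ndim(cond) == 0:
                    cond = np.full(n, bool(cond))
                guard = cond if guard is None else guard & cond
            else:
                result = _apply_vector(ins.operator, a, b)
                d = ins.destination
                if guard is None:
                    calc[d] = result
                else:
                    calc[d] = np.where(guard, result, calc[d])
                    guard = None
    return calc[0].copy()


def execute(program: Program, features) -> float:
    """Run the program on a single feature vector; return the final ``r[0]``."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidInputError("features must be a 1-D vector")
    return float(execute_batch(program, x[None, :])[0])


def predict_proba_batch(program: Program, features: np.ndarray) -> np.ndarray:
    """Sigmoid-squashed program outputs, one probability per sample."""
    return expit(execute_batch(program, features))


def classify_batch(
    program: Program, features: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Hard 0/1 labels; probability ties at the threshold classify as 1."""
    return (predict_proba_batch(program, features) >= threshold).astype(np.int64)


def classify(program: Program, features, threshold: float = 0.5) -> int:
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidInputError("features must be a 1-D vector")
    return int(classify_batch(program, x[None, :], threshold)[0])


def _guard_targets(instructions: list[Instruction]) -> list[int | None]:
    """For each branch, the index of the instruction it guards (the first
    following non-branch), or ``None`` for a trailing branch chain."""
    targets: list[int | None] = [None] * len(instructions)
    nearest = None  # nearest non-branch at a higher index
    for i in range(len(instructions) - 1, -1, -1):
        if instructions[i].kind == BRANCH:
            targets[i] = nearest
        else:
            nearest = i
    return targets


def effective_instructions(program: Program) -> set[int]:
    """Indices of instructions that can influence the final ``r[0]``.

    Backward structural sweep over a needed-register set. A branch-guarded
    assignment may or may not execute, so it never removes its destination
    from the needed set — the prior value can still flow through.
    """
    ins = program.instructions
    targets = _guard_targets(ins)
    effective = [False] * len(ins)
    needed: set[int] = {0}
    for i in range(len(ins) - 1, -1, -1):
        inst = ins[i]
        if inst.kind == ASSIGNMENT:
            if inst.destination in needed:
                effective[i] = True
                guarded = i > 0 and ins[i - 1].kind == BRANCH
                if not guarded:
                    needed.discard(inst.destination)
                needed.update(inst.register_operands())
        else:
            t = targets[i]
            if t is not None and effective[t]:
                effective[i] = True
                needed.update(inst.register_operands())
    return {i for i, e in enumerate(effective) if e}


def effective_features(program: Program) -> set[int]:
    """Feature indices read by at least one effective instruction."""
    rf = program.register_file
    out: set[int] = set()
    for i in effective_instructions(program):
        for r in program.instructions[i].register_operands():
            if rf.is_input(r):
                out.add(rf.feature_of(r))
    return out


def simplify(program: Program) -> Program:
    """Intron-free form: the subsequence of effective instructions.

    Semantics-preserving: ``execute(simplify(p), x) == execute(p, x)`` for
    every ``x``. A program with no effective instructions collapses to the
    empty program, whose output is the register initial value 0.
    """
    keep = sorted(effective_instructions(program))
    return Program(
        [program.instructions[i] for i in keep], program.register_file
    )


def _format_operand(op: Operand) -> str:
    if op.kind == CONSTANT:
        return str(op.constant_value)
    return f"r[{op.register_index}]"


def render(program: Program, feature_names: list[str] | None = None) -> str:
    """One instruction per line, Fig-style dialect: ``r[1] = r[8] - 4`` /
    ``if r[6] < r[10]:``. With ``feature_names``, input-register reads are
    annotated in a trailing comment that the parser ignores."""
    rf = program.register_file
    if feature_names is not None and len(feature_names) != rf.n_input:
        raise InvalidInputError("feature_names length must equal n_input")
    lines = []
    for ins in program.instructions:
        a = _format_operand(ins.operand_a)
        b = _format_operand(ins.operand_b)
        if ins.kind == ASSIGNMENT:
            line = f"r[{ins.destination}] = {a} {OPERATOR_SYMBOLS[ins.operator]} {b}"
        else:
            line = f"if {a} {COMPARISON_SYMBOLS[ins.comparison]} {b}:"
        if feature_names is not None:
            notes = [
                f"r[{r}]={feature_names[rf.feature_of(r)]}"
                for r in dict.fromkeys(ins.register_operands())
                if rf.is_input(r)
            ]
            if notes:
                line += "  # " + ", ".join(notes)
        lines.append(line)
    return "\n".join(lines)


_OPERAND_RE = r"(r\[\d+\]|-?\d+)"
_ASSIGN_RE = re.compile(
    rf"^r\[(\d+)\]\s*=\s*{_OPERAND_RE}\s*([+\-*/^])\s*{_OPERAND_RE}$"
)
_BRANCH_RE = re.compile(rf"^if\s+{_OPERAND_RE}\s*([<>])\s*{_OPERAND_RE}\s*:$")


def _parse_operand(text: str) -> Operand:
    if text.startswith("r["):
        return reg(int(text[2:-1]))
    return const(int(text))


def parse_program(text: str, register_file: RegisterFile) -> Program:
    """Read a program back from the :func:`render` dialect."""
    instructions = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _ASSIGN_RE.match(line)
        if m:
            d, a, sym, b = m.groups()
            instructions.append(
                assign(int(d), _SYMBOL_OPERATORS[sym], _parse_operand(a), _parse_operand(b))
            )
            continue
        m = _BRANCH_RE.match(line)
        if m:
            a, sym, b = m.groups()
            instructions.append(
                branch(_SYMBOL_COMPARISONS[sym], _parse_operand(a), _parse_operand(b))
            )
            continue
        raise FormatError(f"line {lineno}: cannot parse {raw!r}")
    return Program(instructions, register_file)


def write_program(program: Program, path, feature_names=None) -> None:
    with open(path, "w") as fh:
        fh.write(render(program, feature_names) + "\n")


def read_program(path, register_file: RegisterFile) -> Program:
    with open(path) as fh:
        return parse_program(fh.read(), register_file)
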