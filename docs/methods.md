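# Methods

## The program model

A classifier genotype is a sequence of 1–300 register-machine instructions.
The register file lays calculation registers first (`r[0]`, the output,
plus by default five scratch registers `r[1]`–`r[5]`) and then one
read-only input register per feature. Two instruction forms exist:

- assignment `r[d] = a op b`, `op ∈ {+, -, *, /, ^}`, destination restricted
  to calculation registers;
- branch `if a < b:` / `if a > b:`, guarding the next non-branch
  instruction. Consecutive branches accumulate: the guarded assignment
  executes only when every condition in the chain holds. A false chain
  skips the remaining branches of the chain and the guarded assignment; a
  trailing branch guards nothing.

Operands are registers or integer constants drawn from 1–10. Classification
projects the final `r[0]` through a logistic sigmoid; probability ≥ 0.5
(i.e. `r[0] ≥ 0`) is class 1, so an untouched output register is a
class-1 tie by construction.

Numerical choices:

- **Register initialisation.** All calculation registers start at 0 for
  every execution. Zero sits exactly on the sigmoid decision boundary, is
  reproducible, and makes "program never writes `r[0]`" a well-defined
  degenerate case.
- **Protected arithmetic.** Division returns the numerator when
  `|b| ≤ 1e-9`; exponentiation computes `|a| ** b`, replaces non-finite
  intermediates by 1, and clamps into `[-1e6, 1e6]`. Add/sub/mul are left
  exact. Execution is therefore total: no operand values raise.
- **Branch comparison** uses the raw operand values (no absolute value).
- Both-constant operands are legal anywhere; they constant-fold at
  execution and evolution occasionally produces them.

## Effective code (intron) analysis

An instruction is *effective* when its result can flow into the final
`r[0]`. Detection is the standard backward sweep over a needed-register
set: walking last-to-first, an assignment is effective iff its destination
is currently needed; it then adds its register operands to the set and —
only when it executes unconditionally — removes its destination. A
branch-guarded assignment may be skipped at run time, so its destination
stays needed (the prior value can still flow through); dropping that
exception would mark semantically live writes as dead. A branch is
effective iff the assignment it guards is, and then contributes its own
register operands. `simplify()` keeps the effective subsequence in order;
this is exactly semantics-preserving, which the test suite checks
bit-for-bit against re-execution on random programs. Structural
effectiveness is an over-approximation of semantic necessity: an effective
instruction may still be numerically neutral (e.g. multiplying by an
expression that happens to equal 1); only the preservation direction is
asserted.

Effective *features* — input registers read by at least one effective
instruction — are the unit of all ensemble statistics. Programs whose
effective set is empty simplify to the empty program (output 0).

## Evolutionary search

Defaults (changeable per YAML config / keyword): population 800, 240
generations, tournament size 8, crossover 0.75, macro-mutation 0.75,
micro-mutation 0.5, initial length uniform on [10, 40], cap 300,
constants 1–10, six calculation registers, bootstrap fraction uniform on
[0.5, 1.0]. One steady-state *tournament event* draws eight distinct
contestants, copies the two fittest, recombines and mutates the copies,
evaluates each once on a fresh bootstrap subsample, and writes them over
the two worst of the *remaining* contestants (never the winners, so parents
survive fitness ties). `tournaments_per_generation` (default 1, the literal
reading of "generation") decouples the generation count from the event
count; the scaled-down experiments below set the event count explicitly,
so nothing depends on this reading.

Design points worth knowing:

- **Noisy fitness is cached.** A model keeps the fitness measured at its
  creation; it is not re-evaluated when later tournaments sample it. This
  matches evaluating offspring at replacement time and keeps the evaluation
  budget proportional to offspring count, at the cost of occasionally
  promoting models that were lucky on one subsample.
- **Crossover** picks an independent contiguous (possibly empty) segment in
  each parent and swaps them; cut pairs breaching the length bounds are
  re-drawn up to 10 times, then the parents pass through unchanged. Total
  instruction count is conserved.
- **Fitness evaluation executes the intron-free form** of the candidate;
  this is semantics-preserving (above) and typically an order of magnitude
  cheaper than executing the raw program.
- **Operand sampling.** A freshly generated operand is a constant with
  probability 0.25, otherwise a uniformly chosen register. Assignments and
  branches are equally likely at initialisation and insertion.
- **Seeding.** Run *i* of an experiment uses seed `base_seed + i` for its
  split and its generator, making collections reproducible model-by-model
  and invariant to the worker count of a parallel batch.

Each run makes a fresh stratified 80/20 split. Stratification is a
deliberate stabilisation for small cohorts (115 samples split 92/23); a
non-stratified split would make tiny test sets occasionally one-sided.

## Data handling

Input is a CSV whose header names the features and whose `category` column
holds a two-level label; the sorted levels map to 0/1 and the mapping is
recorded. Features are min–max scaled per column onto [−1, 1]
(`x' = 2(x−min)/(max−min) − 1`; constant columns map to 0 with a warning).
By default the scaler is fit on the full table *before* splitting —
matching the normalise-then-learn protocol this pipeline reproduces — and a
`fit_indices` argument provides the leakage-safe train-only alternative.
Model archives are versioned JSON (program in the text dialect, config,
seed, split indices, metrics), portable and diff-able where a pickle would
not be; re-executing an archived program on its stored test indices
reproduces its stored test accuracy exactly.

## Metrics

Accuracy, precision/recall/F1 (class 1 — the disease class under the
default label mapping — is positive; configurable at the confusion-count
level) and trapezoidal ROC-AUC over sigmoid probabilities. AUC is checked
in the tests against brute-force concordant-pair counting (ties ½) to
1e-12. F1 returns 0 when precision and recall are both 0.

## Ensemble mining

Occurrence counts use set semantics (a feature counts once per model);
ranking is by count, ties alphabetical. Co-occurrence stores raw model
counts (frequencies follow by dividing by the collection size). The synergy
network keeps the top `p`% (default 3%) of *nonzero* pairs — zero-count
pairs are not "common pairs" — with an inclusive cutoff: every pair tying
the rank-⌈p/100·N⌉ count is kept, which makes the edge set deterministic
and order-free, and makes smaller percentages yield subsets of larger ones.
Model filtering (test accuracy strictly greater than a threshold, optional
exact effective-feature count) mirrors the interactive workflow it
replaces. The Pearson screen over the raw table follows the signed
convention `r > 0.8` (an `absolute=True` switch exists), raw p-values with
no multiplicity correction by default and an optional Benjamini–Hochberg
flag.

## Synthetic data

The generator emulates the *shape* of a plasma-metabolomics case/control
table (default 170 × 240, balanced classes): i.i.d. Gaussian backgrounds, a
log-normal option aside, because downstream everything is min–max
normalised — only the ordering/threshold structure of a feature matters to
the register machine, not its marginal shape. What it does **not** emulate:
inter-metabolite correlation blocks (real pathway co-membership), missing
values, batch effects, or instrument error models. Passing recovery tests
therefore show that the pipeline finds the kinds of signal planted —
additive pair thresholds (`label = [Σ effects·x > 0]`, the structure the
compact evolved models exhibit) and XOR-style pure interactions (exactly
one of a pair above its median; marginal correlations ≈ 0) — not that it
handles correlated real-world noise.

Labels come from the planted rule, then flip independently with the
label-noise probability; datasets violating the class-balance target by
more than 0.1 are redrawn (bounded retries). The ground-truth sidecar
records the planted indices, the pre-noise labels, and each planted
feature's marginal point-biserial correlation.

## Scaled-down experiment sizes

Full-scale usage (hundreds of runs at population 800 × 240+ generations) is
a cluster workload. The in-repo experiments use sizes chosen so the whole
suite runs on one CPU in a couple of minutes while preserving the
phenomena: recovery experiments use 200 samples × 50 features, 30 runs at
population 200 / 600 tournament events, five repetitions; convergence
checks use one-feature separable data at population 100 / 200 events.

## Known limitations

- **Pure interactions are beyond the scaled-down search budget.** An
  XOR-planted pair gives every single-feature intermediate program zero
  fitness gradient; assembling the required multi-instruction construct
  (a signed product, or a branch-pair quadrant test — a hand-built
  7-instruction version scores 0.82 training accuracy) by unbiased
  variation is a rare event at 1,200 offspring evaluations, and bootstrap
  fitness noise (~0.70 best fitness on signal-free data of the same shape)
  hides partial progress. In our experiments the planted XOR pair does not
  reach the top co-occurrence rank at this scale; detecting pure epistasis
  this way should be expected to require search budgets orders of magnitude
  larger, as in full-scale use.
- Best-of-run selection maximises *bootstrap* fitness, which is an upward-
  biased, noisy estimate; the saved model is not always the best
  generaliser of its run.
- Structural intron analysis does not detect semantic introns.
- Binary classification only; no multi-class or regression mode.
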