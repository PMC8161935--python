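# lgpmine

Interpretable classification of metabolomics tables by **linear genetic
programming (LGP)**, plus ensemble mining of many independently evolved
models for influential metabolites and synergistic metabolite pairs.

`lgpmine` is aimed at metabolomics studies of the usual case/control shape —
one or two hundred plasma samples, a few hundred quantified metabolite
concentrations, a binary phenotype (e.g. Alzheimer's disease vs healthy
controls). Instead of fitting one black-box model, it evolves a *population*
of tiny register-machine programs, keeps the best program of each run, and
repeats the whole search many times under independent seeds. Because each
evolved program is a handful of readable instructions, the models themselves
are the explanation; because feature selection is implicit in evolution, the
*frequency* with which a metabolite appears across hundreds of best-of-run
models measures its importance, and the frequency with which two metabolites
appear together in the same model flags candidate synergistic (epistatic)
interactions.

## The model

A candidate classifier is an imperative program over a register file: input
registers hold the (min–max normalised, $[-1,1]$) metabolite concentrations
of one sample; calculation registers $r[0],\dots$ are writable scratch space
initialised to 0. Instructions are either assignments

```
r[1] = r[8] - 4
```

(destination always a calculation register, so features are never
overwritten; operators $+,-,\times,\div,\hat{\ }$ with protected division
and exponent) or conditional branches `if r[6] < r[10]:` that guard the next
assignment — a chain of branches guards one assignment and all conditions
must hold. After sequential execution, the final value of the output
register $r[0]$ is squashed through a sigmoid,
$p = 1/(1+e^{-r[0]})$, and $p \ge 0.5$ calls the sample diseased.

Search is a steady-state evolutionary algorithm: size-8 tournaments pick two
winners whose copies undergo two-point crossover (p = 0.75), instruction
insertion/deletion (macro-mutation, p = 0.75) and single-component change
(micro-mutation, p = 0.5), and the offspring displace the tournament's two
worst members. Fitness is classification accuracy on a fresh 50–100%
bootstrap subsample of the training set (without replacement), a noise
injection that discourages overfitting. Each run uses its own stratified
80/20 train/test split and reports held-out accuracy, F1 and AUC.

Instructions whose result cannot reach $r[0]$ are *structural introns*;
`lgpmine` detects them by a backward register-flow sweep, and the intron-free
("effective") program is what gets reported and mined. A metabolite is an
**effective feature** of a model when some effective instruction reads its
register. Across a collection of N runs:

- **occurrence frequency** of a feature = fraction of models whose effective
  feature set contains it (importance ranking);
- **co-occurrence count** of a pair = number of models containing both
  (synergy evidence); the top 3% of nonzero pairs form the synergy network.

## Worked example

Generate a synthetic 200-sample × 50-metabolite table whose label is
`[x3 + x7 > 0]` with 5% label noise, evolve 30 independent models, and mine
the collection:

```bash
lgpmine simulate --n-samples 200 --n-features 50 \
    --pair "3,7:additive_threshold:1.0" --label-noise 0.05 \
    --seed 1 --out ad_like.csv
printf 'population_size: 200\nn_generations: 600\n' > config.yaml
lgpmine batch --data ad_like.csv --config config.yaml \
    --n-runs 30 --base-seed 0 --out-dir runs
lgpmine analyze --runs runs --top-percent 3 --feature met_003 --out-dir analysis
```

`analysis/occurrence.csv` then begins

```
feature,count,frequency
met_003,23,0.7666666666666667
met_007,13,0.43333333333333335
met_018,5,0.16666666666666666
```

i.e. the two planted metabolites are the top-ranked features — `met_003`
appears in 77% of the 30 best-of-run models, `met_007` in 43%, all
bystanders at or below 17%. The strongest co-occurring pair
(`analysis/cooccurrence_long.csv`, and the heaviest edge of
`analysis/network.graphml`) is the planted pair:

```
feature_a,feature_b,count
met_003,met_007,6
```

`analysis/feature_report.json` holds the single-feature view (occurrence
count 23, partners ranked by co-occurrence, one-hop sub-network as GraphML),
and `analysis/metrics_summary.csv` the per-model test accuracy / F1 / AUC /
effective-feature counts. Every archive under `runs/` is a versioned JSON
document containing the program text, so you can read the winning model
directly, e.g. `r[1] = r[9] + r[13]`, `r[0] = r[1] - 1` — "call the sample
diseased when the two concentrations sum past a constant".

The same workflow applies to a real table: any CSV whose header names the
metabolites and whose `category` column holds a two-level label
(`lgpmine check-format your.csv` validates the dialect).

## Layout

- `src/lgpmine/program.py` — register machine: execution, protected
  operators, intron detection, text dialect
- `src/lgpmine/evolution.py` — steady-state search, runs and collections
- `src/lgpmine/metrics.py` — accuracy / F1 / ROC-AUC
- `src/lgpmine/analysis.py` — occurrence, co-occurrence, synergy network,
  neighbour reports, Pearson correlation screen
- `src/lgpmine/dataio.py` — CSV dialect, normalization, splits, JSON archives
- `src/lgpmine/synthetic.py` — planted-signal generators and fixture programs
- `src/lgpmine/cli.py` — `simulate` / `run` / `batch` / `analyze` /
  `check-format`

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
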