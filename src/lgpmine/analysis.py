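"""Mining a collection of independently evolved models.

A feature that keeps reappearing in the effective code of best-of-run
models is likely influential; a *pair* of features that keeps appearing
together in the same model suggests a synergistic (epistatic) interaction.
This module ranks features by occurrence frequency, counts pairwise
co-occurrence, thresholds the strongest pairs into a synergy network, and
offers a per-feature neighbourhood report plus a plain Pearson correlation
screen of the raw concentration table.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from math import ceil

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .evolution import RunCollection
from .exceptions import FeatureNotFoundError, InvalidInputError


@dataclass
class OccurrenceTable:
    """Per-feature model counts and frequencies, sorted by count descending
    (ties by name)."""

    table: pd.DataFrame  # index: feature name; columns: count, frequency
    n_models: int

    def count(self, feature: str) -> int:
        return int(self.table["count"].get(feature, 0))

    def frequency(self, feature: str) -> float:
        return float(self.table["frequency"].get(feature, 0.0))

    def top(self, k: int) -> list[str]:
        return list(self.table.index[:k])


@dataclass
class CooccurrenceMatrix:
    """Symmetric pair counts of effective-feature co-membership."""

    counts: dict[tuple[str, str], int]  # keys are sorted name pairs, count > 0
    feature_names: list[str]
    n_models: int

    def get(self, a: str, b: str) -> int:
        return self.counts.get(tuple(sorted((a, b))), 0)

    def nonzero_pairs(self) -> list[tuple[tuple[str, str], int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def max_pair(self) -> tuple[tuple[str, str], int]:
        pairs = self.nonzero_pairs()
        if not pairs:
            raise InvalidInputError("all pair counts are zero")
        return pairs[0]

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"feature_a": a, "feature_b": b, "count": c}
            for (a, b), c in self.nonzero_pairs()
        ]
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "count"])

    def to_wide_frame(self) -> pd.DataFrame:
        names = self.feature_names
        wide = pd.DataFrame(0, index=names, columns=names, dtype=int)
        for (a, b), c in self.counts.items():
            wide.at[a, b] = c
            wide.at[b, a] = c
        return wide


def filter_models(
    collection: RunCollection,
    min_test_accuracy: float = 0.0,
    n_effective_features: int | None = None,
) -> RunCollection:
    """Keep models with test accuracy strictly above the threshold and,
    when requested, exactly the given effective-feature count."""
    kept = [
        m
        for m in collection.models
        if m.test_accuracy is not None
        and m.test_accuracy > min_test_accuracy
        and (
            n_effective_features is None
            or m.n_effective_features == n_effective_features
        )
    ]
    return replace(collection, models=kept)


def occurrence_ranking(collection: RunCollection) -> OccurrenceTable:
    """Count, per feature, the models whose effective set contains it."""
    if collection.n_runs == 0:
        raise InvalidInputError("empty collection")
    counts: dict[str, int] = {}
    for m in collection.models:
        for name in m.effective_feature_names:
            counts[name] = counts.get(name, 0) + 1
    n = collection.n_runs
    frame = pd.DataFrame(
        {"count": pd.Series(counts, dtype=int)}
    ).sort_index()
    frame["frequency"] = frame["count"] / n
    frame = frame.sort_values(["count"], ascending=False, kind="stable")
    return OccurrenceTable(table=frame, n_models=n)


def cooccurrence(collection: RunCollection) -> CooccurrenceMatrix:
    """For every unordered feature pair, the number of models whose
    effective set contains both (set semantics: once per model)."""
    if collection.n_runs == 0:
        raise InvalidInputError("empty collection")
    counts: dict[tuple[str, str], int] = {}
    for m in collection.models:
        for a, b in combinations(sorted(m.effective_feature_names), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return CooccurrenceMatrix(
        counts=counts,
        feature_names=list(collection.feature_names),
        n_models=collection.n_runs,
    )


def build_network(
    matrix: CooccurrenceMatrix,
    occurrence: OccurrenceTable,
    top_percent: float = 3.0,
) -> nx.Graph:
    """Synergy network of the top ``top_percent``% most common pairs.

    Nonzero pairs are ranked by count; the cutoff is the count at rank
    ``ceil(top_percent/100 * n_nonzero)`` and every pair tying the cutoff
    is kept. Nodes carry their occurrence count/frequency, edges their
    co-occurrence count as ``weight``.
    """
    if not 0 < top_percent <= 100:
        raise InvalidInputError("top_percent must lie in (0, 100]")
    graph = nx.Graph(top_percent=float(top_percent))
    pairs = matrix.nonzero_pairs()
    if not pairs:
        warnings.warn("all co-occurrence counts are zero; empty network", stacklevel=2)
        graph.graph["cutoff"] = None
        return graph
    k = max(1, ceil(top_percent / 100.0 * len(pairs)))
    k = min(k, len(pairs))
    cutoff = pairs[k - 1][1]
    graph.graph["cutoff"] = int(cutoff)
    for (a, b), c in pairs:
        if c < cutoff:
            break
        graph.add_edge(a, b, weight=int(c))
    for node in graph.nodes:
        graph.nodes[node]["count"] = occurrence.count(node)
        graph.nodes[node]["frequency"] = occurrence.frequency(node)
    return graph


@dataclass
class NeighborReport:
    """One feature's occurrence plus its co-occurring partners."""

    feature: str
    occurrence_count: int
    occurrence_frequency: float
    neighbors: list[tuple[str, int]]  # sorted by count desc, ties by name
    subnetwork: nx.Graph  # induced one-hop co-occurrence sub-network

    @property
    def mean_edge_weight(self) -> float:
        if not self.neighbors:
            return 0.0
        return float(np.mean([c for _, c in self.neighbors]))


def feature_neighbors(
    matrix: CooccurrenceMatrix,
    occurrence: OccurrenceTable,
    feature_name: str,
) -> NeighborReport:
    """Rank a feature's interaction partners by co-occurrence count."""
    universe = set(matrix.feature_names) | set(occurrence.table.index)
    if feature_name not in universe:
        candidates = difflib.get_close_matches(feature_name, sorted(universe), n=5)
        raise FeatureNotFoundError(feature_name, candidates)
    neighbors = sorted(
        (
            (b if a == feature_name else a, c)
            for (a, b), c in matrix.counts.items()
            if feature_name in (a, b)
        ),
        key=lambda nc: (-nc[1], nc[0]),
    )
    members = {feature_name, *(n for n, _ in neighbors)}
    sub = nx.Graph()
    sub.add_node(feature_name)
    for (a, b), c in matrix.counts.items():
        if a in members and b in members:
            sub.add_edge(a, b, weight=int(c))
    for node in sub.nodes:
        sub.nodes[node]["count"] = occurrence.count(node)
        sub.nodes[node]["frequency"] = occurrence.frequency(node)
    return NeighborReport(
        feature=feature_name,
        occurrence_count=occurrence.count(feature_name),
        occurrence_frequency=occurrence.frequency(feature_name),
        neighbors=neighbors,
        subnetwork=sub,
    )


def correlation_screen(
    dataset,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
    absolute: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson-correlated feature pairs in the raw concentration table.

    Keeps pairs with (signed, by default) ``r > r_threshold`` and
    ``p < p_threshold``; ``absolute=True`` switches to ``|r|``. Constant
    features are skipped with a warning. ``fdr=True`` applies
    Benjamini-Hochberg to the p-values before thresholding (off by
    default). Returns a frame sorted by r descending.
    """
    X = dataset.features
    n = X.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 samples")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        skipped = [dataset.feature_names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"constant features skipped: {skipped}", stacklevel=2)
    names = [dataset.feature_names[i] for i in np.flatnonzero(keep)]
    R = np.corrcoef(X[:, keep], rowvar=False)
    iu, ju = np.triu_indices(len(names), k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    # two-sided p-value via the exact beta distribution of r under the null
    p = 2 * stats.beta(n / 2 - 1, n / 2 - 1, loc=-1, scale=2).sf(np.abs(r))
    if fdr:
        p = _benjamini_hochberg(p)
    stat = np.abs(r) if absolute else r
    mask = (stat > r_threshold) & (p < p_threshold)
    frame = pd.DataFrame(
        {
            "feature_a": [names[i] for i in iu[mask]],
            "feature_b": [names[j] for j in ju[mask]],
            "r": r[mask],
            "p": p[mask],
        }
    )
    return frame.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adjusted, 1.0)


def scatter_data(dataset, feature_a: str, feature_b: str) -> pd.DataFrame:
    """Per-sample values of two features plus the class label, for
    two-feature scatter plots."""
    for name in (feature_a, feature_b):
        if name not in dataset.feature_names:
            candidates = difflib.get_close_matches(name, dataset.feature_names, n=5)
            raise FeatureNotFoundError(name, candidates)
    ia = dataset.feature_names.index(feature_a)
    ib = dataset.feature_names.index(feature_b)
    return pd.DataFrame(
        {
            feature_a: dataset.features[:, ia],
            feature_b: dataset.features[:, ib],
            "label": dataset.labels,
        }
    )


def metrics_summary(collection: RunCollection) -> pd.DataFrame:
    """Per-model metric table (one row per run) for distribution summaries."""
    rows = [
        {
            "model_id": i,
            "run_seed": m.run_seed,
            "train_acc": m.fitness,
            "test_acc": m.test_accuracy,
            "f1": m.f1,
            "auc": m.auc,
            "n_effective_features": m.n_effective_features,
        }
        for i, m in enumerate(collection.models)
    ]
    return pd.DataFrame(rows)
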