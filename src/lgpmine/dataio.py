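"""Dataset ingestion, min-max normalization, stratified splitting, and
model-archive serialization.

The on-disk dataset dialect is a plain CSV whose header names the features
(metabolites); each row is one sample and a column named exactly
``category`` carries the binary class label. Model archives are versioned
JSON documents (portable across languages, unlike pickles).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .exceptions import ConfigurationError, FormatError, SchemaVersionError
from .program import RegisterFile, parse_program, render

LABEL_FIELD = "category"
ARCHIVE_SCHEMA_VERSION = 1


@dataclass
class Dataset:
    """A sample-by-feature concentration table with binary labels."""

    features: np.ndarray  # (n_samples, n_features) float64
    labels: np.ndarray  # (n_samples,) int, values in {0, 1}
    feature_names: list[str]
    sample_ids: list[str]
    normalized: bool = False
    label_mapping: dict = field(default_factory=dict)  # original value -> 0/1
    norm_min: np.ndarray | None = None  # per-feature min/max used to normalise
    norm_max: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise FormatError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise FormatError("features and labels disagree on sample count")
        if self.features.shape[1] != len(self.feature_names):
            raise FormatError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FormatError("duplicate feature names")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise FormatError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def fingerprint(self) -> str:
        """Stable content hash of values, labels and names."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.features).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update("\x1f".join(self.feature_names).encode())
        return h.hexdigest()[:16]

    def subset(self, indices) -> "Dataset":
        idx = np.asarray(indices)
        return replace(
            self,
            features=self.features[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def check_format(path) -> list[str]:
    """Return a list of human-readable format problems (empty when clean)."""
    problems: list[str] = []
    try:
        with open(path) as fh:
            header_line = fh.readline()
    except OSError as exc:
        return [f"cannot read file: {exc}"]
    header = [h.strip() for h in header_line.rstrip("\n").split(",")]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        problems.append(f"duplicate feature names in header: {sorted(dupes)}")
    if LABEL_FIELD not in header:
        msg = f'missing required label field "{LABEL_FIELD}" in the header'
        try:
            first_cells = pd.read_csv(path, header=None, nrows=2).iloc[:, 0]
            if LABEL_FIELD in {str(v).strip() for v in first_cells}:
                msg += " (found it in the first column: is the file transposed?)"
        except Exception:
            pass
        problems.append(msg)
        return problems
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        return problems + [f"CSV parse failure: {exc}"]
    for col in frame.columns:
        if col == LABEL_FIELD:
            n_levels = frame[col].nunique(dropna=True)
            if n_levels != 2:
                problems.append(
                    f'"{LABEL_FIELD}" has {n_levels} distinct values; expected 2'
                )
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna()
        for row in frame.index[bad]:
            problems.append(
                f"non-numeric value {frame.at[row, col]!r} at row {row}, "
                f"column {col!r}"
            )
    return problems


def read_dataset(path) -> Dataset:
    """Load the CSV dialect; labels are mapped onto {0, 1} with the mapping
    recorded (two sorted distinct values map in order)."""
    problems = check_format(path)
    if problems:
        raise FormatError("; ".join(problems))
    frame = pd.read_csv(path)
    labels_raw = frame[LABEL_FIELD]
    feature_frame = frame.drop(columns=[LABEL_FIELD]).apply(
        pd.to_numeric, errors="raise"
    )
    levels = sorted(labels_raw.unique(), key=str)
    if set(levels) == {0, 1}:
        levels = [0, 1]
    mapping = {levels[0]: 0, levels[1]: 1}
    return Dataset(
        features=feature_frame.to_numpy(dtype=np.float64),
        labels=labels_raw.map(mapping).to_numpy(),
        feature_names=[str(c) for c in feature_frame.columns],
        sample_ids=[str(i) for i in frame.index],
        label_mapping={str(k): v for k, v in mapping.items()},
    )


def write_dataset(dataset: Dataset, path) -> None:
    frame = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    inverse = {v: k for k, v in dataset.label_mapping.items()} or {0: 0, 1: 1}
    frame.insert(0, LABEL_FIELD, [inverse[l] for l in dataset.labels])
    frame.to_csv(path, index=False)


def normalize(dataset: Dataset, fit_indices=None) -> Dataset:
    """Min-max scale each feature onto [-1, 1]: ``x' = 2 (x-min)/(max-min) - 1``.

    Constant features map to 0 (with a warning). By default min/max are fit
    on the full dataset, mirroring the normalise-then-split protocol; pass
    ``fit_indices`` (e.g. the training rows) for the leakage-safe variant.
    """
    X = dataset.features
    fit = X if fit_indices is None else X[np.asarray(fit_indices)]
    lo = fit.min(axis=0)
    hi = fit.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        names = [dataset.feature_names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant features mapped to 0: {names}", stacklevel=2)
    safe_span = np.where(constant, 1.0, span)
    scaled = 2.0 * (X - lo) / safe_span - 1.0
    scaled[:, constant] = 0.0
    return replace(
        dataset, features=scaled, normalized=True, norm_min=lo, norm_max=hi
    )


def denormalize(dataset: Dataset) -> Dataset:
    """Invert :func:`normalize` using the stored per-feature min/max."""
    if not dataset.normalized or dataset.norm_min is None:
        raise ConfigurationError("dataset carries no normalization parameters")
    lo, hi = dataset.norm_min, dataset.norm_max
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    X = (dataset.features + 1.0) / 2.0 * span + lo
    X[:, hi - lo == 0] = lo[hi - lo == 0]
    return replace(dataset, features=X, normalized=False, norm_min=None, norm_max=None)


def split(dataset: Dataset, test_fraction: float = 0.2, seed: int = 0):
    """Stratified train/test split; returns (train, test, index record)."""
    if not 0 < test_fraction < 1:
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() < 2:
        raise ConfigurationError(
            "both classes need at least 2 samples for a stratified split"
        )
    idx = np.arange(dataset.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=dataset.labels,
        random_state=int(seed) % (2**32 - 1),
        shuffle=True,
    )
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    record = {
        "train_indices": train_idx.tolist(),
        "test_indices": test_idx.tolist(),
        "seed": int(seed),
        "test_fraction": float(test_fraction),
    }
    return dataset.subset(train_idx), dataset.subset(test_idx), record


def save_model(model, path) -> dict:
    """Serialise an EvolvedModel to a versioned JSON archive; returns the
    document that was written."""
    from .evolution import EvolvedModel  # local import avoids a cycle

    assert isinstance(model, EvolvedModel)
    rf = model.program.register_file
    doc = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "program_text": render(model.program),
        "n_calculation_registers": rf.n_calculation,
        "n_input_registers": rf.n_input,
        "feature_names": model.feature_names,
        "effective_feature_names": sorted(model.effective_feature_names),
        "fitness": model.fitness,
        "test_accuracy": model.test_accuracy,
        "f1": model.f1,
        "auc": model.auc,
        "run_seed": model.run_seed,
        "config": model.config.to_dict() if model.config is not None else None,
        "split": model.split_record,
        "dataset_fingerprint": model.dataset_fingerprint,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return doc


def load_model(path):
    """Load an EvolvedModel archive written by :func:`save_model`."""
    from .evolution import EvolutionConfig, EvolvedModel

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupted archive {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != ARCHIVE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"archive {path} has schema version {version!r}; "
            f"this reader supports {ARCHIVE_SCHEMA_VERSION}"
        )
    rf = RegisterFile(doc["n_calculation_registers"], doc["n_input_registers"])
    program = parse_program(doc["program_text"], rf)
    config = (
        EvolutionConfig.from_dict(doc["config"]) if doc.get("config") else None
    )
    return EvolvedModel(
        program=program,
        fitness=doc["fitness"],
        feature_names=doc["feature_names"],
        effective_feature_names=set(doc["effective_feature_names"]),
        test_accuracy=doc["test_accuracy"],
        f1=doc["f1"],
        auc=doc["auc"],
        run_seed=doc["run_seed"],
        config=config,
        split_record=doc.get("split"),
        dataset_fingerprint=doc.get("dataset_fingerprint"),
    )
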