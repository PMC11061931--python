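"""Sequence classifiers over embedding windows.

An :class:`ArchitectureSpec` declares a stack drawn from the explored
layer set (LSTM, BiLSTM, GRU, SimpleRNN, Conv1D, MaxPool, Dropout); the
classifier head is always a single sigmoid unit, and a recurrent layer
feeding the head returns only its last state.  :class:`SequenceClassifier`
wraps construction + training behind the scikit-learn estimator API, and
:func:`cross_validate` / :func:`grid_search` reproduce the stratified
5-fold protocol with early stopping (patience 10, max 100 epochs).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import nn
from .dataset import (
    DatasetSplit,
    TrainingInstance,
    instances_to_arrays,
    stratified_kfold,
    truncate_windows,
)

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainingConfig",
    "FoldResult",
    "SequenceClassifier",
    "build_classifier",
    "train_classifier",
    "evaluate_accuracy",
    "cross_validate",
    "grid_search",
    "predict_repurposing",
    "save_model",
    "load_model",
    "read_grid_file",
    "TOP_SEMREP_ARCHITECTURE",
]

_RECURRENT_KINDS = {"LSTM", "BiLSTM", "GRU", "SimpleRNN"}
_KINDS = _RECURRENT_KINDS | {"Conv1D", "MaxPool", "Dropout"}
_KIND_ALIASES = {k.lower(): k for k in _KINDS}


@dataclasses.dataclass(frozen=True)
class LayerSpec:
    """One layer of a declarative architecture."""

    kind: str
    size: int | None = None  # units / filters / pool width
    rate: float | None = None  # dropout only
    kernel: int | None = None  # Conv1D only (default 3)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; expected one of {sorted(_KINDS)}")
        if self.kind == "Dropout":
            if self.rate is None or not (0.0 < self.rate < 1.0):
                raise ValueError("Dropout needs a rate in (0, 1)")
        elif self.size is None or self.size < 1:
            raise ValueError(f"{self.kind} needs a positive size")

    def describe(self) -> str:
        if self.kind == "Dropout":
            return f"Dropout {self.rate}"
        if self.kind == "Conv1D" and self.kernel not in (None, 3):
            return f"Conv1D {self.size} (k{self.kernel})"
        return f"{self.kind} {self.size}"


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer stack plus batch size and window length."""

    layers: tuple[LayerSpec, ...]
    batch_size: int = 64
    window_length: int = 20

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.window_length < 1:
            raise ValueError("batch_size and window_length must be >= 1")
        prev_kind = None
        for spec in self.layers:
            if spec.kind == "MaxPool" and prev_kind != "Conv1D":
                raise ValueError("a pooling layer must directly follow a Conv1D layer")
            prev_kind = spec.kind

    @staticmethod
    def parse(text: str, batch_size: int = 64, window_length: int = 20) -> "ArchitectureSpec":
        """Parse ``"conv1d:32,maxpool:2,dropout:0.2,bilstm:32,dropout:0.2"``.

        Each comma-separated token is ``kind:arg`` with an optional
        ``:kN`` kernel width for Conv1D.
        """
        layers = []
        for token in text.split(","):
            parts = [p.strip() for p in token.strip().split(":")]
            kind = _KIND_ALIASES.get(parts[0].lower())
            if kind is None:
                raise ValueError(f"unknown layer kind {parts[0]!r} in {token!r}")
            if kind == "Dropout":
                layers.append(LayerSpec(kind, rate=float(parts[1])))
            elif kind == "Conv1D":
                kernel = None
                if len(parts) > 2:
                    kernel = int(parts[2].lstrip("k"))
                layers.append(LayerSpec(kind, size=int(parts[1]), kernel=kernel))
            else:
                layers.append(LayerSpec(kind, size=int(parts[1])))
        return ArchitectureSpec(tuple(layers), batch_size=batch_size, window_length=window_length)

    def describe(self) -> str:
        return ", ".join(s.describe() for s in self.layers)

    def table_row(self) -> dict:
        """Summary columns: length, L1, pool, D1, L2, D2, batch."""
        row = {"length": self.window_length, "L1": None, "pool": None, "D1": None,
               "L2": None, "D2": None, "batch": self.batch_size}
        for spec in self.layers:
            if spec.kind == "MaxPool":
                row["pool"] = spec.size
            elif spec.kind == "Dropout":
                slot = "D1" if row["D1"] is None else "D2"
                row[slot] = spec.rate
            else:
                slot = "L1" if row["L1"] is None else "L2"
                row[slot] = f"{spec.kind} {spec.size}"
        return row


TOP_SEMREP_ARCHITECTURE = ArchitectureSpec.parse(
    "conv1d:32,maxpool:2,dropout:0.2,bilstm:32,dropout:0.2", batch_size=64, window_length=20
)


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings: binary cross-entropy, Adam, early stopping."""

    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.patience < self.max_epochs):
            raise ValueError("require 0 < patience < max_epochs")


@dataclasses.dataclass
class FoldResult:
    """Cross-validation outcome for one architecture."""

    architecture: ArchitectureSpec
    seed: int
    fold_accuracies: list[float]
    fold_correct: list[int]
    fold_sizes: list[int]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled(self) -> tuple[int, int]:
        """(total correct, total test instances) across folds."""
        return int(sum(self.fold_correct)), int(sum(self.fold_sizes))


def build_classifier(arch: ArchitectureSpec, window_length: int, dimension: int,
                     seed: int = 0) -> nn.Network:
    """Materialise an architecture as an untrained network with a sigmoid head."""
    layers: list[nn.Layer] = []
    specs = arch.layers
    for pos, spec in enumerate(specs):
        later_sequence = any(
            s.kind in ("Conv1D", "MaxPool") or s.kind in _RECURRENT_KINDS
            for s in specs[pos + 1 :]
        )
        if spec.kind == "Conv1D":
            layers.append(nn.Conv1D(spec.size, kernel_size=spec.kernel or 3))
        elif spec.kind == "MaxPool":
            layers.append(nn.MaxPool1D(spec.size))
        elif spec.kind == "Dropout":
            layers.append(nn.Dropout(spec.rate))
        elif spec.kind == "BiLSTM":
            layers.append(nn.Bidirectional(nn.LSTM, spec.size, return_sequences=later_sequence))
        elif spec.kind == "LSTM":
            layers.append(nn.LSTM(spec.size, return_sequences=later_sequence))
        elif spec.kind == "GRU":
            layers.append(nn.GRU(spec.size, return_sequences=later_sequence))
        elif spec.kind == "SimpleRNN":
            layers.append(nn.SimpleRNN(spec.size, return_sequences=later_sequence))
    if not any(s.kind in _RECURRENT_KINDS for s in specs):
        layers.append(nn.Flatten())
    layers.append(nn.Dense(1))
    return nn.Network(layers, input_shape=(window_length, dimension), seed=seed)


class SequenceClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style classifier over (n, window, dimension) inputs.

    Parameters
    ----------
    architecture : layer-stack string (see :meth:`ArchitectureSpec.parse`)
        or an :class:`ArchitectureSpec`.
    batch_size : overrides the architecture's batch size when given.
    validation_fraction : stratified share of the training data held out
        for early stopping when ``fit`` receives no explicit validation set.
    """

    def __init__(
        self,
        architecture: str | ArchitectureSpec = "gru:16,dropout:0.2,gru:8",
        batch_size: int | None = None,
        max_epochs: int = 100,
        patience: int = 10,
        validation_fraction: float = 0.1,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> None:
        self.architecture = architecture
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.learning_rate = learning_rate
        self.seed = seed

    def _arch(self, window_length: int) -> ArchitectureSpec:
        arch = self.architecture
        if isinstance(arch, str):
            arch = ArchitectureSpec.parse(arch, window_length=window_length)
        if self.batch_size is not None and self.batch_size != arch.batch_size:
            arch = dataclasses.replace(arch, batch_size=self.batch_size)
        return arch

    def fit(self, X, y, validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_instances, window_length, dimension)")
        if validation_data is None:
            idx_tr, idx_va = train_test_split(
                np.arange(len(X)),
                test_size=self.validation_fraction,
                random_state=self.seed,
                stratify=y,
            )
            X_tr, y_tr, X_va, y_va = X[idx_tr], y[idx_tr], X[idx_va], y[idx_va]
        else:
            X_tr, y_tr = X, y
            X_va, y_va = validation_data
            X_va = np.asarray(X_va, dtype=np.float32)
            y_va = np.asarray(y_va)
        arch = self._arch(window_length=X.shape[1])
        self.architecture_ = arch
        self.network_ = build_classifier(arch, X.shape[1], X.shape[2], seed=self.seed)
        self.history_ = nn.train_network(
            self.network_,
            X_tr, y_tr, X_va, y_va,
            batch_size=arch.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )
        self.classes_ = np.array([0, 1])
        self.n_epochs_ = len(self.history_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        p = self.network_.predict_proba(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_classifier(
    clf: SequenceClassifier, split: DatasetSplit, config: TrainingConfig | None = None
) -> tuple[SequenceClassifier, nn.TrainingHistory]:
    """Fit a classifier on one fold's train/validation partitions."""
    if not split.train or not split.validation:
        raise ValueError("split must have non-empty train and validation partitions")
    if config is not None:
        clf.set_params(
            max_epochs=config.max_epochs,
            patience=config.patience,
            learning_rate=config.learning_rate,
            seed=config.seed,
        )
    X_tr, y_tr = instances_to_arrays(split.train)
    X_va, y_va = instances_to_arrays(split.validation)
    clf.fit(X_tr, y_tr, validation_data=(X_va, y_va))
    return clf, clf.history_


def evaluate_accuracy(clf: SequenceClassifier, test: Sequence[TrainingInstance]) -> float:
    """Fraction of test instances where thresholding the probability at 0.5 matches the label."""
    if not len(test):
        raise ValueError("empty test set")
    X, y = instances_to_arrays(test)
    return float(np.mean(clf.predict(X) == y))


def cross_validate(
    instances: Sequence[TrainingInstance],
    arch: ArchitectureSpec,
    config: TrainingConfig | None = None,
    k: int = 5,
    validation_fraction: float = 0.1,
) -> FoldResult:
    """Stratified k-fold cross-validation of one architecture.

    Each fold trains with early stopping on its own validation portion and
    is scored on its held-out test portion; folds are fixed by the
    run-level seed so different architectures see identical partitions.
    """
    config = config or TrainingConfig()
    have = instances[0].window.shape[0] if len(instances) else 0
    if arch.window_length < have:
        # shorter history length: use only the trailing snapshots
        instances = truncate_windows(instances, arch.window_length)
    elif arch.window_length > have:
        raise ValueError(
            f"architecture expects windows of {arch.window_length}, instances have {have}"
        )
    y = np.array([i.label for i in instances])
    if (y == 1).sum() != (y == 0).sum():
        warnings.warn(
            f"classes are not balanced ({int((y == 1).sum())} positives vs "
            f"{int((y == 0).sum())} negatives)", stacklevel=2,
        )
    splits = stratified_kfold(instances, k=k, validation_fraction=validation_fraction,
                              seed=config.seed)
    accuracies, corrects, sizes = [], [], []
    for split in splits:
        clf = SequenceClassifier(
            architecture=arch,
            max_epochs=config.max_epochs,
            patience=config.patience,
            learning_rate=config.learning_rate,
            seed=config.seed + split.fold,
        )
        train_classifier(clf, split)
        acc = evaluate_accuracy(clf, split.test)
        accuracies.append(acc)
        corrects.append(int(round(acc * len(split.test))))
        sizes.append(len(split.test))
    return FoldResult(architecture=arch, seed=config.seed, fold_accuracies=accuracies,
                      fold_correct=corrects, fold_sizes=sizes)


def grid_search(
    instances: Sequence[TrainingInstance],
    grid: Sequence[tuple[ArchitectureSpec, TrainingConfig]],
    label_source: str = "synthetic",
    k: int = 5,
) -> tuple[pd.DataFrame, list[FoldResult]]:
    """Cross-validate every grid point; report ranked by mean accuracy.

    The report mirrors the usual results-table layout: label source,
    window length, L1 / pool / D1 / L2 / D2, batch size, mean accuracy.
    """
    if not len(grid):
        raise ValueError("empty grid")
    results = [cross_validate(instances, arch, config, k=k) for arch, config in grid]
    rows = []
    for res in results:
        row = {"label": label_source}
        row.update(res.architecture.table_row())
        row["result"] = res.mean_accuracy
        rows.append(row)
    report = pd.DataFrame(rows).sort_values("result", ascending=False, kind="stable")
    report = report.reset_index(drop=True)
    return report, results


def predict_repurposing(clf: SequenceClassifier, window: np.ndarray) -> float | np.ndarray:
    """Repurposing-potential score for one drug window (or a batch of windows)."""
    window = np.asarray(window, dtype=np.float32)
    single = window.ndim == 2
    batch = window[None] if single else window
    expected = (batch.shape[1], batch.shape[2])
    net_shape = clf.network_.input_shape
    if expected != net_shape:
        raise ValueError(f"window shape {expected} does not match model input {net_shape}")
    p = clf.predict_proba(batch)[:, 1]
    return float(p[0]) if single else p


def save_model(clf: SequenceClassifier, path: str | pathlib.Path) -> None:
    root = pathlib.Path(path)
    root.mkdir(parents=True, exist_ok=True)
    arch = clf.architecture_
    meta = {
        "layers": [dataclasses.asdict(s) for s in arch.layers],
        "batch_size": arch.batch_size,
        "window_length": arch.window_length,
        "input_shape": list(clf.network_.input_shape),
        "seed": clf.seed,
        "params": {
            "max_epochs": clf.max_epochs,
            "patience": clf.patience,
            "validation_fraction": clf.validation_fraction,
            "learning_rate": clf.learning_rate,
        },
    }
    (root / "model.json").write_text(json.dumps(meta, indent=1) + "\n")
    np.savez(root / "weights.npz", **{f"p{i}": p for i, p in enumerate(clf.network_.params)})


def load_model(path: str | pathlib.Path) -> SequenceClassifier:
    root = pathlib.Path(path)
    meta = json.loads((root / "model.json").read_text())
    arch = ArchitectureSpec(
        layers=tuple(LayerSpec(**s) for s in meta["layers"]),
        batch_size=meta["batch_size"],
        window_length=meta["window_length"],
    )
    clf = SequenceClassifier(architecture=arch, seed=meta["seed"], **meta["params"])
    t, d = meta["input_shape"]
    clf.architecture_ = arch
    clf.network_ = build_classifier(arch, t, d, seed=meta["seed"])
    weights = np.load(root / "weights.npz")
    clf.network_.set_weights([weights[f"p{i}"] for i in range(len(clf.network_.params))])
    clf.classes_ = np.array([0, 1])
    return clf


def read_grid_file(path: str | pathlib.Path) -> list[tuple[ArchitectureSpec, TrainingConfig]]:
    """Parse a key-value grid file: one point per line,
    ``layers=...; batch=64; window=20 [; seed=0]``; '#' starts a comment."""
    grid = []
    for ln, line in enumerate(pathlib.Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = dict(
            (kv.split("=", 1)[0].strip(), kv.split("=", 1)[1].strip())
            for kv in line.split(";") if kv.strip()
        )
        try:
            arch = ArchitectureSpec.parse(
                fields["layers"],
                batch_size=int(fields.get("batch", 64)),
                window_length=int(fields.get("window", 20)),
            )
        except KeyError:
            raise ValueError(f"{path}: line {ln}: missing 'layers=' field")
        grid.append((arch, TrainingConfig(seed=int(fields.get("seed", 0)))))
    return grid
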