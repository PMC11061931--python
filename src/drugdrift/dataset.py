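"""Windowed, balanced, stratified datasets from embedding time series.

A training instance is |w| consecutive snapshot vectors for one drug with
a binary label describing the *final* state only: 1 iff a repurposing
event maps onto the window's last snapshot.  Negatives are all full-
coverage windows whose final state carries label 0; classes are balanced
by seeded down-sampling of the negatives.
"""

from __future__ import annotations

import dataclasses
import pathlib
from collections.abc import Sequence

import numpy as np
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)

from .embeddings import EmbeddingStore
from .labelling import LabelSeries

__all__ = [
    "TrainingInstance",
    "DatasetSplit",
    "build_instances",
    "balance_classes",
    "stratified_kfold",
    "instances_to_arrays",
    "save_dataset",
    "load_dataset",
]


@dataclasses.dataclass(frozen=True)
class TrainingInstance:
    """One drug's window of consecutive embedding vectors plus its final-state label."""

    drug: str
    start: int  # snapshot index of the first vector
    window: np.ndarray  # (|w|, dimension), float32
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.window.ndim != 2:
            raise ValueError("window must be (|w|, dimension)")


@dataclasses.dataclass
class DatasetSplit:
    """Disjoint, stratified train / validation / test subsets for one fold."""

    train: list[TrainingInstance]
    validation: list[TrainingInstance]
    test: list[TrainingInstance]
    fold: int
    seed: int


def build_instances(
    store: EmbeddingStore,
    labels: Sequence[LabelSeries],
    window_length: int,
    stride: int = 1,
    subsample_step: int = 1,
) -> list[TrainingInstance]:
    """Slide windows over each drug's snapshot series.

    A window is emitted only when the drug is present at every selected
    position (no gaps).  With ``subsample_step`` m > 1, the window takes
    every m-th snapshot, spanning (window_length-1)*m + 1 snapshots while
    still feeding ``window_length`` vectors to the classifier.  The label
    is the label-series value at the window's final snapshot index.
    """
    if window_length < 1 or stride < 1 or subsample_step < 1:
        raise ValueError("window_length, stride and subsample_step must be >= 1")
    n_snap = len(store)
    span = (window_length - 1) * subsample_step + 1
    instances: list[TrainingInstance] = []
    for series in labels:
        if len(series) != n_snap:
            raise ValueError(
                f"label series for {series.drug!r} has length {len(series)}, store has {n_snap}"
            )
        present = store.presence(series.drug)
        if not present.any():
            continue
        lab = series.labels
        for start in range(0, n_snap - span + 1, stride):
            positions = range(start, start + span, subsample_step)
            if not all(present[p] for p in positions):
                continue
            window = np.stack([store.vector(series.drug, p) for p in positions])
            instances.append(
                TrainingInstance(
                    drug=series.drug, start=start, window=window, label=int(lab[start + span - 1])
                )
            )
    return instances


def balance_classes(instances: Sequence[TrainingInstance], seed: int = 0) -> list[TrainingInstance]:
    """Keep all positives; down-sample negatives to match; shuffle (seeded)."""
    positives = [i for i in instances if i.label == 1]
    negatives = [i for i in instances if i.label == 0]
    if not positives or not negatives:
        raise ValueError(
            f"both classes required for balancing (got {len(positives)} positives, "
            f"{len(negatives)} negatives)"
        )
    if len(negatives) < len(positives):
        raise ValueError("fewer negatives than positives; cannot down-sample negatives")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(negatives), size=len(positives), replace=False)
    balanced = positives + [negatives[i] for i in sorted(keep)]
    order = rng.permutation(len(balanced))
    return [balanced[i] for i in order]


def stratified_kfold(
    instances: Sequence[TrainingInstance],
    k: int = 5,
    validation_fraction: float = 0.1,
    seed: int = 0,
    grouped: bool = False,
) -> list[DatasetSplit]:
    """k stratified folds; each fold's test is 1/k of the data, and
    ``validation_fraction`` of the remaining training portion is held out
    (also stratified) for early stopping.

    With ``grouped=True`` all windows of one drug land in the same subset,
    preventing overlap leakage at the cost of exact class-ratio guarantees.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.array([i.label for i in instances])
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} instances")
    idx = np.arange(len(instances))
    groups = np.array([i.drug for i in instances])
    if grouped:
        folds = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed).split(
            idx, y, groups
        )
    else:
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(idx, y)
    splits: list[DatasetSplit] = []
    for fold, (train_idx, test_idx) in enumerate(folds):
        if validation_fraction > 0:
            if grouped:
                gss = GroupShuffleSplit(n_splits=1, test_size=validation_fraction, random_state=seed)
                tr, va = next(gss.split(train_idx, y[train_idx], groups[train_idx]))
            else:
                tr, va = train_test_split(
                    np.arange(len(train_idx)),
                    test_size=validation_fraction,
                    random_state=seed,
                    stratify=y[train_idx],
                )
            train_sel, val_sel = train_idx[tr], train_idx[va]
        else:
            train_sel, val_sel = train_idx, np.zeros(0, dtype=int)
        splits.append(
            DatasetSplit(
                train=[instances[i] for i in train_sel],
                validation=[instances[i] for i in val_sel],
                test=[instances[i] for i in test_idx],
                fold=fold,
                seed=seed,
            )
        )
    return splits


def truncate_windows(
    instances: Sequence[TrainingInstance], window_length: int
) -> list[TrainingInstance]:
    """Keep only the trailing ``window_length`` vectors of each instance.

    The label describes the final state, which is preserved, so a shorter
    history length can be explored without rebuilding instances.
    """
    out = []
    for inst in instances:
        have = inst.window.shape[0]
        if window_length > have:
            raise ValueError(f"cannot extend a window of {have} to {window_length}")
        if window_length == have:
            out.append(inst)
        else:
            out.append(
                TrainingInstance(
                    drug=inst.drug,
                    start=inst.start + (have - window_length),
                    window=inst.window[have - window_length :],
                    label=inst.label,
                )
            )
    return out


def instances_to_arrays(instances: Sequence[TrainingInstance]) -> tuple[np.ndarray, np.ndarray]:
    """Stack instances into (n, |w|, dim) float32 X and (n,) int y."""
    if not instances:
        raise ValueError("no instances to stack")
    X = np.stack([i.window for i in instances]).astype(np.float32)
    y = np.array([i.label for i in instances], dtype=np.int64)
    return X, y


def save_dataset(instances: Sequence[TrainingInstance], path: str | pathlib.Path) -> None:
    """Windows as one 3-axis array (.npz) plus a TSV index alongside."""
    path = pathlib.Path(path)
    X, y = instances_to_arrays(instances)
    np.savez_compressed(path, windows=X, labels=y)
    index = path.with_suffix(".tsv")
    with index.open("w") as fh:
        fh.write("DRUG\tSTART\tLABEL\n")
        for inst in instances:
            fh.write(f"{inst.drug}\t{inst.start}\t{inst.label}\n")


def load_dataset(path: str | pathlib.Path) -> list[TrainingInstance]:
    path = pathlib.Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    data = np.load(npz)
    X, y = data["windows"], data["labels"]
    rows = pathlib.Path(npz).with_suffix(".tsv").read_text().splitlines()[1:]
    instances = []
    for i, row in enumerate(r for r in rows if r.strip()):
        drug, start, label = row.split("\t")
        if int(label) != int(y[i]):
            raise ValueError(f"index row {i} disagrees with stored labels")
        instances.append(TrainingInstance(drug, int(start), X[i], int(label)))
    return instances
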