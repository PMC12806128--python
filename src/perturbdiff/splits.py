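"""Data-splitting strategies for out-of-distribution benchmarking.

Two schemes:

- a five-way benchmark split that holds out drugs and cell lines
  independently, yielding train / val / Drug_unseen / Cell_line_unseen /
  Both_unseen partitions from a single training run;
- classic 5-fold cross-validation in three modes (random record split, drug
  split, cell-line split) at roughly 6:2:2 train:val:test proportions.

Drugs are identified by canonical SMILES so a compound held out at one dose
is held out at all doses.  All assignments are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import PerturbationDataset

__all__ = ["SplitAssignment", "split_benchmark", "split_prnet_cv", "BENCHMARK_PARTS"]

BENCHMARK_PARTS = ("train", "val", "test_drug_unseen", "test_cell_unseen", "test_both_unseen")
CV_PARTS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Per-record part labels plus the held-out unit sets that induced them."""

    labels: np.ndarray  # array of part names, one per record
    held_out_drugs: set = field(default_factory=set)
    held_out_cells: set = field(default_factory=set)
    seed: int = 0
    fold: int | None = None

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.labels == part)

    def parts(self) -> list[str]:
        return [p for p in (BENCHMARK_PARTS if self.fold is None else CV_PARTS) if (self.labels == p).any()]

    def to_csv(self, path) -> None:
        pd.DataFrame({"record_id": np.arange(len(self.labels)), "part": self.labels}).to_csv(
            path, index=False
        )

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "fold": self.fold,
            "held_out_drugs": sorted(self.held_out_drugs),
            "held_out_cells": sorted(self.held_out_cells),
            "part_sizes": {p: int((self.labels == p).sum()) for p in np.unique(self.labels)},
        }

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=1))


def _unique_sorted(values) -> list:
    return sorted(set(values))


def split_benchmark(
    dataset: PerturbationDataset,
    drug_holdout_frac: float = 0.2,
    cell_holdout_frac: float = 0.2,
    val_frac: float = 0.25,
    seed: int = 0,
) -> SplitAssignment:
    """Five-way benchmark split with independently held-out drugs and cells.

    Records are routed by the cross-classification of their drug and cell
    holdout status; the remainder (neither held out) is split into train/val
    at record level by ``val_frac``.  Raises if any of the five parts ends up
    empty.
    """
    for name, frac in (("drug_holdout_frac", drug_holdout_frac),
                       ("cell_holdout_frac", cell_holdout_frac),
                       ("val_frac", val_frac)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    obs = dataset.obs
    drugs = _unique_sorted(obs["drug_id"].dropna())
    cells = _unique_sorted(obs["cell_line"])
    n_drug_out = max(1, int(round(drug_holdout_frac * len(drugs))))
    n_cell_out = max(1, int(round(cell_holdout_frac * len(cells))))
    if n_drug_out >= len(drugs) or n_cell_out >= len(cells):
        raise ValueError("holdout fraction leaves no training drugs or cells")
    rng = np.random.default_rng(seed)
    held_drugs = set(rng.choice(drugs, size=n_drug_out, replace=False))
    held_cells = set(rng.choice(cells, size=n_cell_out, replace=False))

    drug_out = obs["drug_id"].isin(held_drugs).to_numpy()
    cell_out = obs["cell_line"].isin(held_cells).to_numpy()
    labels = np.empty(len(dataset), dtype=object)
    labels[drug_out & cell_out] = "test_both_unseen"
    labels[drug_out & ~cell_out] = "test_drug_unseen"
    labels[~drug_out & cell_out] = "test_cell_unseen"
    rest = np.flatnonzero(~drug_out & ~cell_out)
    rng.shuffle(rest)
    n_val = int(round(val_frac * len(rest)))
    labels[rest[:n_val]] = "val"
    labels[rest[n_val:]] = "train"
    assignment = SplitAssignment(
        labels=labels.astype(str), held_out_drugs=held_drugs, held_out_cells=held_cells, seed=seed
    )
    for part in BENCHMARK_PARTS:
        if not (assignment.labels == part).any():
            raise ValueError(f"benchmark split produced an empty part: {part}")
    return assignment


def split_prnet_cv(
    dataset: PerturbationDataset,
    mode: str = "random",
    n_folds: int = 5,
    seed: int = 0,
) -> list[SplitAssignment]:
    """K-fold cross-validation by record (random), drug, or cell line.

    ``random`` mode partitions records into ``n_folds`` chunks; fold ``i``
    uses chunk ``i`` as test, chunk ``i+1`` as validation and the rest as
    train (5 folds gives the 6:2:2 proportions).  ``drug``/``cell`` modes
    partition the drug or cell-line units the same way so test units never
    appear in training; validation records are drawn from training-side units.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if mode not in ("random", "drug", "cell"):
        raise ValueError("mode must be one of random, drug, cell")
    rng = np.random.default_rng(seed)
    n = len(dataset)

    if mode == "random":
        order = rng.permutation(n)
        chunks = np.array_split(order, n_folds)
        assignments = []
        for i in range(n_folds):
            labels = np.full(n, "train", dtype=object)
            labels[chunks[i]] = "test"
            labels[chunks[(i + 1) % n_folds]] = "val"
            assignments.append(SplitAssignment(labels=labels.astype(str), seed=seed, fold=i))
        return assignments

    col = "drug_id" if mode == "drug" else "cell_line"
    units = _unique_sorted(dataset.obs[col].dropna())
    if len(units) < n_folds:
        raise ValueError(f"{mode} mode needs at least n_folds={n_folds} units, got {len(units)}")
    unit_order = rng.permutation(units)
    unit_chunks = np.array_split(unit_order, n_folds)
    unit_col = dataset.obs[col].to_numpy()
    assignments = []
    for i in range(n_folds):
        test_units = set(unit_chunks[i])
        labels = np.full(n, "train", dtype=object)
        test_mask = np.isin(unit_col, list(test_units))
        labels[test_mask] = "test"
        # validation drawn from training-side records: 1/(n_folds-1) of them,
        # giving ~6:2:2 at 5 folds
        train_idx = np.flatnonzero(~test_mask)
        fold_rng = np.random.default_rng(seed * 1000 + i)
        fold_rng.shuffle(train_idx)
        n_val = int(round(len(train_idx) / (n_folds - 1)))
        labels[train_idx[:n_val]] = "val"
        held_drugs = test_units if mode == "drug" else set()
        held_cells = test_units if mode == "cell" else set()
        assignments.append(
            SplitAssignment(
                labels=labels.astype(str),
                held_out_drugs=held_drugs,
                held_out_cells=held_cells,
                seed=seed,
                fold=i,
            )
        )
    return assignments
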