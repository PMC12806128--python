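"""The 10-metric evaluation suite for perturbation-response prediction.

Two metrics — the coefficient of determination R^2 between predicted and true
perturbed profiles, and the Pearson correlation of log fold changes
PCC(lnFC) relative to the paired control — are each evaluated under five
grouping granularities: drug, drug_dose, cov_drug (drug x cell line),
cov_drug_dose (drug x cell x dose), and per_sample (no grouping).  Within a
group the true, predicted and control profiles are averaged first, then the
metric is computed; the reported value is the unweighted mean over groups.
Groups on which a metric is undefined (constant truth, zero-variance fold
change) are excluded and counted.

Additionally, a DEG-restricted per-gene analysis: for each drug and each of
its differentially expressed genes, the Pearson correlation across that
drug's samples between true and predicted per-sample lnFC of the single gene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DEGSet, PerturbationDataset

__all__ = [
    "STRATEGIES",
    "r_squared",
    "ln_fc",
    "pcc_lnfc",
    "grouped_metric",
    "evaluate_all",
    "MetricReport",
    "deg_gene_pcc",
]

STRATEGIES = ("drug", "drug_dose", "cov_drug", "cov_drug_dose", "per_sample")
METRICS = ("R2", "PCC_lnFC")


def r_squared(y_true, y_pred, center: str = "true") -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    ``center="true"`` (default) centers the total sum of squares on
    mean(y_true), the standard definition; ``center="pred"`` reproduces the
    printed-formula variant that centers on mean(y_pred).  Returns NaN with a
    warning when the denominator is zero.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ValueError("r_squared needs at least 2 elements")
    if center == "true":
        ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    elif center == "pred":
        ss_tot = np.sum((y_true - y_pred.mean()) ** 2)
    else:
        raise ValueError("center must be 'true' or 'pred'")
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined for constant y_true; returning NaN", stacklevel=2)
        return float("nan")
    return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)


def ln_fc(y, x_control) -> np.ndarray:
    """Log fold change: elementwise difference of log-normalized profiles."""
    y = np.asarray(y, dtype=np.float64)
    x_control = np.asarray(x_control, dtype=np.float64)
    if y.shape != x_control.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {x_control.shape}")
    return y - x_control


def pcc_lnfc(y_true, y_pred, x_control) -> float:
    """Pearson correlation of true vs predicted lnFC against the shared control."""
    fc_true = ln_fc(y_true, x_control)
    fc_pred = ln_fc(y_pred, x_control)
    if np.std(fc_true) == 0.0 or np.std(fc_pred) == 0.0:
        warnings.warn("PCC(lnFC) undefined for zero-variance fold change; NaN", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(fc_true, fc_pred)[0, 1])


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0:
        return 0.0
    return float(np.format_float_positional(x, precision=sig, fractional=False))


def _group_labels(dataset: PerturbationDataset, strategy: str) -> pd.Series:
    obs = dataset.obs
    dose = obs["dose_um"].map(_round_sig).astype(str)
    if strategy == "drug":
        key = obs["drug_id"].astype(str)
    elif strategy == "drug_dose":
        key = obs["drug_id"].astype(str) + "|" + dose
    elif strategy == "cov_drug":
        key = obs["drug_id"].astype(str) + "|" + obs["cell_line"].astype(str)
    elif strategy == "cov_drug_dose":
        key = obs["drug_id"].astype(str) + "|" + obs["cell_line"].astype(str) + "|" + dose
    elif strategy == "per_sample":
        key = pd.Series(np.arange(len(dataset)).astype(str), index=obs.index)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    return key


def _grouped(dataset, predictions, strategy, metric, r2_center="true"):
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.shape != dataset.perturbed.shape:
        raise ValueError("predictions must align 1:1 with records")
    labels = _group_labels(dataset, strategy)
    values = []
    n_excluded = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key in sorted(labels.unique()):
            idx = np.flatnonzero((labels == key).to_numpy())
            y_true = dataset.perturbed[idx].mean(axis=0)
            y_pred = predictions[idx].mean(axis=0)
            x_ctrl = dataset.control[idx].mean(axis=0)
            if metric == "R2":
                v = r_squared(y_true, y_pred, center=r2_center)
            elif metric == "PCC_lnFC":
                v = pcc_lnfc(y_true, y_pred, x_ctrl)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            if np.isnan(v):
                n_excluded += 1
            else:
                values.append(v)
    if not values:
        raise ValueError(f"no evaluable group for {metric} under {strategy}")
    return float(np.mean(values)), len(values), n_excluded


def grouped_metric(dataset, predictions, strategy: str, metric: str, r2_center: str = "true") -> float:
    """Group-averaged metric (mean over groups of the within-group value)."""
    value, _, _ = _grouped(dataset, predictions, strategy, metric, r2_center)
    return value


@dataclass
class MetricReport:
    """The 2 x 5 metric grid for one evaluation split."""

    values: dict = field(default_factory=dict)  # (metric, strategy) -> float
    n_groups: dict = field(default_factory=dict)  # strategy -> int
    n_excluded: dict = field(default_factory=dict)  # (metric, strategy) -> int

    def __getitem__(self, key):
        return self.values[key]

    def to_dict(self) -> dict:
        return {
            "values": {f"{m}.{s}": v for (m, s), v in self.values.items()},
            "n_groups": dict(self.n_groups),
            "n_excluded": {f"{m}.{s}": v for (m, s), v in self.n_excluded.items()},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_frame(self, split: str | None = None) -> pd.DataFrame:
        rows = [
            {
                "metric": m,
                "strategy": s,
                "split": split,
                "value": v,
                "n_groups": self.n_groups.get(s),
            }
            for (m, s), v in self.values.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path, split: str | None = None) -> None:
        self.to_frame(split).to_csv(path, index=False)


def evaluate_all(dataset: PerturbationDataset, predictions, r2_center: str = "true") -> MetricReport:
    """Run the full 2-metric x 5-strategy grid on aligned predictions."""
    report = MetricReport()
    for strategy in STRATEGIES:
        for metric in METRICS:
            try:
                value, n_groups, n_excl = _grouped(
                    dataset, predictions, strategy, metric, r2_center
                )
            except ValueError as exc:
                raise ValueError(f"evaluation failed for {metric} under {strategy}") from exc
            report.values[(metric, strategy)] = value
            report.n_groups[strategy] = n_groups
            report.n_excluded[(metric, strategy)] = n_excl
    return report


def deg_gene_pcc(
    dataset: PerturbationDataset, predictions, deg_sets: list[DEGSet]
) -> dict[str, float]:
    """Per-drug mean of single-gene PCC(lnFC) over that drug's DEGs.

    For each (drug, DEG gene) pair the correlation is computed across all of
    the drug's samples between the true and predicted per-sample lnFC of that
    gene; genes with zero variance within a drug are skipped with a warning.
    Each DEG set scoped to a cell line restricts to that drug-cell group.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.shape != dataset.perturbed.shape:
        raise ValueError("predictions must align 1:1 with records")
    gene_index = {g: i for i, g in enumerate(dataset.gene_names)}
    fc_true = dataset.perturbed - dataset.control
    fc_pred = predictions - dataset.control
    out: dict[str, float] = {}
    for deg in deg_sets:
        sel = (dataset.obs["drug_id"] == deg.drug_id).to_numpy()
        if deg.cell_line is not None:
            sel &= (dataset.obs["cell_line"] == deg.cell_line).to_numpy()
        idx = np.flatnonzero(sel)
        if len(idx) < 3:
            warnings.warn(
                f"drug {deg.drug_id}: fewer than 3 samples; DEG PCC skipped", stacklevel=2
            )
            continue
        per_gene = []
        for gene in list(deg.up_genes) + list(deg.down_genes):
            gi = gene_index.get(gene)
            if gi is None:
                raise ValueError(f"DEG gene {gene!r} not in the dataset panel")
            a = fc_true[idx, gi]
            b = fc_pred[idx, gi]
            if np.std(a) == 0.0 or np.std(b) == 0.0:
                warnings.warn(
                    f"gene {gene} has zero lnFC variance under drug {deg.drug_id}; skipped",
                    stacklevel=2,
                )
                continue
            per_gene.append(float(np.corrcoef(a, b)[0, 1]))
        if per_gene:
            key = deg.drug_id if deg.cell_line is None else f"{deg.drug_id}|{deg.cell_line}"
            out[key] = float(np.mean(per_gene))
    return out
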