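"""Data model and preprocessing for paired perturbation transcriptomes.

A :class:`PerturbationDataset` holds paired (control, perturbed) log-normalized
expression profiles over a shared gene panel, annotated with drug SMILES, dose
(micromolar), cell line and optional organ.  Storage is columnar (two
samples-by-genes matrices plus an observation table) for efficiency, with
record-level views for per-observation work.  I/O uses the AnnData ``.h5ad``
container (long format: control and treated rows linked by a pairing column)
or an equivalent CSV trio.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .perturbations import canonical_smiles, InvalidSMILESError

__all__ = [
    "ExpressionProfile",
    "PerturbationRecord",
    "PerturbationDataset",
    "DEGSet",
    "log_normalize",
    "pair_controls",
    "filter_records",
    "compute_degs",
    "degs_to_json",
    "degs_from_json",
]

OBS_COLUMNS = ["smiles", "dose_um", "cell_line", "drug_id", "organ"]


@dataclass
class ExpressionProfile:
    """A single log-normalized expression vector over a named gene panel."""

    values: np.ndarray
    gene_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) != len(self.gene_names):
            raise ValueError("values must be a vector aligned with gene_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")


@dataclass
class PerturbationRecord:
    """One paired observation: control and perturbed profiles plus annotations."""

    control: ExpressionProfile
    perturbed: ExpressionProfile
    smiles: str
    dose_um: float
    cell_line: str
    drug_id: str | None
    organ: str | None = None

    def __post_init__(self):
        if self.control.gene_names != self.perturbed.gene_names:
            raise ValueError("control and perturbed must share the gene panel")
        if not self.dose_um > 0:
            raise ValueError(f"dose_um must be positive, got {self.dose_um}")


class PerturbationDataset:
    """Paired perturbation observations over a fixed gene panel.

    Parameters
    ----------
    control, perturbed : (n_records, n_gene) matrices of log-normalized values.
    obs : table with columns smiles, dose_um, cell_line and optionally organ;
        drug_id is derived from SMILES canonicalization when missing (invalid
        SMILES leave drug_id null; :func:`filter_records` removes them).
    gene_names : the shared gene panel, fixed at construction.
    """

    def __init__(self, control, perturbed, obs: pd.DataFrame, gene_names):
        self.control = np.asarray(control, dtype=np.float64)
        self.perturbed = np.asarray(perturbed, dtype=np.float64)
        self.gene_names = [str(g) for g in gene_names]
        obs = obs.reset_index(drop=True).copy()
        n, g = self.perturbed.shape
        if n == 0:
            raise ValueError("dataset must contain at least one record")
        if self.control.shape != (n, g) or g != len(self.gene_names):
            raise ValueError("control/perturbed/gene_names shapes are inconsistent")
        if not (np.all(np.isfinite(self.control)) and np.all(np.isfinite(self.perturbed))):
            raise ValueError("expression matrices must be finite")
        for col in ("smiles", "dose_um", "cell_line"):
            if col not in obs.columns:
                raise ValueError(f"obs is missing required column {col!r}")
        if "organ" not in obs.columns:
            obs["organ"] = None
        if "drug_id" not in obs.columns:
            obs["drug_id"] = [_safe_canonical(s) for s in obs["smiles"]]
        obs["dose_um"] = obs["dose_um"].astype(float)
        if not (obs["dose_um"] > 0).all():
            bad = obs.index[~(obs["dose_um"] > 0)].tolist()
            raise ValueError(f"non-positive dose_um at records {bad}")
        if len(obs) != n:
            raise ValueError("obs length must match the expression matrices")
        self.obs = obs[OBS_COLUMNS]

    # -- container protocol --------------------------------------------------
    @property
    def n_gene(self) -> int:
        return len(self.gene_names)

    def __len__(self) -> int:
        return self.perturbed.shape[0]

    def __getitem__(self, i: int) -> PerturbationRecord:
        row = self.obs.iloc[i]
        return PerturbationRecord(
            control=ExpressionProfile(self.control[i], self.gene_names),
            perturbed=ExpressionProfile(self.perturbed[i], self.gene_names),
            smiles=row["smiles"],
            dose_um=float(row["dose_um"]),
            cell_line=row["cell_line"],
            drug_id=row["drug_id"],
            organ=row["organ"],
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def subset(self, indices) -> "PerturbationDataset":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return PerturbationDataset(
            self.control[indices],
            self.perturbed[indices],
            self.obs.iloc[indices],
            self.gene_names,
        )

    # -- I/O -----------------------------------------------------------------
    def to_anndata(self):
        """Long-format AnnData: treated rows then control rows, linked by
        ``control_index``."""
        import anndata as ad

        n = len(self)
        X = np.vstack([self.perturbed, self.control])
        obs = pd.DataFrame(
            {
                "smiles": list(self.obs["smiles"]) + [""] * n,
                "dose_um": list(self.obs["dose_um"]) + [np.nan] * n,
                "cell_line": list(self.obs["cell_line"]) * 2,
                "organ": ["" if o is None else str(o) for o in self.obs["organ"]] * 2,
                "pert_type": ["treated"] * n + ["control"] * n,
                "control_index": list(range(n, 2 * n)) + [-1] * n,
            },
            index=[f"treated_{i}" for i in range(n)] + [f"control_{i}" for i in range(n)],
        )
        return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=self.gene_names))

    @classmethod
    def from_anndata(cls, adata) -> "PerturbationDataset":
        obs = adata.obs
        if "pert_type" not in obs.columns or "control_index" not in obs.columns:
            raise ValueError("AnnData must carry pert_type and control_index columns")
        X = np.asarray(adata.X, dtype=np.float64)
        treated = np.flatnonzero(np.asarray(obs["pert_type"]) == "treated")
        ctrl_idx = np.asarray(obs["control_index"])[treated].astype(int)
        if np.any(ctrl_idx < 0) or np.any(ctrl_idx >= X.shape[0]):
            raise ValueError("control_index out of range for a treated row")
        meta = obs.iloc[treated][["smiles", "dose_um", "cell_line"]].copy()
        meta["organ"] = obs["organ"].iloc[treated].values if "organ" in obs.columns else None
        return cls(X[ctrl_idx], X[treated], meta, list(adata.var_names))

    def write_h5ad(self, path) -> None:
        self.to_anndata().write_h5ad(path)

    @classmethod
    def read_h5ad(cls, path) -> "PerturbationDataset":
        import anndata as ad

        return cls.from_anndata(ad.read_h5ad(path))

    def write_csv(self, directory) -> None:
        """CSV trio: expression.csv, metadata.csv, pairing.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        adata = self.to_anndata()
        expr = pd.DataFrame(adata.X, index=adata.obs_names, columns=self.gene_names)
        expr.to_csv(directory / "expression.csv")
        meta = adata.obs[["smiles", "dose_um", "cell_line", "organ", "pert_type"]]
        meta.to_csv(directory / "metadata.csv")
        treated = adata.obs[adata.obs["pert_type"] == "treated"]
        pairing = pd.DataFrame(
            {
                "treated_id": treated.index,
                "control_id": [adata.obs_names[i] for i in treated["control_index"]],
            }
        )
        pairing.to_csv(directory / "pairing.csv", index=False)

    @classmethod
    def read_csv(cls, directory) -> "PerturbationDataset":
        directory = Path(directory)
        expr = pd.read_csv(directory / "expression.csv", index_col=0)
        meta = pd.read_csv(directory / "metadata.csv", index_col=0)
        pairing = pd.read_csv(directory / "pairing.csv")
        treated_ids = list(pairing["treated_id"])
        control_ids = list(pairing["control_id"])
        perturbed = expr.loc[treated_ids].to_numpy(dtype=np.float64)
        control = expr.loc[control_ids].to_numpy(dtype=np.float64)
        obs = meta.loc[treated_ids][["smiles", "dose_um", "cell_line", "organ"]]
        return cls(control, perturbed, obs, list(expr.columns))


def _safe_canonical(smiles) -> str | None:
    try:
        return canonical_smiles(smiles)
    except InvalidSMILESError:
        return None


def log_normalize(counts, scale: float = 1e4, gene_names=None):
    """Total-count scale each sample to ``scale`` then apply log(1 + x).

    Returns a matrix, or a list of :class:`ExpressionProfile` when
    ``gene_names`` is given.  Mirrors the standard scanpy
    normalize_total + log1p convention (cross-checked against it in tests).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 1:
        counts = counts[None, :]
    if not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not scale > 0:
        raise ValueError("scale must be positive")
    totals = counts.sum(axis=1)
    zero_rows = np.flatnonzero(totals == 0)
    if zero_rows.size:
        raise ValueError(f"cannot normalize all-zero sample(s) at rows {zero_rows.tolist()}")
    out = np.log1p(counts / totals[:, None] * scale)
    if gene_names is not None:
        return [ExpressionProfile(row, list(gene_names)) for row in out]
    return out


def pair_controls(
    perturbed_X,
    perturbed_obs: pd.DataFrame,
    control_X,
    control_obs: pd.DataFrame,
    match_keys=("cell_line",),
    seed: int = 0,
    gene_names=None,
) -> PerturbationDataset:
    """Assign one control sample to each perturbed sample by metadata match.

    Controls are matched on ``match_keys`` (default cell line; add a batch
    column when available).  When several controls match, one is chosen
    uniformly with the given seed, so the pairing is reproducible.
    """
    perturbed_X = np.asarray(perturbed_X, dtype=np.float64)
    control_X = np.asarray(control_X, dtype=np.float64)
    match_keys = list(match_keys)
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(perturbed_X.shape[1])]
    if control_X.shape[1] != perturbed_X.shape[1]:
        raise ValueError("perturbed and control gene panels differ in size")

    pools: dict[tuple, np.ndarray] = {}
    for key, idx in control_obs.reset_index(drop=True).groupby(match_keys).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        pools[key] = np.asarray(idx)
    rng = np.random.default_rng(seed)
    chosen = np.empty(len(perturbed_obs), dtype=int)
    unmatched = []
    keys = perturbed_obs[match_keys].itertuples(index=False, name=None)
    for i, key in enumerate(keys):
        pool = pools.get(tuple(key))
        if pool is None or len(pool) == 0:
            unmatched.append(tuple(key))
            continue
        chosen[i] = pool[rng.integers(len(pool))]
    if unmatched:
        raise ValueError(f"no matching control for keys: {sorted(set(map(str, unmatched)))}")
    obs = perturbed_obs.reset_index(drop=True)[
        [c for c in ("smiles", "dose_um", "cell_line", "organ") if c in perturbed_obs.columns]
    ]
    return PerturbationDataset(control_X[chosen], perturbed_X, obs, gene_names)


def filter_records(dataset: PerturbationDataset, min_obs_per_compound: int = 5) -> PerturbationDataset:
    """Drop records with invalid SMILES, then compounds with too few observations.

    The default threshold of 5 matches the preprocessing convention for the
    L1000-style corpus this pipeline targets.  Idempotent.
    """
    valid = dataset.obs["drug_id"].notna().to_numpy()
    counts = dataset.obs.loc[valid, "drug_id"].value_counts()
    keep_drugs = set(counts[counts >= min_obs_per_compound].index)
    keep = valid & dataset.obs["drug_id"].isin(keep_drugs).to_numpy()
    if not keep.any():
        raise ValueError("no records remain after compound filtering")
    return dataset.subset(keep)


@dataclass
class DEGSet:
    """Ranked up-/down-regulated gene lists for one drug (or drug-cell) group."""

    drug_id: str
    up_genes: list[str]
    down_genes: list[str]
    cell_line: str | None = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up_genes and down_genes must be disjoint")


def compute_degs(
    dataset: PerturbationDataset,
    n_up: int = 25,
    n_down: int = 25,
    group_by: str = "drug_cell",
    method: str = "mean_lnfc",
) -> list[DEGSet]:
    """Differentially expressed genes per drug (or drug-cell) group.

    Genes are scored within each group by the mean log fold change of
    perturbed vs. paired control profiles (``method="mean_lnfc"``), or by the
    Wilcoxon rank-sum statistic of perturbed vs. control values
    (``method="wilcoxon"``).  The top ``n_up`` (descending score) and top
    ``n_down`` (ascending, excluding the up set) are reported; ties break by
    gene-panel order via stable sorting, so output is independent of record
    order.  Groups with fewer than 2 records are skipped with a warning.
    """
    if group_by not in ("drug", "drug_cell"):
        raise ValueError("group_by must be 'drug' or 'drug_cell'")
    if method not in ("mean_lnfc", "wilcoxon"):
        raise ValueError("method must be 'mean_lnfc' or 'wilcoxon'")
    cols = ["drug_id"] if group_by == "drug" else ["drug_id", "cell_line"]
    out: list[DEGSet] = []
    obs = dataset.obs.reset_index(drop=True)
    for key, idx in sorted(obs.dropna(subset=["drug_id"]).groupby(cols).groups.items()):
        idx = np.asarray(idx)
        if len(idx) < 2:
            warnings.warn(f"DEG group {key} has < 2 records; skipped", stacklevel=2)
            continue
        pert = dataset.perturbed[idx]
        ctrl = dataset.control[idx]
        if method == "mean_lnfc":
            score = (pert - ctrl).mean(axis=0)
        else:
            from scipy.stats import ranksums

            score = ranksums(pert, ctrl, axis=0).statistic
            score = np.nan_to_num(score, nan=0.0)
        order_up = np.argsort(-score, kind="stable")
        up = [dataset.gene_names[i] for i in order_up[:n_up]]
        up_set = set(up)
        order_down = [i for i in np.argsort(score, kind="stable") if dataset.gene_names[i] not in up_set]
        down = [dataset.gene_names[i] for i in order_down[:n_down]]
        drug_id, cell = (key, None) if group_by == "drug" else key
        out.append(
            DEGSet(
                drug_id=drug_id,
                cell_line=cell,
                up_genes=up,
                down_genes=down,
                scores={dataset.gene_names[i]: float(score[i]) for i in range(len(score))},
            )
        )
    return out


def degs_to_json(deg_sets: list[DEGSet], path) -> None:
    payload = [
        {
            "drug_id": d.drug_id,
            "cell_line": d.cell_line,
            "up_genes": d.up_genes,
            "down_genes": d.down_genes,
        }
        for d in deg_sets
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def degs_from_json(path) -> list[DEGSet]:
    payload = json.loads(Path(path).read_text())
    return [DEGSet(**entry) for entry in payload]
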