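"""Dataset container, file I/O, somite-stage conversion, and splits.

The central object is :class:`TimeSeriesDataset`: a cells x features count
matrix with per-cell metadata (collection time in days, condition such as
sex, batch, modality tag, optional co-assay pairing and cell-type labels).
Chromatin-accessibility (ATAC) cells are binarized on construction; RNA
cells keep raw counts. Genomic coordinates, where present, are 0-based
half-open with strand in {+, -}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "TimeSeriesDataset",
    "SplitSpec",
    "load_dataset",
    "somite_to_time",
    "make_splits",
]

MODALITIES = ("RNA", "ATAC")
SOMITE_DAYS_PER_SOMITE = 2.0 / 34.0  # staging rate: 34 somites span two days

_REQUIRED_COLUMNS = ("modality",)


def somite_to_time(somite_count: int, anchor_somite: int, anchor_day: float) -> float:
    """Convert a somite count to developmental time in days.

    Somite staging assumes equal intervals between somite stages at a rate
    of 2/34 day per somite, anchored at a known (somite, day) pair.
    """
    if somite_count < 0:
        raise ValueError(f"somite_count must be >= 0, got {somite_count}")
    return anchor_day + (somite_count - anchor_somite) * SOMITE_DAYS_PER_SOMITE


@dataclass
class TimeSeriesDataset:
    """Single-cell time-series profiles across conditions and modalities.

    Parameters
    ----------
    counts : (cells x features) non-negative matrix, dense or CSR sparse.
    obs : per-cell metadata with columns ``time_days``, ``condition``,
        ``batch``, ``modality`` and optional ``pair_id`` / ``cell_type``.
    var : per-feature table indexed by feature id; optional genomic columns
        ``chrom``, ``start``, ``end``, ``strand``, ``tss``.
    """

    counts: sp.csr_matrix
    obs: pd.DataFrame
    var: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr().astype(np.float64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        n = self.counts.shape[0]
        if len(self.obs) != n:
            raise ValueError(
                f"cell-axis mismatch: matrix has {n} cells but metadata has "
                f"{len(self.obs)} rows"
            )
        if self.var is None:
            self.var = pd.DataFrame(index=[f"feat{i}" for i in range(self.counts.shape[1])])
        if len(self.var) != self.counts.shape[1]:
            raise ValueError(
                f"feature-axis mismatch: matrix has {self.counts.shape[1]} features "
                f"but var has {len(self.var)} rows"
            )
        self.obs = self.obs.reset_index(drop=True)
        for col in ("condition", "batch"):
            if col not in self.obs:
                self.obs[col] = "unknown"
            self.obs[col] = self.obs[col].astype(str)
        if "cell_type" in self.obs:
            self.obs["cell_type"] = self.obs["cell_type"].astype(str)
        if "modality" not in self.obs:
            raise ValueError("metadata must contain a 'modality' column")
        bad = set(self.obs["modality"]) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modality tag(s) {sorted(bad)}; expected {MODALITIES}")
        if "time_days" not in self.obs:
            raise ValueError("metadata must contain 'time_days' (or a 'somite' column)")
        t = pd.to_numeric(self.obs["time_days"], errors="coerce")
        if t.isna().any():
            raise ValueError(
                f"{int(t.isna().sum())} cell(s) have missing/non-finite time_days"
            )
        self.obs["time_days"] = t.astype(float)
        # ATAC profiles are modeled as Bernoulli: binarize once, here.
        atac = (self.obs["modality"] == "ATAC").to_numpy()
        if atac.any() and self.counts.nnz:
            row_of_nnz = np.repeat(np.arange(n), np.diff(self.counts.indptr))
            in_atac = atac[row_of_nnz]
            self.counts.data[in_atac] = (self.counts.data[in_atac] > 0).astype(np.float64)
        self._check_pairs()

    def _check_pairs(self):
        if "pair_id" not in self.obs:
            return
        paired = self.obs[self.obs["pair_id"].notna() & (self.obs["pair_id"] != "")]
        for pid, grp in paired.groupby("pair_id"):
            mods = sorted(grp["modality"])
            if len(grp) != 2 or mods != ["ATAC", "RNA"]:
                raise ValueError(
                    f"pair_id {pid!r} must link exactly one RNA and one ATAC cell, "
                    f"got modalities {list(grp['modality'])}"
                )

    # -- convenience ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def time_days(self) -> np.ndarray:
        return self.obs["time_days"].to_numpy()

    def modality_mask(self, modality: str) -> np.ndarray:
        return (self.obs["modality"] == modality).to_numpy()

    def subset(self, idx) -> "TimeSeriesDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        ds = TimeSeriesDataset.__new__(TimeSeriesDataset)
        ds.counts = self.counts[idx]
        ds.obs = self.obs.iloc[idx].reset_index(drop=True)
        ds.var = self.var
        return ds

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    # -- I/O -----------------------------------------------------------
    def write(self, counts_path, metadata_path):
        """Write the dataset as MTX (or .h5 container) plus a metadata TSV."""
        counts_path, metadata_path = Path(counts_path), Path(metadata_path)
        if counts_path.suffix in (".h5", ".h5ad"):
            self.to_anndata().write_h5ad(counts_path)
        else:
            scipy.io.mmwrite(str(counts_path), self.counts.tocoo())
            self.var.to_csv(counts_path.with_suffix(".features.tsv"), sep="\t")
        self.obs.to_csv(metadata_path, sep="\t", index=False)

    def to_anndata(self):
        import anndata as ad

        obs = self.obs.copy()
        obs.index = obs.index.astype(str)
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=self.var.copy())


def load_dataset(counts_path, metadata_path) -> TimeSeriesDataset:
    """Read a dataset from MTX or an HDF5 (.h5/.h5ad) container + metadata TSV.

    The metadata must carry a ``modality`` column and either ``time_days``
    or ``somite`` (converted with anchor columns ``anchor_somite`` and
    ``anchor_day`` if present, else anchored at somite 0 = day 8 must be
    supplied explicitly by the caller via time_days).
    """
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    if not counts_path.exists():
        raise FileNotFoundError(counts_path)
    if not metadata_path.exists():
        raise FileNotFoundError(metadata_path)
    obs = pd.read_csv(metadata_path, sep="\t")
    if counts_path.suffix in (".h5", ".h5ad"):
        import anndata as ad

        adata = ad.read_h5ad(counts_path)
        counts, var = adata.X, adata.var
    else:
        counts = sp.csr_matrix(scipy.io.mmread(str(counts_path)))
        feat_path = counts_path.with_suffix(".features.tsv")
        var = pd.read_csv(feat_path, sep="\t", index_col=0) if feat_path.exists() else None
    if "time_days" not in obs and "somite" in obs:
        if {"anchor_somite", "anchor_day"} - set(obs.columns):
            raise ValueError(
                "somite staging requires 'anchor_somite' and 'anchor_day' columns"
            )
        obs["time_days"] = [
            somite_to_time(s, a_s, a_d)
            for s, a_s, a_d in zip(obs["somite"], obs["anchor_somite"], obs["anchor_day"])
        ]
    return TimeSeriesDataset(counts=counts, obs=obs, var=var)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test splitting policy.

    Cells at the held-out time (and condition, if given) form the test set.
    Remaining cells are split per time point 1:4 validation:train with the
    validation size capped per time point.
    """

    held_out_time: float | None = None
    held_out_condition: str | None = None
    val_fraction: float = 0.2
    val_cap_per_time: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.val_cap_per_time < 1:
            raise ValueError("val_cap_per_time must be >= 1")


def make_splits(data: TimeSeriesDataset, spec: SplitSpec):
    """Return (train_idx, val_idx, test_idx): disjoint, covering all cells.

    Deterministic given ``spec.seed``; the test set depends only on the
    hold-out definition, never on the seed.
    """
    t = data.time_days
    test_mask = np.zeros(data.n_cells, dtype=bool)
    if spec.held_out_time is not None:
        time_mask = np.isclose(t, spec.held_out_time)
        if not time_mask.any():
            raise ValueError(
                f"held_out_time={spec.held_out_time} not present in the data"
            )
        if not (~time_mask).any():
            raise ValueError("cannot hold out the only time point")
        test_mask = time_mask
        if spec.held_out_condition is not None:
            test_mask = test_mask & (data.obs["condition"] == spec.held_out_condition).to_numpy()
    elif spec.held_out_condition is not None:
        test_mask = (data.obs["condition"] == spec.held_out_condition).to_numpy()

    rng = np.random.default_rng(spec.seed)
    train, val = [], []
    remaining = np.where(~test_mask)[0]
    for tp in np.unique(t[remaining]):
        cells = remaining[np.isclose(t[remaining], tp)]
        cells = cells[rng.permutation(len(cells))]
        n_val = min(int(round(len(cells) * spec.val_fraction)), spec.val_cap_per_time)
        val.append(np.sort(cells[:n_val]))
        train.append(np.sort(cells[n_val:]))
    train_idx = np.sort(np.concatenate(train)) if train else np.array([], dtype=int)
    val_idx = np.sort(np.concatenate(val)) if val else np.array([], dtype=int)
    test_idx = np.where(test_mask)[0]
    if train_idx.size == 0:
        warnings.warn("training split is empty", stacklevel=2)
    return train_idx, val_idx, test_idx
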