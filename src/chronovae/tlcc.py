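"""Time-lagged cross-correlation between accessibility and expression.

For a peak/gene pair, predicted trajectories are compared under time
shifts: the accessibility trajectory is shifted by -delta (so a POSITIVE
best shift means the accessibility pattern precedes the expression
pattern), and the Pearson correlation is taken over a core time window.
Peaks whose accessibility consistently leads nearby transcription are
classified "before" (chromatin priming); those lagging, "after".

All coordinates are 0-based half-open; the peak-to-gene map is
strand-aware and upstream-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import predict_trajectory

__all__ = [
    "TLCCMatrix",
    "map_peaks_to_genes",
    "tlcc_vector",
    "tlcc_matrix",
    "classify_lag_direction",
]

DEFAULT_GRID = (7.5, 9.0)       # prediction interval, days
DEFAULT_CORE = (8.0, 8.5)       # correlation window, days
DEFAULT_SHIFT = (-0.5, 0.5)     # shift range, days
DEFAULT_STEP = 0.01             # grid and shift step, days


def map_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                       window: int = 200_000) -> pd.DataFrame:
    """Pair peaks with genes whose upstream window they overlap.

    ``peaks`` needs columns (chrom, start, end); ``genes`` needs
    (chrom, tss, strand). For + strand genes the window is
    [tss - window, tss); for - strand, positions (tss, tss + window]
    (half-open: [tss + 1, tss + window + 1)). Upstream only — downstream
    peaks are not paired.
    """
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("every gene needs strand '+' or '-'")
    rows = []
    for g, gene in genes.iterrows():
        tss = int(gene["tss"])
        if gene["strand"] == "+":
            w_start, w_end = tss - window, tss
        else:
            w_start, w_end = tss + 1, tss + window + 1
        on_chrom = peaks[peaks["chrom"] == gene["chrom"]]
        hit = on_chrom[(on_chrom["end"] > w_start) & (on_chrom["start"] < w_end)]
        for p in hit.index:
            rows.append({"peak": p, "gene": g})
    return pd.DataFrame(rows, columns=["peak", "gene"])


def _shift_grid(shift_range=DEFAULT_SHIFT, step=DEFAULT_STEP) -> np.ndarray:
    n = int(round((shift_range[1] - shift_range[0]) / step)) + 1
    return shift_range[0] + step * np.arange(n)


def tlcc_vector(expr_traj, acc_traj, time_grid=None, shift_range=DEFAULT_SHIFT,
                step=DEFAULT_STEP, core_window=DEFAULT_CORE):
    """Correlation-vs-shift vector for one peak/gene trajectory pair.

    Both trajectories must be sampled on the common ``time_grid`` (default:
    [7.5, 9] at 0.01-day steps), which must cover the core window expanded
    by the shift range. For shift delta, the correlation is between
    expr(t) and acc(t - delta) over t in the core window, so
    ``best_shift > 0`` means accessibility changes ahead of expression.
    Ties in the maximum go to the smallest |shift|. Returns
    (shifts, correlations, best_shift); correlations are NaN for
    constant trajectories.
    """
    expr = np.asarray(expr_traj, dtype=float)
    acc = np.asarray(acc_traj, dtype=float)
    if time_grid is None:
        time_grid = np.round(DEFAULT_GRID[0] + step * np.arange(
            int(round((DEFAULT_GRID[1] - DEFAULT_GRID[0]) / step)) + 1), 9)
    time_grid = np.asarray(time_grid, dtype=float)
    if expr.shape != time_grid.shape or acc.shape != time_grid.shape:
        raise ValueError("trajectories must be sampled on the common time grid")
    shifts = _shift_grid(shift_range, step)
    core = (time_grid >= core_window[0] - 1e-9) & (time_grid <= core_window[1] + 1e-9)
    core_idx = np.where(core)[0]
    lo_needed = core_idx[0] - int(round(max(abs(shifts[0]), abs(shifts[-1])) / step))
    hi_needed = core_idx[-1] + int(round(max(abs(shifts[0]), abs(shifts[-1])) / step))
    if lo_needed < 0 or hi_needed >= len(time_grid):
        raise ValueError("time grid must cover the core window expanded by the shifts")
    e = expr[core_idx]
    corr = np.full(len(shifts), np.nan)
    for i, delta in enumerate(shifts):
        off = int(round(delta / step))
        a = acc[core_idx - off]  # acc(t - delta)
        if np.std(e) == 0 or np.std(a) == 0:
            continue
        corr[i] = np.corrcoef(e, a)[0, 1]
    if np.all(np.isnan(corr)):
        return shifts, corr, float("nan")
    finite = np.where(np.isfinite(corr))[0]
    cmax = corr[finite].max()
    at_max = finite[np.isclose(corr[finite], cmax)]
    best = at_max[np.lexsort((shifts[at_max], np.abs(shifts[at_max])))[0]]
    return shifts, corr, float(shifts[best])


@dataclass
class TLCCMatrix:
    """Shift-by-column TLCC matrix with per-pair lag classification.

    Columns are (pair, cell) combinations surviving the correlation and
    multi-cell filters; ``summary`` is tidy with one row per surviving
    column (pair, cell, best_shift, max_corr) and ``categories`` one row
    per pair with its before/after/unclassified call.
    """

    shifts: np.ndarray
    corr: np.ndarray
    columns: pd.DataFrame
    categories: pd.DataFrame = field(default=None)


def tlcc_matrix(models, data, query_cell: int, neighbor_cells, pairs: pd.DataFrame,
                expr_traj_fn=None, acc_traj_fn=None, time_grid=None,
                shift_range=DEFAULT_SHIFT, step=DEFAULT_STEP,
                core_window=DEFAULT_CORE, min_max_corr: float = 0.5,
                min_cells: int = 2, reference_batch=None) -> TLCCMatrix:
    """TLCC matrix over a query cell plus its aggregated neighbors.

    Trajectories are ensemble medians of predicted expression (RNA) and
    accessibility (ATAC) over the default [7.5, 9] day grid, computed per
    cell. Columns (pair x cell) with maximum correlation below
    ``min_max_corr`` are dropped, then pairs surviving in fewer than
    ``min_cells`` cells are dropped entirely.

    ``expr_traj_fn(cell) -> (time x genes)`` and ``acc_traj_fn(cell)`` can
    override prediction (e.g. for generator-direct trajectories).
    """
    if time_grid is None:
        time_grid = np.round(DEFAULT_GRID[0] + step * np.arange(
            int(round((DEFAULT_GRID[1] - DEFAULT_GRID[0]) / step)) + 1), 9)
    cells = [int(query_cell)] + [int(c) for c in neighbor_cells]

    def _median_traj(cell, modality):
        mats = [predict_trajectory(m, data, cell, time_grid, target_modality=modality,
                                   reference_batch=reference_batch) for m in models]
        return np.median(np.stack(mats, axis=0), axis=0)

    expr_traj_fn = expr_traj_fn or (lambda c: _median_traj(c, "RNA"))
    acc_traj_fn = acc_traj_fn or (lambda c: _median_traj(c, "ATAC"))

    shifts = _shift_grid(shift_range, step)
    cols, mat = [], []
    for cell in cells:
        expr = expr_traj_fn(cell)
        acc = acc_traj_fn(cell)
        for _, row in pairs.iterrows():
            _, corr, best = tlcc_vector(expr[:, int(row["gene"])],
                                        acc[:, int(row["peak"])],
                                        time_grid=time_grid, shift_range=shift_range,
                                        step=step, core_window=core_window)
            cmax = np.nanmax(corr) if np.any(np.isfinite(corr)) else np.nan
            if not np.isfinite(cmax) or cmax < min_max_corr:
                continue
            cols.append({"peak": int(row["peak"]), "gene": int(row["gene"]),
                         "cell": cell, "best_shift": best, "max_corr": float(cmax)})
            mat.append(corr)
    columns = pd.DataFrame(cols, columns=["peak", "gene", "cell", "best_shift", "max_corr"])
    if columns.empty:
        warnings.warn("no (pair, cell) column survives the correlation filter")
        return TLCCMatrix(shifts=shifts, corr=np.empty((len(shifts), 0)),
                          columns=columns, categories=pd.DataFrame(
                              columns=["peak", "gene", "category"]))
    keep_pairs = (columns.groupby(["peak", "gene"])["cell"].nunique() >= min_cells)
    keep_pairs = set(keep_pairs[keep_pairs].index)
    keep_mask = columns.apply(lambda r: (r["peak"], r["gene"]) in keep_pairs, axis=1)
    columns = columns[keep_mask.to_numpy()].reset_index(drop=True)
    mat = np.column_stack([m for m, k in zip(mat, keep_mask) if k]) \
        if keep_mask.any() else np.empty((len(shifts), 0))
    out = TLCCMatrix(shifts=shifts, corr=mat, columns=columns)
    out.categories = classify_lag_direction(out)
    return out


def classify_lag_direction(matrix: TLCCMatrix) -> pd.DataFrame:
    """Per-pair before/after call from per-cell best shifts.

    "before": best shift > 0 in every surviving cell (accessibility leads
    expression everywhere); "after": < 0 in every cell; otherwise
    "unclassified".
    """
    rows = []
    for (peak, gene), grp in matrix.columns.groupby(["peak", "gene"]):
        s = grp["best_shift"].to_numpy()
        if np.all(s > 0):
            cat = "before"
        elif np.all(s < 0):
            cat = "after"
        else:
            cat = "unclassified"
        rows.append({"peak": peak, "gene": gene, "category": cat,
                     "median_best_shift": float(np.median(s)), "n_cells": len(grp)})
    return pd.DataFrame(rows, columns=["peak", "gene", "category",
                                       "median_best_shift", "n_cells"])
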