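"""Shared statistics and the model-selection / evaluation harness.

Includes the normalized Wilcoxon signed-rank effect score (0.5 under
exchangeable signs), depth-normalized pseudobulk profiles, a local
inverse Simpson index (LISI) for embedding mixing, AUROC, BH-FDR, the
rank-sum hyperparameter selection over the default grid, and the
held-out-time / held-out-condition evaluation procedures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .data import TimeSeriesDataset
from .inference import predict_profiles
from .models import LAMBDA_GRID, LATENT_GRID, WAVELENGTH_GRID

__all__ = [
    "signed_rank_score",
    "pseudobulk_profile",
    "lisi_score",
    "auroc",
    "bh_fdr",
    "hyperparameter_grid",
    "select_model",
    "evaluate_cross_time",
    "evaluate_peakwise",
    "differential_direction_score",
    "EvalReport",
]


def signed_rank_score(paired_diffs) -> float:
    """Normalized Wilcoxon W+ of paired differences, in [0, 1].

    Zero differences are dropped (classic signed-rank convention);
    absolute differences get average ranks on ties. Returns NaN when all
    differences are zero. 1 = all positive, 0 = all negative, 0.5 =
    exchangeable signs.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return float("nan")
    ranks = sps.rankdata(np.abs(d))
    n = d.size
    return float(ranks[d > 0].sum() / (n * (n + 1) / 2.0))


def pseudobulk_profile(counts) -> np.ndarray:
    """Mean of depth-normalized cell profiles; output sums to 1.

    Cells with zero total count are excluded with a warning.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    depth = X.sum(axis=1)
    keep = depth > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-depth cell(s) from pseudobulk")
    if not keep.any():
        raise ValueError("no cells with positive depth")
    return (X[keep] / depth[keep, None]).mean(axis=0)


def lisi_score(embeddings, labels, perplexity: float = 30.0, max_neighbors: int = 90):
    """Local inverse Simpson index per cell, plus its mean.

    For each cell, neighbor weights use a Gaussian kernel whose bandwidth
    is tuned by binary search so the weight entropy matches
    log(perplexity); the score is the inverse Simpson index of the label
    distribution under those weights, in [1, #levels]. Higher values mean
    better label mixing in the embedding neighborhood.
    """
    X = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of cells ({n})")
    levels, lab_idx = np.unique(labels, return_inverse=True)
    k = int(min(max_neighbors, 3 * perplexity, n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    target = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        lo, hi, beta = 0.0, np.inf, 1.0
        for _ in range(64):
            w = np.exp(-beta * (d2 - d2.min()))
            s = w.sum()
            p = w / s
            h = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(h - target) < 1e-5:
                break
            if h > target:  # too flat -> sharpen
                lo, beta = beta, beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
            else:
                hi, beta = beta, (lo + beta) / 2
        probs = np.bincount(lab_idx[idx[i]], weights=p, minlength=len(levels))
        simpson = float((probs**2).sum())
        scores[i] = 1.0 / max(simpson, 1e-12)
    return scores, float(scores.mean())


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC (ties counted 1/2); NaN if one class is absent."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------

def hyperparameter_grid(latent_dims=LATENT_GRID, min_wavelengths=WAVELENGTH_GRID,
                        lambdas=LAMBDA_GRID, multimodal: bool = True):
    """Enumerate the default hyperparameter grid as parameter dicts.

    Defaults: latent in {25, 50, 100} x min wavelength in {1, 2*pi}
    (x lambda_mse in {1, 100, 10000} for the multimodal model) = 18
    configurations.
    """
    grid = []
    for ld, wl in itertools.product(latent_dims, min_wavelengths):
        if multimodal:
            for lam in lambdas:
                grid.append({"latent_dim": ld, "min_wavelength": wl, "lambda_mse": lam})
        else:
            grid.append({"latent_dim": ld, "min_wavelength": wl})
    return grid


def select_model(grid_results: pd.DataFrame, higher_better=None):
    """Pick the config with the smallest summed criterion rank.

    ``grid_results``: one row per configuration; metric columns are ranked
    per criterion (direction given by ``higher_better``, a dict defaulting
    to True except for columns containing "loss"). Ties in the summed rank
    are broken by row order. Returns the index of the winning row.
    """
    metrics = [c for c in grid_results.columns
               if np.issubdtype(grid_results[c].dtype, np.number)]
    if not metrics:
        raise ValueError("no numeric metric columns to rank")
    if grid_results[metrics].isna().any().any():
        raise ValueError("inconsistent metric sets: NaN metric for some configuration")
    total = np.zeros(len(grid_results))
    for c in metrics:
        hb = (higher_better or {}).get(c, "loss" not in c)
        vals = grid_results[c].to_numpy(dtype=float)
        total += sps.rankdata(-vals if hb else vals, method="average")
    best = int(np.argmin(total))  # argmin is first on ties -> row order
    return grid_results.index[best]


# ---------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------

@dataclass
class EvalReport:
    """Tidy evaluation tables: per cell type (cross-time) or per peak."""

    per_group: pd.DataFrame
    pvalue: float = float("nan")
    extras: dict = field(default_factory=dict)


def _neighbor_times(times, held_out_time):
    times = np.asarray(sorted(set(np.round(times, 9))))
    below = times[times < held_out_time - 1e-9]
    above = times[times > held_out_time + 1e-9]
    prev_t = below.max() if below.size else None
    next_t = above.min() if above.size else None
    return prev_t, next_t


def evaluate_cross_time(model, data: TimeSeriesDataset, held_out_time: float,
                        query_side: str = "previous", condition_mode: str = "same",
                        baseline_mode: str = "neighbor", min_cells: int = 25,
                        held_out_condition=None, models=None) -> EvalReport:
    """Held-out-time pseudobulk evaluation against neighbor baselines.

    For each cell type with >= ``min_cells`` held-out cells, predict the
    held-out pseudobulk by factor-swapping query cells from the previous
    or subsequent time point (optionally from the opposite sex), and
    compare its Pearson correlation with the held-out truth to that of a
    baseline: the query time point's own pseudobulk, or the mean of the
    previous and subsequent pseudobulks. A one-sided paired signed-rank
    p-value across cell types is reported.
    """
    if "cell_type" not in data.obs:
        raise ValueError("evaluation requires cell_type labels")
    modality = getattr(model, "modality", "RNA")
    mod_mask = data.modality_mask(modality)
    t = data.time_days
    prev_t, next_t = _neighbor_times(t[mod_mask], held_out_time)
    query_t = prev_t if query_side == "previous" else next_t
    if query_t is None:
        raise ValueError(f"no {query_side} time point relative to {held_out_time}")

    cond = data.obs["condition"].to_numpy()
    held_mask = mod_mask & np.isclose(t, held_out_time)
    if held_out_condition is not None:
        held_mask &= cond == str(held_out_condition)
    rows = []
    pred_fn = predict_profiles if models is None else None
    for ct in sorted(data.obs.loc[held_mask, "cell_type"].dropna().unique()):
        ct_mask = (data.obs["cell_type"] == ct).to_numpy()
        held = np.where(held_mask & ct_mask)[0]
        if held.size < min_cells:
            continue
        qmask = mod_mask & ct_mask & np.isclose(t, query_t)
        if held_out_condition is not None:
            if condition_mode == "opposite":
                qmask &= cond != str(held_out_condition)
            else:
                qmask &= cond == str(held_out_condition)
        query = np.where(qmask)[0]
        if query.size == 0:
            continue
        truth = pseudobulk_profile(data.counts[held].toarray())
        target_cond = str(held_out_condition) if held_out_condition is not None else None
        if models is not None:
            from .inference import ensemble_median

            pred_cells = ensemble_median(models, data, query, held_out_time,
                                         target_condition=target_cond)
        else:
            pred_cells = pred_fn(model, data, query, held_out_time,
                                 target_condition=target_cond)
        pred = pred_cells.mean(axis=0)  # predictions are already depth-normalized
        if baseline_mode == "neighbor":
            base = pseudobulk_profile(data.counts[query].toarray())
        else:  # mean of previous and subsequent pseudobulks
            parts = []
            for tt in (prev_t, next_t):
                if tt is None:
                    continue
                m = mod_mask & ct_mask & np.isclose(t, tt)
                if condition_mode == "opposite" and held_out_condition is not None:
                    m &= cond != str(held_out_condition)
                if m.any():
                    parts.append(pseudobulk_profile(data.counts[m].toarray()))
            if not parts:
                continue
            base = np.mean(parts, axis=0)
        rows.append({
            "cell_type": ct,
            "held_out_time": held_out_time,
            "query_side": query_side,
            "n_held_out": int(held.size),
            "prediction_score": float(np.corrcoef(pred, truth)[0, 1]),
            "baseline_score": float(np.corrcoef(base, truth)[0, 1]),
        })
    per_group = pd.DataFrame(rows)
    if per_group.empty:
        warnings.warn("no cell type meets the minimum held-out cell count")
        return EvalReport(per_group=per_group)
    diffs = per_group["prediction_score"] - per_group["baseline_score"]
    pval = float("nan")
    if len(diffs) >= 1 and np.any(diffs != 0):
        pval = float(sps.wilcoxon(diffs, alternative="greater").pvalue)
    return EvalReport(per_group=per_group, pvalue=pval)


def evaluate_peakwise(predicted_atac, true_atac, min_accessible_frac: float = 0.05,
                      fdr_threshold: float = 0.05) -> EvalReport:
    """Per-peak AUROC and rank-sum test of predicted vs. binary accessibility.

    Peaks accessible in <= ``min_accessible_frac`` of cells are excluded.
    For each kept peak, AUROC of predicted probabilities against the
    binary truth across cells, plus a one-sided rank-sum p (predicted
    higher in accessible cells); BH over kept peaks, reporting the
    fraction with FDR <= ``fdr_threshold``.
    """
    pred = np.asarray(predicted_atac, dtype=float)
    true = (np.asarray(true_atac) > 0).astype(int)
    if pred.shape != true.shape:
        raise ValueError("predicted and true matrices must share a cell set and shape")
    frac = true.mean(axis=0)
    keep = np.where(frac > min_accessible_frac)[0]
    if keep.size == 0:
        raise ValueError("no peaks pass the accessibility filter")
    rows = []
    for j in keep:
        y = true[:, j]
        if y.min() == y.max():
            continue
        a = auroc(pred[:, j], y)
        p = sps.mannwhitneyu(pred[y == 1, j], pred[y == 0, j],
                             alternative="greater").pvalue
        rows.append({"peak": int(j), "accessible_frac": float(frac[j]),
                     "auroc": a, "p": float(p)})
    per_peak = pd.DataFrame(rows)
    per_peak["q"] = bh_fdr(per_peak["p"].to_numpy())
    per_peak["significant"] = per_peak["q"] <= fdr_threshold
    frac_sig = float(per_peak["significant"].mean())
    return EvalReport(per_group=per_peak,
                      extras={"fraction_fdr_significant": frac_sig,
                              "mean_auroc": float(per_peak["auroc"].mean())})


def differential_expression(counts_a, counts_b, min_expressed_frac: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sample DE on depth-corrected, log-normalized profiles.

    Counts are normalized to counts-per-10k, log1p-transformed, and
    compared with a Welch t-test (group a vs. group b, e.g. female vs.
    male cells at one time point). Genes expressed in fewer than
    ``min_expressed_frac`` of all cells are excluded (``kept`` = False,
    statistics NaN). Returns a tidy frame with t statistic, p, BH q and
    the mean log-normalized difference (a - b).
    """
    Xa = np.asarray(counts_a, dtype=float)
    Xb = np.asarray(counts_b, dtype=float)
    if Xa.ndim != 2 or Xb.ndim != 2 or Xa.shape[1] != Xb.shape[1]:
        raise ValueError("need two cells x genes matrices over the same genes")
    expressed = (np.vstack([Xa, Xb]) > 0).mean(axis=0)
    kept = expressed >= min_expressed_frac

    def norm(X):
        depth = np.maximum(X.sum(axis=1, keepdims=True), 1.0)
        return np.log1p(X / depth * 1e4)

    La, Lb = norm(Xa), norm(Xb)
    t_stat = np.full(Xa.shape[1], np.nan)
    p = np.full(Xa.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_kept, p_kept = sps.ttest_ind(La[:, kept], Lb[:, kept], equal_var=False)
    t_stat[kept], p[kept] = t_kept, np.where(np.isfinite(p_kept), p_kept, 1.0)
    q = np.full(Xa.shape[1], np.nan)
    if kept.any():
        q[kept] = bh_fdr(np.nan_to_num(p[kept], nan=1.0))
    return pd.DataFrame({"t": t_stat, "p": p, "q": q,
                         "mean_diff": La.mean(axis=0) - Lb.mean(axis=0),
                         "kept": kept})


def differential_direction_score(predicted_t1, predicted_t2) -> np.ndarray:
    """Per-peak signed-rank score of paired (t2 - t1) changes across cells.

    Accepts single (cells x peaks) matrices or lists of them (one per
    ensemble member), in which case the per-peak median score across the
    ensemble is returned. Scores > 0.5 mean accessibility increases from
    t1 to t2.
    """
    if isinstance(predicted_t1, (list, tuple)):
        per_model = [differential_direction_score(a, b)
                     for a, b in zip(predicted_t1, predicted_t2)]
        return np.nanmedian(np.stack(per_model, axis=0), axis=0)
    a = np.asarray(predicted_t1, dtype=float)
    b = np.asarray(predicted_t2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matched cell sets required")
    d = b - a
    return np.array([signed_rank_score(d[:, j]) for j in range(d.shape[1])])
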