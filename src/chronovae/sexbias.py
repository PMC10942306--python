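"""Sex-biased transcription scoring and downstream gene-set statistics.

Because most developmental time points are profiled in only one sex,
direct differential expression between sexes is impossible. Instead,
each cell's denoised profile is predicted under BOTH sexes by swapping
the condition factor of a trained ensemble, and a per-gene sex-biased
score in [0, 1] is computed as the normalized Wilcoxon signed-rank
statistic of the per-cell (female - male) predicted differences
(0.5 = no bias, 1 = strongly female-biased, 0 = strongly male-biased).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import TimeSeriesDataset
from .inference import ensemble_median
from .stats import bh_fdr, signed_rank_score

__all__ = [
    "CONSTITUTIVE_ESCAPE_GENES",
    "compute_sexbias_table",
    "consistent_bias_genes",
    "geneset_shift_test",
    "ppi_odds_ratio_test",
    "hypergeometric_enrichment",
]

# Genes known to escape X inactivation in most/all mouse tissues; expected
# female-biased. Used for real-data validation; synthetic tests plant their own.
CONSTITUTIVE_ESCAPE_GENES = (
    "Ddx3x", "Kdm6a", "Kdm5c", "Eif2s3x", "Pbdc1", "Jpx", "Ftx", "5530601H04Rik",
)


def compute_sexbias_table(models, data: TimeSeriesDataset, cell_types=None,
                          time_points=None, female: str = "F", male: str = "M",
                          min_pooled_cells: int = 50, pool_neighbors: bool = True,
                          reference_batch=None) -> pd.DataFrame:
    """Per-(gene, cell type, time point) sex-biased scores from an ensemble.

    For every RNA cell, predict its denoised profile under both sexes at
    its own time (ensemble median across models). For each cell type and
    time point, cells from the current, previous and subsequent time
    points are pooled; the per-gene score is the signed-rank score of the
    pooled per-cell (F - M) differences, reported only when the pool
    exceeds ``min_pooled_cells`` cells. Predicted mean expression per sex
    is included for downstream expression filtering.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    levels = models[0].condition_levels_
    for sex in (female, male):
        if sex not in levels:
            raise ValueError(f"sex level {sex!r} unknown to the model; known: {levels}")
    if "cell_type" not in data.obs:
        raise ValueError("cell_type labels are required to group the scores")
    rna = np.where(data.modality_mask("RNA"))[0]
    obs = data.obs.iloc[rna]
    times = np.asarray(sorted(obs["time_days"].round(9).unique()))
    if time_points is None:
        time_points = times
    if cell_types is None:
        cell_types = sorted(obs["cell_type"].dropna().unique())

    # predict each cell under both sexes, one time point at a time so the
    # decoder sees the cell's own collection time
    pred = {}
    for sex in (female, male):
        mats = np.zeros((len(rna), data.n_features))
        for tp in times:
            m = np.isclose(obs["time_days"].to_numpy(), tp)
            cells = rna[m]
            mats[m] = ensemble_median(models, data, cells, tp, target_condition=sex,
                                      reference_batch=reference_batch)
        pred[sex] = mats

    genes = np.asarray(data.var.index)
    rows = []
    t_arr = obs["time_days"].to_numpy()
    ct_arr = obs["cell_type"].to_numpy()
    for ct in cell_types:
        for ti, tp in enumerate(time_points):
            here = np.isclose(t_arr, tp) & (ct_arr == ct)
            pool = here.copy()
            if pool_neighbors:
                for tj in (ti - 1, ti + 1):
                    if 0 <= tj < len(time_points):
                        pool |= np.isclose(t_arr, time_points[tj]) & (ct_arr == ct)
            n_pool = int(pool.sum())
            dF = pred[female][pool]
            dM = pred[male][pool]
            diffs = dF - dM
            mean_f, mean_m = dF.mean(axis=0) if n_pool else np.full(len(genes), np.nan), \
                             dM.mean(axis=0) if n_pool else np.full(len(genes), np.nan)
            if n_pool > min_pooled_cells:
                scores = np.array([signed_rank_score(diffs[:, j])
                                   for j in range(diffs.shape[1])])
            else:
                scores = np.full(len(genes), np.nan)
            rows.append(pd.DataFrame({
                "gene": genes, "cell_type": ct, "time_days": tp,
                "score": scores, "n_cells": int(here.sum()), "n_pooled": n_pool,
                "mean_expr_F": mean_f, "mean_expr_M": mean_m,
            }))
    return pd.concat(rows, ignore_index=True)


def consistent_bias_genes(table: pd.DataFrame, cell_type: str,
                          min_cells_per_time: int = 25):
    """Genes consistently female- or male-biased across all qualifying times.

    Qualifying time points have more than ``min_cells_per_time`` cells of
    the cell type. Genes must sit in the top half by predicted mean
    expression (averaged over sexes) at EVERY qualifying time point;
    the female set then requires score > 0.5 at all of them, the male
    set score < 0.5 at all.
    """
    sub = table[table["cell_type"] == cell_type]
    qual_times = sorted(sub.loc[sub["n_cells"] > min_cells_per_time, "time_days"].unique())
    if not qual_times:
        warnings.warn(f"no qualifying time points for cell type {cell_type!r}")
        return set(), set()
    female, male, expressed = None, None, None
    for tp in qual_times:
        rows = sub[np.isclose(sub["time_days"], tp)].set_index("gene")
        mean_expr = (rows["mean_expr_F"] + rows["mean_expr_M"]) / 2.0
        top_half = set(mean_expr.sort_values(ascending=False)
                       .index[: int(np.ceil(len(mean_expr) / 2))])
        scr = rows["score"].dropna()
        f_here = set(scr[scr > 0.5].index)
        m_here = set(scr[scr < 0.5].index)
        expressed = top_half if expressed is None else expressed & top_half
        female = f_here if female is None else female & f_here
        male = m_here if male is None else male & m_here
    return female & expressed, male & expressed


def geneset_shift_test(scores_by_gene, set_a, set_b) -> float:
    """One-sided Mann-Whitney p that genes in ``set_a`` score above ``set_b``.

    Exact enumeration of all rank assignments (including tie mass) when
    the combined size is <= 12; normal approximation otherwise.
    """
    scores = pd.Series(scores_by_gene).dropna()
    a = scores[scores.index.isin(set(set_a))].to_numpy(dtype=float)
    b = scores[scores.index.isin(set(set_b))].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both gene sets must intersect the scored genes")
    if a.size + b.size <= 12:
        return _exact_ranksum_p(a, b)
    return float(sps.mannwhitneyu(a, b, alternative="greater").pvalue)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """P(rank sum of a random |a|-subset >= observed) over all subsets."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    obs = ranks[: a.size].sum()
    count = total = 0
    for comb in combinations(range(pooled.size), a.size):
        total += 1
        if ranks[list(comb)].sum() >= obs - 1e-12:
            count += 1
    return count / total


def ppi_odds_ratio_test(edges, female_autosomal, female_xlinked,
                        autosomal_universe, n_perm: int = 100, seed: int = 0,
                        min_edges: int = 50):
    """Odds ratio of interactions between female-biased autosomal and X-linked
    genes, with a permutation p-value.

    The 2x2 table contrasts edges vs non-edges among (candidate autosomal
    x female X-linked) pairs against (other autosomal x female X-linked)
    pairs, with a Haldane-Anscombe 0.5 correction when any cell is zero.
    The null redraws the candidate set from the autosomal universe
    ``n_perm`` times; p = (#null >= observed + 1) / (n_perm + 1). The
    p-value is reported as NaN (test skipped) when fewer than
    ``min_edges`` relevant interactions exist.
    """
    fa = set(female_autosomal)
    fx = set(female_xlinked)
    universe = sorted(set(autosomal_universe))
    if not universe:
        raise ValueError("autosomal universe must be nonempty")
    if fa & fx:
        raise ValueError("autosomal and X-linked sets must be disjoint")
    adj = set()
    for u, v in edges:
        if u != v:
            adj.add((min(u, v), max(u, v)))

    def _or(candidates: set) -> tuple[float, int]:
        other = set(universe) - candidates
        e1 = sum(1 for u, v in adj
                 if (u in candidates and v in fx) or (v in candidates and u in fx))
        e2 = sum(1 for u, v in adj
                 if (u in other and v in fx) or (v in other and u in fx))
        n1 = len(candidates) * len(fx) - e1
        n2 = len(other) * len(fx) - e2
        cells = np.array([e1, n1, e2, n2], dtype=float)
        if np.any(cells == 0):
            cells = cells + 0.5
        return float((cells[0] / cells[1]) / (cells[2] / cells[3])), e1 + e2

    observed, n_edges = _or(fa)
    if n_edges < min_edges:
        warnings.warn(f"only {n_edges} relevant interaction(s) (< {min_edges}); "
                      "permutation test skipped")
        return observed, float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        null_set = set(rng.choice(universe, size=len(fa), replace=False))
        if _or(null_set)[0] >= observed:
            count += 1
    return observed, (count + 1) / (n_perm + 1)


def hypergeometric_enrichment(study_set, term_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a study set in named term sets.

    Returns one row per term with the overlap, p-value and BH q-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    study = set(study_set) & universe
    if set(study_set) - universe:
        raise ValueError("study_set must be a subset of the universe")
    N, n = len(universe), len(study)
    rows = []
    for name, genes in term_sets.items():
        term = set(genes) & universe
        k = len(study & term)
        p = float(sps.hypergeom.sf(k - 1, N, len(term), n))
        rows.append({"term": name, "term_size": len(term), "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out
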