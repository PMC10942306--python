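"""Factor-swapping prediction of denoised profiles.

A trained model decomposes each cell into a cell-identity embedding plus
time/condition/batch factors. Prediction encodes a query cell with its
OWN observed covariates (posterior mean, no sampling — deterministic),
then decodes with the requested target time, condition and modality.
RNA predictions are depth-normalized expected proportions (sum to 1);
ATAC predictions are accessibility probabilities in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import TimeSeriesDataset
from .models import MultimodalTemporalVAE, TemporalVAE

__all__ = [
    "PredictedProfile",
    "predict_profile",
    "predict_profiles",
    "predict_trajectory",
    "ensemble_median",
    "aggregate_neighbors",
]


@dataclass
class PredictedProfile:
    values: np.ndarray
    query_cell: int
    target_time: float
    target_condition: str
    target_modality: str


def _default_modality(model):
    return "RNA" if isinstance(model, TemporalVAE) else "ATAC"


def predict_profiles(model, data: TimeSeriesDataset, cells, target_time,
                     target_condition=None, target_modality=None,
                     reference_batch=None) -> np.ndarray:
    """Vectorized factor-swapping prediction for several query cells.

    Each cell is encoded under its observed covariates; the decoder then
    receives the target time encoding, the target condition one-hot
    (default: each cell's own condition) and a fixed reference batch
    (default: first batch level). Returns a (cells x features) matrix.
    """
    cells = np.atleast_1d(np.asarray(cells))
    if target_modality is None:
        target_modality = _default_modality(model)
    if reference_batch is None:
        reference_batch = model.batch_levels_[0]
    z = model.transform(data, cells)
    if target_condition is None:
        conds = data.obs["condition"].iloc[cells].to_numpy(dtype=object)
    else:
        if str(target_condition) not in model.condition_levels_:
            raise ValueError(
                f"unknown condition {target_condition!r}; known: {model.condition_levels_}"
            )
        conds = np.full(len(cells), str(target_condition), dtype=object)
    if isinstance(model, MultimodalTemporalVAE):
        return model.decode(z, target_time, conds, reference_batch,
                            target_modality=target_modality)
    if target_modality != model.modality:
        raise ValueError(
            f"single-modality model ({model.modality}) cannot decode {target_modality}"
        )
    return model.decode(z, target_time, conds, reference_batch)


def predict_profile(model, data: TimeSeriesDataset, cell: int, target_time,
                    target_condition=None, target_modality=None,
                    reference_batch=None) -> PredictedProfile:
    """Single-cell wrapper around :func:`predict_profiles`."""
    if target_modality is None:
        target_modality = _default_modality(model)
    vals = predict_profiles(model, data, [cell], target_time, target_condition,
                            target_modality, reference_batch)[0]
    cond = (data.obs["condition"].iloc[cell] if target_condition is None
            else str(target_condition))
    return PredictedProfile(values=vals, query_cell=int(cell),
                            target_time=float(target_time),
                            target_condition=cond, target_modality=target_modality)


def predict_trajectory(model, data: TimeSeriesDataset, cell: int, time_grid,
                       target_modality=None, target_condition=None,
                       reference_batch=None) -> np.ndarray:
    """Predicted profile of one cell at every time on an increasing grid.

    Returns a (len(time_grid) x features) matrix; row t is the
    factor-swapped prediction at time_grid[t]. The cell identity factor
    is encoded once, so rows vary smoothly with the time encoding.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise ValueError("time_grid must be nonempty")
    if not np.all(np.isfinite(time_grid)) or np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be finite and strictly increasing")
    if target_modality is None:
        target_modality = _default_modality(model)
    if reference_batch is None:
        reference_batch = model.batch_levels_[0]
    z = model.transform(data, [cell])
    zz = np.repeat(z, len(time_grid), axis=0)
    cond = (data.obs["condition"].iloc[cell] if target_condition is None
            else str(target_condition))
    if isinstance(model, MultimodalTemporalVAE):
        return model.decode(zz, time_grid, cond, reference_batch,
                            target_modality=target_modality)
    return model.decode(zz, time_grid, cond, reference_batch)


def ensemble_median(models, data: TimeSeriesDataset, cells, target_time,
                    target_condition=None, target_modality=None,
                    reference_batch=None) -> np.ndarray:
    """Element-wise median of per-model predictions across an ensemble."""
    if len(models) == 0:
        raise ValueError("need at least one model")
    ref = np.asarray(models[0].feature_ids_)
    for m in models[1:]:
        if not np.array_equal(np.asarray(m.feature_ids_), ref):
            raise ValueError("ensemble models must share an identical feature space")
    preds = [predict_profiles(m, data, cells, target_time, target_condition,
                              target_modality, reference_batch) for m in models]
    return np.median(np.stack(preds, axis=0), axis=0)


def aggregate_neighbors(per_model_embeddings, query_cell: int, k_list: int = 25,
                        k_keep: int = 4):
    """Robust nearest neighbors of a query cell across an ensemble.

    Per model, candidates are ranked by Euclidean distance to the query
    (rank 1 = closest) and only the top ``k_list`` kept; a cell absent
    from any model's top list is excluded. Survivors are ordered by
    summed rank (ties broken by cell index) and the best ``k_keep``
    returned.
    """
    if len(per_model_embeddings) == 0:
        raise ValueError("need embeddings from at least one model")
    rank_maps = []
    for emb in per_model_embeddings:
        emb = np.asarray(emb)
        d = np.linalg.norm(emb - emb[query_cell], axis=1)
        order = [i for i in np.argsort(d, kind="stable") if i != query_cell]
        rank_maps.append({int(c): r + 1 for r, c in enumerate(order[:k_list])})
    survivors = set(rank_maps[0])
    for rm in rank_maps[1:]:
        survivors &= set(rm)
    scored = sorted((sum(rm[c] for rm in rank_maps), c) for c in survivors)
    if len(scored) < k_keep:
        warnings.warn(
            f"only {len(scored)} neighbor(s) survive the top-{k_list} filter "
            f"(requested {k_keep})")
    return np.array([c for _, c in scored[:k_keep]], dtype=int)
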