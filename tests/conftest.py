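"""Shared fixtures: synthetic datasets and trained model ensembles.

Training fixtures are session-scoped because fitting even the desk-scale
models dominates suite runtime; every downstream test reuses them
read-only. All randomness is seeded, so the suite is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from chronovae import (
    MultimodalTemporalVAE,
    TemporalVAE,
    default_acceptance_spec,
    simulate_multiomic_timeseries,
)
from chronovae.data import SplitSpec, make_splits

# desk-scale network: small enough to train in seconds on one CPU, large
# enough for the planted effects to be recovered
RNA_KW = dict(latent_dim=16, hidden_width=128, time_dim=32, kl_weight=0.5,
              max_epochs=80, patience=10)
MM_KW = dict(latent_dim=16, hidden_width=128, time_dim=32, kl_weight=0.5,
             lambda_mse=100.0, max_epochs=60, patience=10)

RNA_HELD_OUT = {1: 8.25, 2: 8.5, 3: 8.75}  # seed -> held-out time
MM_HELD_OUT_TIME = 8.5


@pytest.fixture(scope="session")
def tiny_sim():
    """Tiny synthetic multi-omic time series with planted ground truth."""
    spec = default_acceptance_spec("tiny", seed=1)
    data, truth = simulate_multiomic_timeseries(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def rna_ensemble(tiny_sim):
    """Three single-modality models, each with a different held-out time."""
    _, data, _ = tiny_sim
    models = {}
    for seed, held in RNA_HELD_OUT.items():
        splits = make_splits(data, SplitSpec(held_out_time=held, seed=seed))
        models[seed] = (
            TemporalVAE(seed=seed, **RNA_KW).fit(data, splits=splits),
            splits,
            held,
        )
    return models


@pytest.fixture(scope="session")
def mm_heldout_ensemble(tiny_sim):
    """Three multimodal models with one time point held out entirely."""
    _, data, _ = tiny_sim
    models = []
    for seed in (1, 2, 3):
        splits = make_splits(data, SplitSpec(held_out_time=MM_HELD_OUT_TIME, seed=seed))
        models.append(MultimodalTemporalVAE(seed=seed, **MM_KW).fit(data, splits=splits))
    return models


@pytest.fixture(scope="session")
def mm_full_ensemble(tiny_sim):
    """Three multimodal models trained on all time points (for TLCC)."""
    _, data, _ = tiny_sim
    models = []
    for seed in (1, 2, 3):
        splits = make_splits(data, SplitSpec(seed=seed))
        models.append(MultimodalTemporalVAE(seed=seed, **MM_KW).fit(data, splits=splits))
    return models


@pytest.fixture(scope="session")
def sex_heldout_models(tiny_sim):
    """Models trained with the male sample held out at one time point,
    mimicking validation of sex-difference prediction when only one sex
    is profiled."""
    _, data, _ = tiny_sim
    models = []
    for seed in (1, 2, 3):
        splits = make_splits(data, SplitSpec(held_out_time=8.5,
                                             held_out_condition="M", seed=seed))
        models.append(TemporalVAE(seed=seed, **RNA_KW).fit(data, splits=splits))
    return models


@pytest.fixture(scope="session")
def adversary_probe(tiny_sim):
    """Time-probe accuracies of matched adversarial / non-adversarial runs."""
    from sklearn.linear_model import LogisticRegression

    _, data, _ = tiny_sim
    kw = dict(latent_dim=16, hidden_width=64, time_dim=32, kl_weight=0.5,
              max_epochs=40, patience=8)

    def probe_accuracy(model, splits):
        rna = data.modality_mask("RNA")
        tr = splits[0][rna[splits[0]]]
        va = splits[1][rna[splits[1]]]
        ztr, zva = model.transform(data, tr), model.transform(data, va)
        ytr = np.searchsorted(model.time_grid_, np.round(data.time_days[tr], 6))
        yva = np.searchsorted(model.time_grid_, np.round(data.time_days[va], 6))
        clf = LogisticRegression(max_iter=500).fit(ztr, ytr)
        return float(clf.score(zva, yva))

    out = []
    for seed in (1, 2, 3):
        splits = make_splits(data, SplitSpec(seed=seed))
        row = {"seed": seed}
        for adv in (True, False):
            model = TemporalVAE(seed=seed, adversarial=adv, **kw).fit(data, splits=splits)
            row["adv" if adv else "noadv"] = probe_accuracy(model, splits)
            row[("model_adv" if adv else "model_noadv")] = model
            row[("splits")] = splits
        out.append(row)
    return out
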