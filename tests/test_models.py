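"""Loss identities, training contracts and adversarial behavior."""

import numpy as np
import pandas as pd
import pytest

from chronovae import (
    MultimodalTemporalVAE,
    TemporalVAE,
    TimeSeriesDataset,
    kl_gaussian,
    zinb_loglik,
    bernoulli_loglik,
)
from chronovae.data import SplitSpec, make_splits
from chronovae.encodings import sinusoidal_encode, encode_categories
from chronovae.models import _ce_t, _time_class
from chronovae import _autodiff as ad


def _tiny_rna_dataset(n_per_time=40, n_genes=12, times=(8.0, 8.5, 9.0), seed=0):
    rng = np.random.default_rng(seed)
    rows, counts = [], []
    for t in times:
        counts.append(rng.poisson(4.0, size=(n_per_time, n_genes)))
        rows.append(pd.DataFrame({
            "time_days": [t] * n_per_time,
            "condition": ["F", "M"] * (n_per_time // 2),
            "batch": ["b0"] * n_per_time,
            "modality": ["RNA"] * n_per_time,
        }))
    return TimeSeriesDataset(counts=np.vstack(counts), obs=pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="module")
def small_model():
    data = _tiny_rna_dataset()
    splits = make_splits(data, SplitSpec(seed=0))
    model = TemporalVAE(latent_dim=6, hidden_width=16, time_dim=8, max_epochs=3,
                        patience=3, batch_size=64, seed=0).fit(data, splits=splits)
    return model, data, splits


def _batch_for(model, data, idx):
    sub = data.subset(idx)
    X = sub.dense()
    lib = np.maximum(X.sum(axis=1), 1.0)
    return {
        "X": X, "lib": lib, "t": sub.time_days,
        "tenc": sinusoidal_encode(sub.time_days, model.time_cfg_),
        "cond": encode_categories(sub.obs["condition"], model.condition_levels_),
        "batch": encode_categories(sub.obs["batch"], model.batch_levels_),
    }


class TestLossSurfaces:
    def test_reconstruction_matches_numpy_zinb_sum(self, small_model):
        """Decoder NLL equals a brute-force sum of per-entry ZINB terms."""
        model, data, _ = small_model
        batch = _batch_for(model, data, np.arange(2))
        loss = model.loss_rna(batch, kl_weight=0.0)
        br = model.branch_
        mean, _ = br.encode_np(batch["X"], batch["tenc"], batch["cond"], batch["batch"])
        rho = br.decode_np(mean, batch["tenc"], batch["cond"], batch["batch"])
        mu = batch["lib"][:, None] * rho
        theta = np.exp(br.decoder.log_theta.value)
        pi = 1.0 / (1.0 + np.exp(-br.decoder.pi_logit.value))
        manual = -zinb_loglik(batch["X"], mu, theta[None, :], pi[None, :]).sum(axis=1).mean()
        assert float(loss.value) == pytest.approx(manual, rel=1e-9)

    def test_kl_weight_zero_is_pure_reconstruction(self, small_model):
        model, data, _ = small_model
        batch = _batch_for(model, data, np.arange(5))
        l0 = float(model.loss_rna(batch, kl_weight=0.0).value)
        l1 = float(model.loss_rna(batch, kl_weight=1.0).value)
        br = model.branch_
        mean, logvar = br.encode_np(batch["X"], batch["tenc"], batch["cond"], batch["batch"])
        kl = kl_gaussian(mean, np.exp(0.5 * logvar)).mean()
        assert l1 - l0 == pytest.approx(kl, rel=1e-9)

    def test_loss_finite_on_all_zero_cell(self, small_model):
        model, data, _ = small_model
        batch = _batch_for(model, data, np.arange(3))
        batch["X"] = np.zeros_like(batch["X"])
        batch["lib"] = np.ones_like(batch["lib"])
        assert np.isfinite(float(model.loss_rna(batch).value))

    def test_generator_identity_to_machine_precision(self, small_model):
        """loss_gen = loss_rna - loss_dis exactly."""
        model, data, _ = small_model
        batch = _batch_for(model, data, np.arange(20))
        loss_rna = float(model.loss_rna(batch).value)
        loss_dis, loss_gen = model.adversarial_losses(batch)
        assert float(loss_gen.value) == pytest.approx(
            loss_rna - float(loss_dis.value), abs=1e-12)

    def test_uniform_discriminator_cross_entropy_is_log_k(self):
        logits = ad.Tensor(np.zeros((10, 4)))  # uniform over 4 time classes
        y = np.eye(4)[np.arange(10) % 4]
        assert float(_ce_t(logits, y).value) == pytest.approx(np.log(4))

    def test_perfect_discriminator_cross_entropy_near_zero(self):
        y = np.eye(3)[np.arange(9) % 3]
        logits = ad.Tensor(50.0 * y)
        assert float(_ce_t(logits, y).value) == pytest.approx(0.0, abs=1e-10)

    def test_time_class_maps_to_nearest_grid_point(self):
        grid = np.array([8.0, 8.5, 9.0])
        assert np.array_equal(_time_class([8.01, 8.74, 8.76], grid), [0, 1, 2])


class TestTrainingContracts:
    def test_same_seed_identical_history(self):
        data = _tiny_rna_dataset()
        splits = make_splits(data, SplitSpec(seed=0))
        kw = dict(latent_dim=6, hidden_width=16, time_dim=8, max_epochs=4,
                  batch_size=64, seed=11)
        h1 = TemporalVAE(**kw).fit(data, splits=splits).history_
        h2 = TemporalVAE(**kw).fit(data, splits=splits).history_
        assert h1 == h2

    def test_training_reduces_validation_loss(self, rna_ensemble):
        """On structured synthetic data the fitted loss beats epoch 0."""
        model, _, _ = rna_ensemble[1]
        hist = model.history_["val_loss"]
        assert min(hist) < hist[0]

    def test_empty_split_rejected(self):
        data = _tiny_rna_dataset()
        with pytest.raises(ValueError, match="nonempty"):
            TemporalVAE(max_epochs=1).fit(
                data, splits=(np.array([], dtype=int), np.array([], dtype=int),
                              np.array([], dtype=int)))

    def test_single_time_point_disables_discriminator(self):
        data = _tiny_rna_dataset(times=(8.0,))
        idx = np.arange(data.n_cells)
        with pytest.warns(UserWarning, match="discriminator"):
            TemporalVAE(latent_dim=4, hidden_width=8, time_dim=4, max_epochs=1,
                        batch_size=64, seed=0).fit(data, splits=(idx[:30], idx[30:], idx[:0]))


def _tiny_multimodal_dataset(seed=0):
    rng = np.random.default_rng(seed)
    rows, counts = [], []
    n = 30
    for t in (8.0, 8.5):
        rna = np.zeros((n, 16))
        rna[:, :10] = rng.poisson(4.0, size=(n, 10))
        atac = np.zeros((n, 16))
        atac[:, 10:] = (rng.random((n, 6)) < 0.4)
        pids = [f"p{t}{i}" if i < 10 else "" for i in range(n)]
        rows.append(pd.DataFrame({"time_days": [t] * n, "condition": ["F"] * n,
                                  "batch": ["b0"] * n, "modality": ["RNA"] * n,
                                  "pair_id": pids}))
        rows.append(pd.DataFrame({"time_days": [t] * n, "condition": ["F"] * n,
                                  "batch": ["b0"] * n, "modality": ["ATAC"] * n,
                                  "pair_id": pids}))
        counts += [rna, atac]
    return TimeSeriesDataset(counts=np.vstack(counts), obs=pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="module")
def mm():
    data = _tiny_multimodal_dataset()
    splits = make_splits(data, SplitSpec(seed=0))
    model = MultimodalTemporalVAE(latent_dim=5, hidden_width=12, time_dim=8,
                                  lambda_mse=10.0, max_epochs=3, batch_size=32,
                                  seed=0).fit(data, splits=splits)
    return model, data, splits


class TestMultimodal:
    def test_time_layer_shared_bit_identical(self, mm):
        model, _, _ = mm
        assert model.atac_branch_.decoder.Wt is model.rna_branch_.decoder.Wt

    def test_alignment_is_paired_embedding_mse(self, mm):
        """loss_align equals the MSE between paired embedding means, so it
        vanishes exactly when the paired embeddings coincide."""
        model, data, _ = mm
        atac = np.where(data.modality_mask("ATAC"))[0][:8]
        batch = _batch_for(model, data, atac)
        _, loss_align, *_ = model.multimodal_losses(batch, batch, {"rna": batch, "atac": batch})
        mean_a, _ = model.atac_branch_.encode_np(batch["X"], batch["tenc"],
                                                 batch["cond"], batch["batch"])
        mean_r, _ = model.rna_branch_.encode_np(batch["X"], batch["tenc"],
                                                batch["cond"], batch["batch"])
        manual = ((mean_a - mean_r) ** 2).mean(axis=1).mean()
        assert float(loss_align.value) == pytest.approx(manual, rel=1e-9)

    def test_loss_multi_decomposition_brute_force(self, mm):
        """Three-pair toy batch: loss_multi equals a term-by-term oracle."""
        model, data, _ = mm
        atac = np.where(data.modality_mask("ATAC"))[0][:3]
        rna = np.where(data.modality_mask("RNA"))[0][:3]
        ab = _batch_for(model, data, atac)
        rb = _batch_for(model, data, rna)
        pairs = {"rna": rb, "atac": ab}
        la, lal, lab_, lba, lm = model.multimodal_losses(ab, ab, pairs)
        total = (float(la.value) + model.lambda_mse * float(lal.value)
                 + float(lab_.value) + float(lba.value))
        assert float(lm.value) == pytest.approx(total, abs=1e-6)
        # translation RNA->ATAC is the Bernoulli NLL of the true ATAC profile
        mean_r, _ = model.rna_branch_.encode_np(rb["X"], rb["tenc"], rb["cond"], rb["batch"])
        p = model.atac_branch_.decode_np(mean_r, ab["tenc"], ab["cond"], ab["batch"])
        manual_ab = -bernoulli_loglik(ab["X"], p).sum(axis=1).mean()
        assert float(lab_.value) == pytest.approx(manual_ab, rel=1e-6)

    def test_lambda_zero_drops_alignment(self, mm):
        model, data, _ = mm
        atac = np.where(data.modality_mask("ATAC"))[0][:5]
        batch = _batch_for(model, data, atac)
        pairs = {"rna": batch, "atac": batch}
        old = model.lambda_mse
        try:
            model.lambda_mse = 0.0
            la, lal, lab_, lba, lm = model.multimodal_losses(batch, batch, pairs)
            assert float(lm.value) == pytest.approx(
                float(la.value) + float(lab_.value) + float(lba.value), abs=1e-9)
        finally:
            model.lambda_mse = old

    def test_no_pairs_warns_and_zeroes_terms(self, mm):
        model, data, _ = mm
        atac = np.where(data.modality_mask("ATAC"))[0][:5]
        batch = _batch_for(model, data, atac)
        with pytest.warns(UserWarning, match="co-assay"):
            la, lal, lab_, lba, lm = model.multimodal_losses(batch, batch, None)
        assert float(lal.value) == 0.0 and float(lm.value) == pytest.approx(float(la.value))

    def test_missing_pairs_rejected(self):
        data = _tiny_rna_dataset()
        with pytest.raises(ValueError, match="pair_id"):
            MultimodalTemporalVAE(max_epochs=1).fit(data)

    def test_same_seed_identical_history(self):
        data = _tiny_multimodal_dataset()
        splits = make_splits(data, SplitSpec(seed=0))
        kw = dict(latent_dim=5, hidden_width=12, time_dim=8, max_epochs=3,
                  batch_size=32, seed=4)
        h1 = MultimodalTemporalVAE(**kw).fit(data, splits=splits).history_
        h2 = MultimodalTemporalVAE(**kw).fit(data, splits=splits).history_
        assert h1 == h2

    def test_atac_optimizer_excludes_rna_and_shared_time_weights(self, mm):
        """Step 2 cannot touch RNA-branch weights or the shared time layer."""
        model, _, _ = mm
        atac_params = {id(p) for p in model.atac_branch_.gen_params(include_time=False)}
        rna_params = {id(p) for p in model.rna_branch_.gen_params()}
        assert not atac_params & rna_params
        assert id(model.atac_branch_.decoder.Wt) in rna_params

    def test_paired_embeddings_closer_than_random(self, mm_full_ensemble, tiny_sim):
        """Paired co-assay embeddings end closer than random cross pairs."""
        _, data, _ = tiny_sim
        model = mm_full_ensemble[0]
        from chronovae.models import _pair_rows

        rna_rows, atac_rows = _pair_rows(data, np.arange(data.n_cells))
        take = slice(0, 200)
        zr = model.transform(data, rna_rows[take])
        za = model.transform(data, atac_rows[take])
        paired_d = np.linalg.norm(zr - za, axis=1).mean()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(zr))
        random_d = np.linalg.norm(zr - za[perm], axis=1).mean()
        assert paired_d < random_d
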