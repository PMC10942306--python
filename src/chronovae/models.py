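"""Conditional VAE estimators for single-cell time series.

Two sklearn-style estimators:

``TemporalVAE``
    Single-modality conditional VAE. The encoder maps a cell's profile
    plus covariate encodings (sinusoidal time, one-hot condition/batch)
    to a diagonal-Gaussian posterior over a cell-identity latent; the
    decoder reconstructs the profile from the latent and the covariates
    (ZINB likelihood for RNA counts, Bernoulli for binarized ATAC). An
    adversarial discriminator tries to predict the observed time point
    from the cell embedding; the generator is trained against it so that
    cell identity stays invariant of time.

``MultimodalTemporalVAE``
    Adds an ATAC branch trained stepwise against the RNA reference:
    the first decoder sub-layer consuming the time encoding is shared
    (RNA weights, frozen for ATAC updates), co-assayed cell embeddings
    are pulled together by an MSE penalty with weight ``lambda_mse``,
    and cross-modality translation losses tie the two decoders.

Networks run on the package's NumPy autodiff engine; training is plain
Adam with seeded minibatching, so identical seeds give bit-identical
histories.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

from . import _autodiff as ad
from ._autodiff import Tensor
from .data import TimeSeriesDataset, SplitSpec, make_splits
from .encodings import TimeEncodingConfig, encode_categories, sinusoidal_encode

__all__ = [
    "TemporalVAE",
    "MultimodalTemporalVAE",
    "train_single_modality",
    "train_multimodal",
]

LATENT_GRID = (25, 50, 100)
WAVELENGTH_GRID = (1.0, 2.0 * np.pi)
LAMBDA_GRID = (1.0, 100.0, 10000.0)


# ---------------------------------------------------------------------
# network building blocks
# ---------------------------------------------------------------------

def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-lim, lim, size=(n_in, n_out)))


class _Dense:
    def __init__(self, rng, n_in, n_out):
        self.W = _glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x):
        return ad.as_tensor(x) @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class _Encoder:
    """2-hidden-layer MLP -> (posterior mean, log-variance)."""

    def __init__(self, rng, n_in, hidden, latent):
        self.l1 = _Dense(rng, n_in, hidden)
        self.l2 = _Dense(rng, hidden, hidden)
        self.mean = _Dense(rng, hidden, latent)
        self.logvar = _Dense(rng, hidden, latent)

    def __call__(self, x):
        h = ad.relu(self.l1(x))
        h = ad.relu(self.l2(h))
        return self.mean(h), self.logvar(h)

    def params(self):
        return self.l1.params() + self.l2.params() + self.mean.params() + self.logvar.params()


class _Decoder:
    """Decoder whose first layer consumes (z, time enc, condition, batch).

    The time input enters through a dedicated weight block ``Wt`` — the
    time-relevant layer that the multimodal model shares across branches.
    """

    def __init__(self, rng, latent, d_time, n_cond, n_batch, hidden, n_out, likelihood):
        self.Wz = _glorot(rng, latent, hidden)
        self.Wt = _glorot(rng, d_time, hidden)
        self.Wc = _glorot(rng, n_cond, hidden)
        self.Wb = _glorot(rng, n_batch, hidden)
        self.b1 = Tensor(np.zeros(hidden))
        self.l2 = _Dense(rng, hidden, hidden)
        self.out = _Dense(rng, hidden, n_out)
        self.likelihood = likelihood
        if likelihood == "zinb":
            # per-gene inverse dispersion and zero-inflation logit
            self.log_theta = Tensor(np.zeros(n_out))
            self.pi_logit = Tensor(np.full(n_out, -3.0))

    def __call__(self, z, tenc, cond, batch):
        h = (
            ad.as_tensor(z) @ self.Wz
            + ad.as_tensor(tenc) @ self.Wt
            + ad.as_tensor(cond) @ self.Wc
            + ad.as_tensor(batch) @ self.Wb
            + self.b1
        )
        h = ad.relu(h)
        h = ad.relu(self.l2(h))
        raw = self.out(h)
        if self.likelihood == "zinb":
            return ad.log_softmax(raw, axis=1)  # log depth-normalized proportions
        return raw  # Bernoulli logits

    def params(self, include_time: bool = True):
        ps = [self.Wz, self.Wc, self.Wb, self.b1] + self.l2.params() + self.out.params()
        if include_time:
            ps.append(self.Wt)
        if self.likelihood == "zinb":
            ps += [self.log_theta, self.pi_logit]
        return ps


class _Discriminator:
    """2-layer classifier over the observed time grid."""

    def __init__(self, rng, latent, hidden, n_classes):
        self.l1 = _Dense(rng, latent, hidden)
        self.l2 = _Dense(rng, hidden, n_classes)

    def __call__(self, z):
        return self.l2(ad.relu(self.l1(z)))

    def params(self):
        return self.l1.params() + self.l2.params()


# ---------------------------------------------------------------------
# differentiable losses
# ---------------------------------------------------------------------

def _zinb_nll_t(x: np.ndarray, log_mu: Tensor, log_theta: Tensor, pi_logit: Tensor) -> Tensor:
    """Per-cell negative ZINB log-likelihood (sum over genes), autodiff version."""
    theta = ad.exp(log_theta)
    mu = ad.exp(log_mu)
    log_theta_v = log_theta
    log_theta_mu = ad.log(theta + mu)
    log_nb_zero = theta * (log_theta_v - log_theta_mu)
    case_zero = log_nb_zero + ad.softplus(pi_logit - log_nb_zero) - ad.softplus(pi_logit)
    case_nz = (
        -ad.softplus(pi_logit)
        + ad.lgamma(x + theta)
        - ad.lgamma(theta)
        - gammaln(x + 1.0)
        + log_nb_zero
        + x * (log_mu - log_theta_mu)
    )
    zero_mask = (x == 0).astype(np.float64)
    ll = case_zero * zero_mask + case_nz * (1.0 - zero_mask)
    return -ll.sum(axis=1)


def _bce_nll_t(x: np.ndarray, logits: Tensor) -> Tensor:
    """Per-cell Bernoulli negative log-likelihood: softplus(l) - x*l, summed."""
    return (ad.softplus(logits) - x * logits).sum(axis=1)


def _kl_t(mean: Tensor, logvar: Tensor) -> Tensor:
    return (0.5 * (mean * mean + ad.exp(logvar) - 1.0 - logvar)).sum(axis=1)


def _ce_t(logits: Tensor, onehot_y: np.ndarray) -> Tensor:
    lse = ad.logsumexp(logits, axis=1)
    picked = (logits * onehot_y).sum(axis=1)
    return (lse - picked).mean()


# ---------------------------------------------------------------------
# one modality branch (networks + prepared arrays + losses)
# ---------------------------------------------------------------------

class _Branch:
    def __init__(self, rng, n_features, likelihood, latent_dim, hidden_width,
                 time_cfg, n_cond, n_batch, time_grid, disc_hidden=64):
        self.likelihood = likelihood
        self.time_cfg = time_cfg
        self.time_grid = np.asarray(time_grid, dtype=float)
        n_cov = time_cfg.d + n_cond + n_batch
        self.encoder = _Encoder(rng, n_features + n_cov, hidden_width, latent_dim)
        self.decoder = _Decoder(rng, latent_dim, time_cfg.d, n_cond, n_batch,
                                hidden_width, n_features, likelihood)
        self.discriminator = _Discriminator(rng, latent_dim, disc_hidden, len(self.time_grid))

    # -- prepared minibatch tensors -----------------------------------
    def encoder_input(self, X, tenc, cond, batch):
        xin = np.log1p(X) if self.likelihood == "zinb" else X
        return np.concatenate([xin, tenc, cond, batch], axis=1)

    def encode_np(self, X, tenc, cond, batch):
        mean, logvar = self.encoder(self.encoder_input(X, tenc, cond, batch))
        return mean.value, logvar.value

    def decode_np(self, z, tenc, cond, batch):
        out = self.decoder(z, tenc, cond, batch).value
        return np.exp(out) if self.likelihood == "zinb" else expit(out)

    def recon_nll(self, X, lib, z, tenc, cond, batch) -> Tensor:
        dec = self.decoder(z, tenc, cond, batch)
        if self.likelihood == "zinb":
            log_mu = dec + np.log(lib)[:, None]
            return _zinb_nll_t(X, log_mu, self.decoder.log_theta, self.decoder.pi_logit)
        return _bce_nll_t(X, dec)

    def gen_params(self, include_time=True):
        return self.encoder.params() + self.decoder.params(include_time=include_time)


def _prepare(ds: TimeSeriesDataset, idx, time_cfg, cond_levels, batch_levels):
    sub = ds.subset(idx)
    X = sub.dense()
    lib = X.sum(axis=1)
    lib = np.where(lib > 0, lib, 1.0)
    return {
        "X": X,
        "lib": lib,
        "t": sub.time_days,
        "tenc": sinusoidal_encode(sub.time_days, time_cfg),
        "cond": encode_categories(sub.obs["condition"], cond_levels),
        "batch": encode_categories(sub.obs["batch"], batch_levels),
        "obs": sub.obs,
        "idx": np.asarray(idx),
    }


def _time_class(t, grid):
    d = np.abs(np.asarray(t)[:, None] - np.asarray(grid)[None, :])
    return d.argmin(axis=1)


# ---------------------------------------------------------------------
# single-modality estimator
# ---------------------------------------------------------------------

class TemporalVAE(BaseEstimator):
    """Conditional VAE with adversarial time disentanglement.

    Parameters
    ----------
    latent_dim : cell-identity latent dimension (grid default {25, 50, 100}).
    hidden_width : width of the two hidden layers (encoder and decoder).
    time_dim, min_wavelength : sinusoidal time-encoding configuration.
    kl_weight : final weight of the KL term, linearly warmed up over
        ``kl_warmup_epochs`` epochs.
    adversarial : train the time discriminator adversarially (loss_gen =
        loss_rna - loss_dis); when False the discriminator is still fit
        (for diagnostics) but the generator ignores it.
    modality : "RNA" (ZINB likelihood) or "ATAC" (Bernoulli).
    batch_size, learning_rate, max_epochs, patience, seed : optimization.

    Fitted attributes end in an underscore, notably ``history_`` (per-epoch
    losses), ``time_grid_`` (observed training time points), and the
    category levels seen at fit time.
    """

    def __init__(self, latent_dim=50, hidden_width=512, n_hidden_layers=2,
                 time_dim=50, min_wavelength=1.0, kl_weight=1.0,
                 kl_warmup_epochs=10, adversarial=True, modality="RNA",
                 learning_rate=1e-3, batch_size=256, max_epochs=100,
                 patience=10, seed=0):
        self.latent_dim = latent_dim
        self.hidden_width = hidden_width
        self.n_hidden_layers = n_hidden_layers
        self.time_dim = time_dim
        self.min_wavelength = min_wavelength
        self.kl_weight = kl_weight
        self.kl_warmup_epochs = kl_warmup_epochs
        self.adversarial = adversarial
        self.modality = modality
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def __getstate__(self):
        state = self.__dict__.copy()
        state.pop("_last_embedding", None)  # transient graph node, not picklable
        return state

    # -- loss surfaces (spec operations) -------------------------------
    def loss_rna(self, batch: dict, kl_weight=None) -> Tensor:
        """Mean over cells of [reconstruction NLL + kl_weight * KL]."""
        br = self.branch_
        klw = self.kl_weight if kl_weight is None else kl_weight
        mean, logvar = br.encoder(br.encoder_input(batch["X"], batch["tenc"],
                                                   batch["cond"], batch["batch"]))
        eps = batch.get("eps")
        z = mean if eps is None else mean + ad.exp(0.5 * logvar) * eps
        nll = br.recon_nll(batch["X"], batch["lib"], z, batch["tenc"],
                           batch["cond"], batch["batch"])
        self._last_embedding = mean
        return (nll + klw * _kl_t(mean, logvar)).mean()

    def adversarial_losses(self, batch: dict, kl_weight=None):
        """(loss_dis, loss_gen) with loss_gen = loss_rna - loss_dis."""
        br = self.branch_
        loss_rec = self.loss_rna(batch, kl_weight=kl_weight)
        if len(br.time_grid) < 2:
            warnings.warn("single observed time point: discriminator disabled")
            return Tensor(0.0), loss_rec
        y = np.eye(len(br.time_grid))[_time_class(batch["t"], br.time_grid)]
        loss_dis = _ce_t(br.discriminator(self._last_embedding), y)
        return loss_dis, loss_rec - loss_dis

    # -- fitting --------------------------------------------------------
    def fit(self, data: TimeSeriesDataset, splits=None):
        if self.n_hidden_layers != 2:
            raise ValueError("architecture is fixed at 2 hidden layers")
        mask = data.modality_mask(self.modality)
        if not mask.any():
            raise ValueError(f"no {self.modality} cells in the dataset")
        if splits is None:
            splits = make_splits(data, SplitSpec(seed=self.seed))
        train_idx, val_idx = np.asarray(splits[0]), np.asarray(splits[1])
        train_idx = train_idx[mask[train_idx]]
        val_idx = val_idx[mask[val_idx]]
        if train_idx.size == 0 or val_idx.size == 0:
            raise ValueError("train and validation splits must both be nonempty")

        rng = np.random.default_rng(self.seed)
        self.time_cfg_ = TimeEncodingConfig(self.time_dim, self.min_wavelength)
        self.condition_levels_ = sorted(map(str, data.obs["condition"].unique()))
        self.batch_levels_ = sorted(map(str, data.obs["batch"].unique()))
        self.time_grid_ = np.unique(np.round(data.time_days[train_idx], 6))
        self.feature_ids_ = np.asarray(data.var.index)
        lk = "zinb" if self.modality == "RNA" else "bernoulli"
        self.branch_ = _Branch(rng, data.n_features, lk, self.latent_dim,
                               self.hidden_width, self.time_cfg_,
                               len(self.condition_levels_), len(self.batch_levels_),
                               self.time_grid_)
        train = _prepare(data, train_idx, self.time_cfg_, self.condition_levels_,
                         self.batch_levels_)
        val = _prepare(data, val_idx, self.time_cfg_, self.condition_levels_,
                       self.batch_levels_)
        self.history_ = _train_branch_adversarial(
            self, self.branch_, train, val, rng,
            lr=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
            kl_weight=self.kl_weight, warmup=self.kl_warmup_epochs,
            adversarial=self.adversarial)
        return self

    # -- inference ------------------------------------------------------
    def _covariates(self, obs):
        tenc = sinusoidal_encode(obs["time_days"].to_numpy(dtype=float), self.time_cfg_)
        cond = encode_categories(obs["condition"].astype(str), self.condition_levels_)
        batch = encode_categories(obs["batch"].astype(str), self.batch_levels_)
        return tenc, cond, batch

    def transform(self, data: TimeSeriesDataset, idx=None) -> np.ndarray:
        """Posterior-mean cell embeddings under each cell's observed covariates."""
        idx = np.where(data.modality_mask(self.modality))[0] if idx is None else np.asarray(idx)
        sub = data.subset(idx)
        tenc, cond, batch = self._covariates(sub.obs)
        mean, _ = self.branch_.encode_np(sub.dense(), tenc, cond, batch)
        return mean

    def decode(self, z, target_times, target_conditions, target_batches) -> np.ndarray:
        """Decode embeddings at arbitrary covariates.

        Returns depth-normalized expected proportions (RNA, rows sum to 1)
        or accessibility probabilities in [0, 1] (ATAC).
        """
        z = np.atleast_2d(np.asarray(z, dtype=float))
        n = z.shape[0]
        tt = np.broadcast_to(np.asarray(target_times, dtype=float), (n,))
        tenc = sinusoidal_encode(tt, self.time_cfg_)
        cond = encode_categories(np.broadcast_to(np.asarray(target_conditions, dtype=object), (n,)),
                                 self.condition_levels_)
        batch = encode_categories(np.broadcast_to(np.asarray(target_batches, dtype=object), (n,)),
                                  self.batch_levels_)
        return self.branch_.decode_np(z, tenc, cond, batch)


# ---------------------------------------------------------------------
# shared adversarial training loop
# ---------------------------------------------------------------------

def _minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _slice_batch(prep, sel, rng=None, latent_dim=None):
    b = {k: prep[k][sel] for k in ("X", "lib", "t", "tenc", "cond", "batch")}
    if rng is not None:
        b["eps"] = rng.standard_normal((len(sel), latent_dim))
    return b


def _val_loss(model, val):
    loss = model.loss_rna({k: val[k] for k in ("X", "lib", "t", "tenc", "cond", "batch")})
    return float(loss.value)


def _train_branch_adversarial(model, br, train, val, rng, *, lr, batch_size,
                              max_epochs, patience, kl_weight, warmup,
                              adversarial):
    use_disc = len(br.time_grid) >= 2
    if not use_disc:
        warnings.warn("single observed time point: adversarial training disabled")
    opt_gen = ad.Adam(br.gen_params(), lr=lr)
    opt_dis = ad.Adam(br.discriminator.params(), lr=lr)
    history = {"train_loss": [], "val_loss": [], "train_loss_dis": []}
    best, best_state, wait = np.inf, None, 0
    params_all = br.gen_params() + br.discriminator.params()
    n = train["X"].shape[0]
    for epoch in range(max_epochs):
        klw = kl_weight * min(1.0, (epoch + 1) / max(1, warmup))
        ep_loss, ep_dis, nb = 0.0, 0.0, 0
        for sel in _minibatches(n, batch_size, rng):
            batch = _slice_batch(train, sel, rng, model.latent_dim)
            if use_disc:
                # discriminator step: embeddings detached, encoder untouched
                mean, _ = br.encoder(br.encoder_input(batch["X"], batch["tenc"],
                                                      batch["cond"], batch["batch"]))
                y = np.eye(len(br.time_grid))[_time_class(batch["t"], br.time_grid)]
                loss_d = _ce_t(br.discriminator(mean.detach()), y)
                opt_dis.zero_grad()
                loss_d.backward()
                opt_dis.step()
            # generator step: discriminator frozen
            loss_dis, loss_gen = model.adversarial_losses(batch, kl_weight=klw)
            target = loss_gen if (adversarial and use_disc) else loss_gen + loss_dis
            opt_gen.zero_grad()
            for p in br.discriminator.params():
                p.grad = None
            target.backward()
            opt_gen.step()
            ep_loss += float((loss_gen + loss_dis).value)
            ep_dis += float(loss_dis.value)
            nb += 1
        vl = _val_loss(model, val)
        history["train_loss"].append(ep_loss / nb)
        history["train_loss_dis"].append(ep_dis / nb)
        history["val_loss"].append(vl)
        if not np.isfinite(vl):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        if vl < best - 1e-9:
            best, wait = vl, 0
            best_state = [p.value.copy() for p in params_all]
        else:
            wait += 1
            if wait >= patience:
                break
    if best_state is not None:
        for p, v in zip(params_all, best_state):
            p.value = v
    return history


# ---------------------------------------------------------------------
# multimodal estimator
# ---------------------------------------------------------------------

class MultimodalTemporalVAE(BaseEstimator):
    """Reference-guided RNA + ATAC model with a shared time layer.

    Stepwise training alternates (per epoch):

    * Step 1 — update the RNA branch adversarially, ATAC branch frozen.
    * Step 2 — update the ATAC branch on ``loss_multi`` = loss_atac +
      lambda_mse * MSE(paired embeddings) + translation losses in both
      directions, with the decoder time weights copied from (and frozen
      to) the RNA branch.

    Requires co-assay pairing (``pair_id`` linking one RNA to one ATAC
    cell); early stopping monitors the validation multimodal loss of the
    ATAC branch.
    """

    def __init__(self, latent_dim=50, hidden_width=512, time_dim=50,
                 min_wavelength=1.0, lambda_mse=100.0, kl_weight=1.0,
                 kl_warmup_epochs=10, adversarial=True, learning_rate=1e-3,
                 batch_size=256, max_epochs=100, patience=10, seed=0):
        self.latent_dim = latent_dim
        self.hidden_width = hidden_width
        self.time_dim = time_dim
        self.min_wavelength = min_wavelength
        self.lambda_mse = lambda_mse
        self.kl_weight = kl_weight
        self.kl_warmup_epochs = kl_warmup_epochs
        self.adversarial = adversarial
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    # -- losses ---------------------------------------------------------
    def multimodal_losses(self, rna_batch, atac_batch, pairs, kl_weight=None):
        """Return (loss_atac, loss_align, loss_trans_ab, loss_trans_ba, loss_multi).

        ``pairs`` is a dict with RNA-side and ATAC-side prepared arrays for
        co-assayed cells, row-aligned.
        """
        klw = self.kl_weight if kl_weight is None else kl_weight
        ab, rb = self.atac_branch_, self.rna_branch_
        mean_a, logvar_a = ab.encoder(ab.encoder_input(
            atac_batch["X"], atac_batch["tenc"], atac_batch["cond"], atac_batch["batch"]))
        eps = atac_batch.get("eps")
        z_a = mean_a if eps is None else mean_a + ad.exp(0.5 * logvar_a) * eps
        nll = ab.recon_nll(atac_batch["X"], atac_batch["lib"], z_a,
                           atac_batch["tenc"], atac_batch["cond"], atac_batch["batch"])
        loss_atac = (nll + klw * _kl_t(mean_a, logvar_a)).mean()

        if pairs is None or pairs["rna"]["X"].shape[0] == 0:
            warnings.warn("no co-assay pairs in batch: alignment/translation terms are 0")
            zero = Tensor(0.0)
            return loss_atac, zero, zero, zero, loss_atac + zero

        pr, pa = pairs["rna"], pairs["atac"]
        mean_r, _ = rb.encoder(rb.encoder_input(pr["X"], pr["tenc"], pr["cond"], pr["batch"]))
        mean_pa, _ = ab.encoder(ab.encoder_input(pa["X"], pa["tenc"], pa["cond"], pa["batch"]))
        diff = mean_pa - mean_r.detach()  # ATAC embeddings pulled toward RNA reference
        loss_align = (diff * diff).mean(axis=1).mean()
        # translate RNA embedding -> ATAC profile
        trans_ab = ab.recon_nll(pa["X"], pa["lib"], mean_r.detach(),
                                pa["tenc"], pa["cond"], pa["batch"]).mean()
        # translate ATAC embedding -> RNA profile
        trans_ba = rb.recon_nll(pr["X"], pr["lib"], mean_pa,
                                pr["tenc"], pr["cond"], pr["batch"]).mean()
        loss_multi = loss_atac + self.lambda_mse * loss_align + trans_ab + trans_ba
        return loss_atac, loss_align, trans_ab, trans_ba, loss_multi

    # -- fitting ----------------------------------------------------------
    def fit(self, data: TimeSeriesDataset, splits=None):
        if "pair_id" not in data.obs or data.obs["pair_id"].isna().all():
            raise ValueError("multimodal training requires co-assay pair_id links")
        if splits is None:
            splits = make_splits(data, SplitSpec(seed=self.seed))
        train_idx, val_idx = np.asarray(splits[0]), np.asarray(splits[1])
        rna_mask = data.modality_mask("RNA")
        atac_mask = data.modality_mask("ATAC")
        rna_train = train_idx[rna_mask[train_idx]]
        rna_val = val_idx[rna_mask[val_idx]]
        atac_train = train_idx[atac_mask[train_idx]]
        atac_val = val_idx[atac_mask[val_idx]]
        for name, idx in (("RNA train", rna_train), ("RNA val", rna_val),
                          ("ATAC train", atac_train), ("ATAC val", atac_val)):
            if idx.size == 0:
                raise ValueError(f"{name} split is empty")

        rng = np.random.default_rng(self.seed)
        self.time_cfg_ = TimeEncodingConfig(self.time_dim, self.min_wavelength)
        self.condition_levels_ = sorted(map(str, data.obs["condition"].unique()))
        self.batch_levels_ = sorted(map(str, data.obs["batch"].unique()))
        self.rna_time_grid_ = np.unique(np.round(data.time_days[rna_train], 6))
        self.atac_time_grid_ = np.unique(np.round(data.time_days[atac_train], 6))
        self.n_features_ = data.n_features
        self.feature_ids_ = np.asarray(data.var.index)
        nc, nb = len(self.condition_levels_), len(self.batch_levels_)
        self.rna_branch_ = _Branch(rng, data.n_features, "zinb", self.latent_dim,
                                   self.hidden_width, self.time_cfg_, nc, nb,
                                   self.rna_time_grid_)
        self.atac_branch_ = _Branch(rng, data.n_features, "bernoulli", self.latent_dim,
                                    self.hidden_width, self.time_cfg_, nc, nb,
                                    self.atac_time_grid_)
        # share the time-relevant decoder layer: same Tensor object, so the
        # ATAC branch tracks every RNA update and never diverges.
        self.atac_branch_.decoder.Wt = self.rna_branch_.decoder.Wt

        prep = lambda idx: _prepare(data, idx, self.time_cfg_,
                                    self.condition_levels_, self.batch_levels_)
        rna_tr, rna_va = prep(rna_train), prep(rna_val)
        atac_tr, atac_va = prep(atac_train), prep(atac_val)
        pairs_tr = _pair_rows(data, np.concatenate([rna_train, atac_train]))
        pairs_va = _pair_rows(data, np.concatenate([rna_val, atac_val]))
        if len(pairs_tr[0]) == 0:
            raise ValueError("no co-assay pairs fall in the training split")
        pair_tr = {"rna": prep(pairs_tr[0]), "atac": prep(pairs_tr[1])}
        pair_va = ({"rna": prep(pairs_va[0]), "atac": prep(pairs_va[1])}
                   if len(pairs_va[0]) else None)

        self.history_ = self._train_loop(rna_tr, rna_va, atac_tr, atac_va,
                                         pair_tr, pair_va, rng)
        return self

    def _train_loop(self, rna_tr, rna_va, atac_tr, atac_va, pair_tr, pair_va, rng):
        rb, ab = self.rna_branch_, self.atac_branch_
        use_disc = len(rb.time_grid) >= 2
        opt_rna = ad.Adam(rb.gen_params(), lr=self.learning_rate)
        opt_rna_dis = ad.Adam(rb.discriminator.params(), lr=self.learning_rate)
        # ATAC optimizer excludes the shared time layer (frozen in Step 2)
        opt_atac = ad.Adam(ab.gen_params(include_time=False), lr=self.learning_rate)
        params_all = (rb.gen_params() + rb.discriminator.params()
                      + ab.gen_params(include_time=False))
        history = {"rna_train_loss": [], "atac_train_loss": [], "val_loss_multi": []}
        best, best_state, wait = np.inf, None, 0
        n_rna, n_atac = rna_tr["X"].shape[0], atac_tr["X"].shape[0]
        n_pairs = pair_tr["rna"]["X"].shape[0]
        shim = _RnaShim(self, rb)
        for epoch in range(self.max_epochs):
            klw = self.kl_weight * min(1.0, (epoch + 1) / max(1, self.kl_warmup_epochs))
            # ---- Step 1: RNA branch (adversarial), ATAC frozen ----
            ep_rna, nb1 = 0.0, 0
            for sel in _minibatches(n_rna, self.batch_size, rng):
                batch = _slice_batch(rna_tr, sel, rng, self.latent_dim)
                if use_disc:
                    mean, _ = rb.encoder(rb.encoder_input(batch["X"], batch["tenc"],
                                                          batch["cond"], batch["batch"]))
                    y = np.eye(len(rb.time_grid))[_time_class(batch["t"], rb.time_grid)]
                    loss_d = _ce_t(rb.discriminator(mean.detach()), y)
                    opt_rna_dis.zero_grad()
                    loss_d.backward()
                    opt_rna_dis.step()
                loss_dis, loss_gen = shim.adversarial_losses(batch, klw)
                target = loss_gen if (self.adversarial and use_disc) else loss_gen + loss_dis
                opt_rna.zero_grad()
                for p in rb.discriminator.params():
                    p.grad = None
                target.backward()
                opt_rna.step()
                ep_rna += float((loss_gen + loss_dis).value)
                nb1 += 1
            # ---- Step 2: ATAC branch on loss_multi, time layer frozen ----
            ep_atac, nb2 = 0.0, 0
            for sel in _minibatches(n_atac, self.batch_size, rng):
                batch = _slice_batch(atac_tr, sel, rng, self.latent_dim)
                psel = rng.choice(n_pairs, size=min(self.batch_size, n_pairs), replace=False)
                pb = {"rna": _slice_batch(pair_tr["rna"], psel),
                      "atac": _slice_batch(pair_tr["atac"], psel)}
                *_, loss_multi = self.multimodal_losses(batch, batch, pb, kl_weight=klw)
                opt_atac.zero_grad()
                loss_multi.backward()
                opt_atac.step()
                ep_atac += float(loss_multi.value)
                nb2 += 1
            # ---- validation on the ATAC branch ----
            va_batch = {k: atac_va[k] for k in ("X", "lib", "t", "tenc", "cond", "batch")}
            pv = None
            if pair_va is not None:
                pv = {"rna": {k: pair_va["rna"][k] for k in ("X", "lib", "t", "tenc", "cond", "batch")},
                      "atac": {k: pair_va["atac"][k] for k in ("X", "lib", "t", "tenc", "cond", "batch")}}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                *_, vloss = self.multimodal_losses(va_batch, va_batch, pv)
            vl = float(vloss.value)
            history["rna_train_loss"].append(ep_rna / max(nb1, 1))
            history["atac_train_loss"].append(ep_atac / max(nb2, 1))
            history["val_loss_multi"].append(vl)
            if not np.isfinite(vl):
                raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
            if vl < best - 1e-9:
                best, wait = vl, 0
                best_state = [p.value.copy() for p in params_all]
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_state is not None:
            for p, v in zip(params_all, best_state):
                p.value = v
        return history

    # -- inference --------------------------------------------------------
    def _covariates(self, obs):
        tenc = sinusoidal_encode(obs["time_days"].to_numpy(dtype=float), self.time_cfg_)
        cond = encode_categories(obs["condition"].astype(str), self.condition_levels_)
        batch = encode_categories(obs["batch"].astype(str), self.batch_levels_)
        return tenc, cond, batch

    def transform(self, data: TimeSeriesDataset, idx=None, modality=None) -> np.ndarray:
        """Posterior-mean embeddings; branch chosen per cell's modality."""
        if idx is None:
            idx = np.arange(data.n_cells)
        idx = np.asarray(idx)
        sub = data.subset(idx)
        tenc, cond, batch = self._covariates(sub.obs)
        X = sub.dense()
        out = np.zeros((len(idx), self.latent_dim))
        for mod, br in (("RNA", self.rna_branch_), ("ATAC", self.atac_branch_)):
            m = (sub.obs["modality"] == mod).to_numpy()
            if m.any():
                mean, _ = br.encode_np(X[m], tenc[m], cond[m], batch[m])
                out[m] = mean
        return out

    def decode(self, z, target_times, target_conditions, target_batches,
               target_modality="ATAC") -> np.ndarray:
        """Decode embeddings into the requested modality's feature space."""
        br = self.atac_branch_ if target_modality == "ATAC" else self.rna_branch_
        z = np.atleast_2d(np.asarray(z, dtype=float))
        n = z.shape[0]
        tt = np.broadcast_to(np.asarray(target_times, dtype=float), (n,))
        tenc = sinusoidal_encode(tt, self.time_cfg_)
        cond = encode_categories(np.broadcast_to(np.asarray(target_conditions, dtype=object), (n,)),
                                 self.condition_levels_)
        batch = encode_categories(np.broadcast_to(np.asarray(target_batches, dtype=object), (n,)),
                                  self.batch_levels_)
        return br.decode_np(z, tenc, cond, batch)


class _RnaShim:
    """Adapter exposing TemporalVAE's loss surface for the RNA branch."""

    def __init__(self, owner, branch):
        self.owner = owner
        self.branch_ = branch

    def adversarial_losses(self, batch, klw):
        br = self.branch_
        mean, logvar = br.encoder(br.encoder_input(batch["X"], batch["tenc"],
                                                   batch["cond"], batch["batch"]))
        eps = batch.get("eps")
        z = mean if eps is None else mean + ad.exp(0.5 * logvar) * eps
        nll = br.recon_nll(batch["X"], batch["lib"], z, batch["tenc"],
                           batch["cond"], batch["batch"])
        loss_rna = (nll + klw * _kl_t(mean, logvar)).mean()
        if len(br.time_grid) < 2:
            return Tensor(0.0), loss_rna
        y = np.eye(len(br.time_grid))[_time_class(batch["t"], br.time_grid)]
        loss_dis = _ce_t(br.discriminator(mean), y)
        return loss_dis, loss_rna - loss_dis


def _pair_rows(data: TimeSeriesDataset, allowed_idx):
    """Row indices (rna_rows, atac_rows) of co-assay pairs fully inside `allowed_idx`."""
    allowed = set(int(i) for i in np.asarray(allowed_idx))
    if "pair_id" not in data.obs:
        return np.array([], dtype=int), np.array([], dtype=int)
    obs = data.obs
    has = obs["pair_id"].notna() & (obs["pair_id"] != "")
    rna_rows, atac_rows = [], []
    grouped = obs[has].groupby("pair_id")
    for _, grp in grouped:
        rows = grp.index.to_numpy()
        if not all(int(r) in allowed for r in rows):
            continue
        r = rows[grp["modality"].to_numpy() == "RNA"][0]
        a = rows[grp["modality"].to_numpy() == "ATAC"][0]
        rna_rows.append(int(r))
        atac_rows.append(int(a))
    return np.array(rna_rows, dtype=int), np.array(atac_rows, dtype=int)


# ---------------------------------------------------------------------
# functional wrappers (thin, for pipeline use)
# ---------------------------------------------------------------------

def train_single_modality(data: TimeSeriesDataset, splits=None, **config) -> TemporalVAE:
    return TemporalVAE(**config).fit(data, splits=splits)


def train_multimodal(data: TimeSeriesDataset, splits=None, **config) -> MultimodalTemporalVAE:
    return MultimodalTemporalVAE(**config).fit(data, splits=splits)
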