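# Methods

## Model

`chronovae` models single-cell time-series profiles with a conditional
variational autoencoder that decomposes each observed cell into four
factors: a learned cell-identity embedding `z`, a continuous time factor,
and one-hot condition (e.g. sex) and batch factors. The encoder
`Q(z | X, t, c, b)` maps the profile plus covariate encodings to a
diagonal-Gaussian posterior; the decoder reconstructs the profile from a
latent sample concatenated (via separate first-layer weight blocks) with
the covariate encodings. Predictions swap factors: a cell is encoded
under its own observed covariates (posterior mean, no sampling), then
decoded under any target time, condition, or modality.

**Time encoding.** Time in days enters as a transformer-style sinusoidal
embedding: `d/2` pairs `(sin w_j t, cos w_j t)` with
`w_j = (2*pi / L) / 10000^(2(j-1)/d)`, so the fastest component has period
exactly `L` days (the "minimum wavelength" hyperparameter, grid {1, 2*pi}).
The encoding is smooth and injective over the developmental range, which
is what lets the decoder interpolate profiles at unmeasured times.

**Likelihoods.** RNA counts follow a zero-inflated negative binomial:
the decoder emits per-gene proportions through a softmax, scaled by the
cell's observed library size to give the NB mean; inverse dispersion
`theta` and zero-inflation logit are free per-gene parameters.
Predictions are therefore depth-normalized (rows sum to 1). Binarized
ATAC peaks follow a Bernoulli with a sigmoid decoder head.

**Adversarial time disentanglement.** A 2-layer discriminator predicts
the cell's observed time point (categorical over the training grid) from
the posterior-mean embedding. Training alternates per minibatch: one
discriminator step minimizing the cross-entropy `loss_dis` with the
encoder detached, then one generator step minimizing
`loss_gen = loss_recon+KL - loss_dis` with the discriminator frozen.
This pushes cell identity to be invariant of time, so that swapping the
time factor moves a cell along its trajectory rather than to a different
cell. With a single observed time point the discriminator is disabled
(with a warning).

**Multimodal extension.** RNA, with denser time coverage, is the
reference; the ATAC branch is trained stepwise. Step 1 updates the RNA
branch adversarially with the ATAC branch frozen. Step 2 updates the
ATAC branch on

    loss_multi = loss_ATAC + lambda * MSE(z_ATAC, z_RNA)
                 + trans(ATAC|RNA) + trans(RNA|ATAC)

where the MSE runs over co-assayed cell pairs (one RNA and one ATAC
profile of the same cell), the translation terms decode each modality's
profile from the *paired other modality's* embedding, and the decoder
weight block that consumes the time encoding is shared by object
identity with the RNA decoder and excluded from the Step-2 optimizer.
The printed form of the ATAC objective subtracts a cross-entropy; since
cross-entropy is already a negative log-likelihood, the reconstruction
penalty is implemented as +BCE so minimization is well posed, and both
translation directions are included. Co-assay pairing is required; fully
unpaired alignment is out of scope.

**Implementation note.** The networks run on a small reverse-mode
autodiff engine over NumPy (`_autodiff.py`) with an Adam optimizer in
float64. Everything is single-threaded and seeded, so training histories
and predictions are bit-reproducible for a fixed seed.

## Defaults and tunable parameters

| parameter | default | notes |
|---|---|---|
| hidden layers | 2 (fixed) | encoder, decoder and discriminator |
| hidden width | 512 | tests and the acceptance script use 64–128 |
| latent dim | 50 | selection grid {25, 50, 100} |
| time embedding dim | 50 | fixed in the selection procedure |
| min wavelength L | 1 day | grid {1, 2*pi} |
| lambda (pair MSE) | 100 | grid {1, 100, 10000} |
| KL weight | 1 | linear warm-up over 10 epochs |
| batch size / lr | 256 / 1e-3 | Adam |
| val split | 1:4 per time point | capped at 2000 cells per time point |

Hyperparameter selection enumerates the 3 x 2 x 3 = 18-point grid and
picks the configuration with the smallest summed rank over validation
criteria (cross-time pseudobulk Pearson, LISI across neighboring time
points and around the held-out time, plus batch LISI, cross-modality
LISI and both translation losses where applicable).

## Downstream statistics

**Sex-bias scoring.** Each cell's denoised profile is predicted under
both sexes (ensemble median over models trained with different held-out
time points); per (cell type, time point), cells from the current,
previous and subsequent time points are pooled, and each gene's score is
the normalized Wilcoxon signed-rank statistic of the per-cell F−M
differences: 0.5 under exchangeable signs, 1/0 for consistent
female/male bias. Scores require more than 50 pooled cells.
Consistently biased genes must sit in the top half by predicted mean
expression and on the same side of 0.5 at every qualifying (>25 cells)
time point. Downstream set statistics: one-sided Mann-Whitney shift
tests (exact subset enumeration up to combined size 12, including tie
mass), an interaction-graph odds ratio with Haldane-Anscombe correction
and a permutation null (p = (count+1)/(n_perm+1); skipped below 50
relevant edges), and upper-tail hypergeometric enrichment with BH-FDR.
Because predicted profiles are depth-normalized, scores are
compositional: planting strong female-up genes necessarily pushes other
genes slightly male-ward, in the data as well as in the model.

**Time-lagged cross-correlation.** Expression and accessibility
trajectories are predicted on a 0.01-day grid over [7.5, 9] days
(ensemble medians). For each peak-gene pair the accessibility trajectory
is shifted by −delta for delta in [−0.5, 0.5] (101 shifts) and Pearson
correlation with expression is computed over the core [8, 8.5] window,
so a **positive best shift means accessibility changes ahead of
expression** ("before"/priming; negative = "after"). Ties in the maximum
go to the smallest |shift|. Pairs come from a strand-aware, upstream-only
200 kb window around each TSS (0-based half-open coordinates). Per query
cell, four neighbor cells are aggregated across the ensemble by summed
distance rank, excluding cells outside any model's top-25 list; columns
with maximum correlation below 0.5 and pairs surviving in fewer than two
cells are dropped; a pair is classified before/after only when the best
shift has the same sign in every surviving cell (unanimity).

A structural caveat: a time lag is only identifiable when the trajectory
has curvature inside the correlation window. For a monotone (e.g.
linear) trajectory, every shift of the window gives correlation ~1 and
the estimated lag collapses to 0. The synthetic generator therefore
plants lags only on genes with sinusoid temporal programs.

## Synthetic data generator

The generator emulates a developmental multi-omic atlas at desk scale:
3 cell types x 5 time points (8.0–9.0 days at 6-hour spacing), 200 genes
and 300 peaks ("tiny"; "desk" scales to 5 x 8 x 500 x 1000). Per-gene
log-intensity sums a cell-type base (with ~25 marker genes per type at
+1.5), a smooth temporal program (constant/linear/logistic/sinusoid on
half the genes, amplitudes 1–2 in log space), a planted sex effect
(log-FC ±1 on 10 autosomal genes per direction, +1 on 8 "escape-like"
chrX genes; 30 genes sit on chrX in total; plus 8 switch-type genes
whose female bias turns on or off at day 8.375, so sex-biased expression
can be a property of a time point rather than of the gene), a per-batch
gene offset
(sd 0.1, 2 batches), and a scalar per-cell state `u ~ N(0,1)` times a
per-type loading vector (sd 0.4) that gives cells persistent identities
within a type — without it, same-type cells are exchangeable and
cross-model nearest-neighbor aggregation is degenerate. Counts are ZINB
(per-gene theta in [2, 10], dropout in [0, 0.05], log-normal depth around
2000). Sexes alternate across time points with the two middle time points
profiled in both sexes, mimicking designs where most stages are
single-sex. ATAC peaks are Bernoulli with logits alpha + beta *
program(t + tau) for 60 lag-coupled peaks (|tau| in [0.1, 0.2] day, both
signs, beta = 2.5, sinusoid-program genes only) plus the cell-state
loading; co-assay twins (30% of ATAC cells) share the cell state of
their ATAC mate. Features live in a union space (gene columns, then peak
columns).

What the generator does **not** emulate: gene-regulatory network
structure, branching differentiation, cell-cycle effects, doublets and
ambient contamination, per-cell sex-by-gene interactions, and read-level
noise. Passing the planted-recovery suite therefore shows the estimator
recovers effects of the stated form at the stated sizes, not that it
resolves the full complexity of real atlases.

## Problem sizes used in the shipped checks

Tests and the acceptance script run the "tiny" generator (~3k cells
total) with downscaled networks (latent 16, hidden 64–128, time dim 32,
KL weight 0.5, 40–80 epochs, batch 256) and 3-seed ensembles; these
sizes were chosen so the entire pipeline — six model ensembles plus all
statistics — completes in minutes on one CPU while every planted effect
remains recoverable. Evaluation thresholds follow the procedure
definitions: cell types need ≥25 held-out cells for cross-time
pseudobulk evaluation, peaks accessible in ≤5% of cells are excluded
from peak-wise AUROC, and sex-bias scores require >50 pooled cells.

## Numerical choices

- All likelihoods are computed in log space; ZINB's zero case uses
  `logaddexp`-style softplus identities, safe for counts up to 1e5.
- Bernoulli probabilities are clamped to [1e-7, 1 - 1e-7].
- LISI neighborhoods use a Gaussian kernel calibrated to perplexity 30
  by binary search, neighbors capped at 90.
- Zero paired differences are dropped in signed-rank scores (classic
  convention); absolute ties get average ranks.
- Rank-sum ties in model selection use average ranks; ties in the summed
  rank fall to the first configuration in grid order.
- Neighbor-aggregation distance ties break by cell index; TLCC best-shift
  ties break toward the smallest |shift|.
- Early stopping tracks validation loss with patience (default 10) and
  restores the best parameter snapshot.

## Known limitations

- The latent prior is a standard normal independent of time; the
  conditional structure comes entirely from the encoder/decoder
  covariates.
- Dispersion and zero-inflation are per-gene, not per-cell.
- Cross-modal alignment requires co-assay pairs.
- The adversarial game uses coefficient 1 on the discriminator term;
  very strong discriminators can destabilize training at high learning
  rates.
- Batch is held at a caller-chosen reference level at prediction time;
  predictions are not averaged over batches.
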