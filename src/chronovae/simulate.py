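"""Seeded generator of multi-condition, multi-modal single-cell time series.

Emulates the structure of developmental single-cell atlases: ZINB RNA
counts and binarized ATAC peaks over several time points, with cell-type
structure, smooth per-gene temporal programs, planted sex effects of
known sign (including a small set of constitutively female-biased
"escape-like" genes on chrX), batch effects, co-assay pairing, and
planted peak-gene time lags for chromatin-priming analysis. Every
planted parameter is returned as ground truth so downstream recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from .data import TimeSeriesDataset

__all__ = ["SimulationSpec", "GroundTruth", "simulate_multiomic_timeseries",
           "default_acceptance_spec"]


@dataclass
class SimulationSpec:
    """Parameters of the simulated multi-omic time series.

    Sizes refer to cells per (cell type x time point x sex available at
    that time). ``sex_availability`` maps each time point to the profiled
    sexes; the default alternates single sexes with both sexes profiled
    at the two middle time points, mimicking designs where only one sex
    is collected at most stages.
    """

    n_cell_types: int = 3
    rna_cells_per_type_per_time: int = 130
    atac_cells_per_type_per_time: int = 60
    n_genes: int = 200
    n_peaks: int = 300
    time_points: tuple = (8.0, 8.25, 8.5, 8.75, 9.0)
    sex_availability: tuple | None = None  # per time point, e.g. (("F",), ("M","F"), ...)
    n_batches: int = 2
    batch_sd: float = 0.1
    frac_temporal: float = 0.5
    program_amplitude: tuple = (1.0, 2.0)
    n_sex_genes: int = 10           # planted female-up and male-up autosomal genes, each
    sex_lfc: float = 1.0            # planted female/male log fold change magnitude
    # time-specific sex effects: switch-type genes whose female bias turns
    # on (ramp_in) or off (ramp_out) at sex_switch_time, so sex-biased
    # expression is a property of a time point rather than of the gene
    n_dynamic_sex_genes: int = 8
    sex_switch_time: float = 8.375
    n_escape_genes: int = 8         # chrX, female-biased at every time point
    n_chrx_genes: int = 30          # total genes placed on chrX (escape + null)
    n_lag_pairs: int = 60
    lag_magnitude: tuple = (0.10, 0.20)
    lag_beta: float = 2.5           # coupling strength peak logit <- gene program
    theta_range: tuple = (2.0, 10.0)
    pi_range: tuple = (0.0, 0.05)
    depth_log_mean: float = np.log(2000.0)
    depth_log_sd: float = 0.3
    coassay_frac: float = 0.3
    type_marker_genes: int = 25
    type_marker_lfc: float = 1.5
    # continuous within-type cell state: each cell draws a scalar u ~ N(0,1)
    # that loads on genes and peaks, giving cells persistent identities (and
    # co-assay twins a shared state) instead of exchangeable profiles
    cell_state_sd: float = 0.4
    seed: int = 0

    def resolved_sex_availability(self):
        if self.sex_availability is not None:
            avail = tuple(tuple(s) for s in self.sex_availability)
        else:
            avail = []
            mid = {len(self.time_points) // 2 - 1, len(self.time_points) // 2}
            for i in range(len(self.time_points)):
                avail.append(("F", "M") if i in mid else (("F",) if i % 2 == 0 else ("M",)))
            avail = tuple(avail)
        if len(avail) != len(self.time_points) or any(len(a) == 0 for a in avail):
            raise ValueError("sex availability must name >= 1 sex per time point")
        return avail


@dataclass
class GroundTruth:
    """Planted parameters: per-gene effects, per-peak couplings, programs."""

    genes: pd.DataFrame
    peaks: pd.DataFrame
    time_points: np.ndarray
    cell_type_base: np.ndarray  # (types x genes) log-intensity offsets
    state_loading_rna: np.ndarray = None   # (types x genes) cell-state loadings
    state_loading_atac: np.ndarray = None  # (types x peaks)

    sex_switch_time: float = None

    def sex_lfc_at(self, gene_ids, t: float) -> np.ndarray:
        """Planted female-vs-male log fold change in effect at time ``t``."""
        rows = self.genes.loc[list(gene_ids)]
        lfc = rows["sex_lfc"].to_numpy(dtype=float).copy()
        if "sex_dynamic" in rows and self.sex_switch_time is not None:
            dyn = rows["sex_dynamic"].to_numpy()
            if t < self.sex_switch_time:
                lfc[dyn == "ramp_in"] = 0.0
            else:
                lfc[dyn == "ramp_out"] = 0.0
        return lfc

    def program_values(self, gene_ids, times) -> np.ndarray:
        """Temporal program f_g(t) (log scale, 0-centered) for genes x times."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        t0, t1 = self.time_points.min(), self.time_points.max()
        s = (times - t0) / (t1 - t0)
        out = np.zeros((len(gene_ids), len(times)))
        rows = self.genes.loc[list(gene_ids)]
        for i, (_, g) in enumerate(rows.iterrows()):
            out[i] = _program(g["program"], g["amplitude"], g["param1"], g["param2"], s)
        return out

    def peak_logits(self, peak_ids, times) -> np.ndarray:
        """Planted accessibility logits (peaks x times), lag applied."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        rows = self.peaks.loc[list(peak_ids)]
        out = np.zeros((len(peak_ids), len(times)))
        for i, (_, p) in enumerate(rows.iterrows()):
            out[i] = p["alpha"]
            if isinstance(p["gene"], str) and p["gene"]:
                prog = self.program_values([p["gene"]], times + p["tau"])[0]
                out[i] = out[i] + p["beta"] * prog
        return out


def _program(family: str, amplitude: float, p1: float, p2: float, s: np.ndarray):
    """Smooth temporal program on normalized time s (0 at first, 1 at last tp)."""
    s = np.asarray(s, dtype=float)
    if family == "constant":
        return np.zeros_like(s)
    if family == "linear":
        return amplitude * (s - 0.5)
    if family == "logistic":
        return amplitude * (expit((s - p1) / 0.15) - 0.5)
    if family == "sinusoid":
        return 0.5 * amplitude * np.sin(2.0 * np.pi * (p2 * s + p1))
    raise ValueError(f"unknown program family {family!r}")


def default_acceptance_spec(scale: str = "tiny", seed: int = 0) -> SimulationSpec:
    """Canned simulation sizes: 'tiny' (~2k RNA cells) or 'desk' (~10k)."""
    if scale == "tiny":
        return SimulationSpec(seed=seed)
    if scale == "desk":
        return SimulationSpec(
            n_cell_types=5, rna_cells_per_type_per_time=250,
            atac_cells_per_type_per_time=100, n_genes=500, n_peaks=1000,
            time_points=tuple(8.0 + 0.25 * i for i in range(8)),
            n_sex_genes=25, n_lag_pairs=150, n_chrx_genes=60, seed=seed)
    raise ValueError("scale must be 'tiny' or 'desk'")


def _build_truth(spec: SimulationSpec, rng: np.random.Generator) -> GroundTruth:
    G, P = spec.n_genes, spec.n_peaks
    gene_ids = [f"g{i:04d}" for i in range(G)]
    peak_ids = [f"p{i:04d}" for i in range(P)]

    # chromosomes and coordinates: genes spaced 1 Mb apart per chromosome
    chroms = np.array([f"chr{1 + i % 5}" for i in range(G)], dtype=object)
    chrx = rng.choice(G, size=min(spec.n_chrx_genes, G), replace=False)
    chroms[chrx] = "chrX"
    order_on_chrom = {c: 0 for c in set(chroms)}
    tss = np.zeros(G, dtype=int)
    for i in range(G):
        order_on_chrom[chroms[i]] += 1
        tss[i] = 1_000_000 * order_on_chrom[chroms[i]]
    strand = np.where(rng.random(G) < 0.5, "+", "-")

    # temporal programs
    families = np.full(G, "constant", dtype=object)
    temporal = rng.choice(G, size=int(round(spec.frac_temporal * G)), replace=False)
    fam_choices = rng.choice(["linear", "logistic", "sinusoid"], size=len(temporal))
    families[temporal] = fam_choices
    amplitude = rng.uniform(*spec.program_amplitude, size=G) * np.where(
        rng.random(G) < 0.5, 1.0, -1.0)
    param1 = rng.uniform(0.3, 0.7, size=G)   # logistic midpoint / sinusoid phase
    param2 = rng.uniform(0.5, 1.0, size=G)   # sinusoid frequency

    # planted sex effects: escape-like genes on chrX, plus autosomal F-up/M-up
    sex_lfc = np.zeros(G)
    escape = rng.choice(chrx, size=min(spec.n_escape_genes, len(chrx)), replace=False)
    sex_lfc[escape] = spec.sex_lfc
    autosomal = np.where(chroms != "chrX")[0]
    n_dyn = spec.n_dynamic_sex_genes
    picked = rng.choice(autosomal, size=2 * spec.n_sex_genes + n_dyn, replace=False)
    sex_lfc[picked[: spec.n_sex_genes]] = spec.sex_lfc
    sex_lfc[picked[spec.n_sex_genes: 2 * spec.n_sex_genes]] = -spec.sex_lfc
    sex_dynamic = np.array([""] * G, dtype=object)
    dyn = picked[2 * spec.n_sex_genes:]
    sex_lfc[dyn] = spec.sex_lfc  # female-biased while active
    sex_dynamic[dyn[: n_dyn // 2]] = "ramp_in"
    sex_dynamic[dyn[n_dyn // 2:]] = "ramp_out"

    theta = rng.uniform(*spec.theta_range, size=G)
    pi = rng.uniform(*spec.pi_range, size=G)

    genes = pd.DataFrame({
        "chrom": chroms, "tss": tss, "strand": strand,
        "program": families, "amplitude": amplitude,
        "param1": param1, "param2": param2,
        "sex_lfc": sex_lfc, "sex_dynamic": sex_dynamic,
        "escape": np.isin(np.arange(G), escape),
        "theta": theta, "pi": pi,
    }, index=gene_ids)

    # peaks: lag-coupled peaks sit in the upstream window of a temporal gene
    alpha = rng.uniform(-2.5, -0.5, size=P)
    tau = np.zeros(P)
    beta = np.zeros(P)
    paired_gene = np.array([""] * P, dtype=object)
    # lags are planted only on genes with curvature in the window: for a
    # monotone trajectory, a time shift leaves the Pearson correlation
    # profile flat and the lag is unidentifiable by construction
    sinusoid_pool = [i for i in temporal if families[i] == "sinusoid"]
    chosen = rng.choice(sinusoid_pool, size=min(spec.n_lag_pairs, len(sinusoid_pool) * 4),
                        replace=True)
    peak_chrom = np.array([f"chr{1 + i % 5}" for i in range(P)], dtype=object)
    peak_start = rng.integers(1, 5_000_000, size=P)
    for j, gi in enumerate(chosen):
        if j >= P:
            break
        mag = rng.uniform(*spec.lag_magnitude)
        tau[j] = mag * (1 if rng.random() < 0.5 else -1)
        beta[j] = spec.lag_beta
        paired_gene[j] = gene_ids[gi]
        peak_chrom[j] = chroms[gi]
        if strand[gi] == "+":
            peak_start[j] = tss[gi] - int(rng.integers(1_000, 190_000))
        else:
            peak_start[j] = tss[gi] + int(rng.integers(1_000, 190_000))
    peak_end = peak_start + 500

    peaks = pd.DataFrame({
        "chrom": peak_chrom, "start": peak_start, "end": peak_end,
        "alpha": alpha, "beta": beta, "tau": tau, "gene": paired_gene,
    }, index=peak_ids)

    base = rng.normal(0.0, 0.5, size=(spec.n_cell_types, G))
    for k in range(spec.n_cell_types):
        markers = rng.choice(G, size=min(spec.type_marker_genes, G), replace=False)
        base[k, markers] += spec.type_marker_lfc

    truth = GroundTruth(genes=genes, peaks=peaks,
                        time_points=np.asarray(spec.time_points, dtype=float),
                        cell_type_base=base,
                        sex_switch_time=spec.sex_switch_time)
    # per-type loading vectors of the scalar cell-state axis
    truth.state_loading_rna = rng.normal(0.0, spec.cell_state_sd,
                                         size=(spec.n_cell_types, G))
    truth.state_loading_atac = rng.normal(0.0, spec.cell_state_sd,
                                          size=(spec.n_cell_types, P))
    return truth


def simulate_multiomic_timeseries(spec: SimulationSpec):
    """Generate (TimeSeriesDataset, GroundTruth); fully seed-deterministic.

    RNA counts are ZINB with mean = depth x softmax(log-intensity), where
    the log-intensity sums cell-type base, temporal program, sex effect
    (applied to female cells) and a per-batch gene offset. ATAC peaks are
    Bernoulli; lag-coupled peaks follow their gene's program evaluated at
    t + tau. A fraction of ATAC cells carry a co-assayed RNA twin sharing
    a pair_id. Features live in a union space (gene columns then peak
    columns); each cell is nonzero only on its own modality's columns.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _build_truth(spec, rng)
    avail = spec.resolved_sex_availability()
    G, P, K = spec.n_genes, spec.n_peaks, spec.n_cell_types
    gene_ids = list(truth.genes.index)
    peak_ids = list(truth.peaks.index)
    batch_fx = rng.normal(0.0, spec.batch_sd, size=(spec.n_batches, G))

    type_marker_peaks = [rng.choice(P, size=min(30, P), replace=False) for _ in range(K)]
    prog_cache = {}  # (time,) -> (G,) program values

    def programs_at(t):
        key = round(float(t), 9)
        if key not in prog_cache:
            prog_cache[key] = truth.program_values(gene_ids, [t])[:, 0]
        return prog_cache[key]

    def rna_counts(k, sex, batch, t, u):
        n = len(u)
        eta = truth.cell_type_base[k] + programs_at(t) + batch_fx[batch]
        if sex == "F":
            eta = eta + truth.sex_lfc_at(gene_ids, t)
        eta = eta[None, :] + u[:, None] * truth.state_loading_rna[k][None, :]
        rho = np.exp(eta - eta.max(axis=1, keepdims=True))
        rho = rho / rho.sum(axis=1, keepdims=True)
        depth = rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, size=n)
        mu = depth[:, None] * rho
        theta = truth.genes["theta"].to_numpy()
        nb = rng.negative_binomial(theta[None, :], theta[None, :] / (theta[None, :] + mu))
        drop = rng.random((n, G)) < truth.genes["pi"].to_numpy()[None, :]
        return np.where(drop, 0, nb)

    def atac_binary(k, t, u):
        n = len(u)
        logits = truth.peak_logits(peak_ids, [t])[:, 0].copy()
        logits[type_marker_peaks[k]] += 1.5
        logits = logits[None, :] + u[:, None] * truth.state_loading_atac[k][None, :]
        return (rng.random((n, P)) < expit(logits)).astype(np.int64)

    X_rows, obs_rows = [], []
    pair_counter = 0
    for ti, t in enumerate(spec.time_points):
        sexes = avail[ti]
        for k in range(K):
            # RNA cells
            per_sex = max(1, spec.rna_cells_per_type_per_time // len(sexes))
            for sex in sexes:
                counts = rna_counts(k, sex, ti % spec.n_batches, t,
                                    rng.standard_normal(per_sex))
                full = np.zeros((per_sex, G + P))
                full[:, :G] = counts
                X_rows.append(full)
                obs_rows.append(pd.DataFrame({
                    "time_days": t, "condition": sex, "batch": f"b{ti % spec.n_batches}",
                    "modality": "RNA", "cell_type": f"type{k}", "pair_id": "",
                }, index=range(per_sex)))
            # ATAC cells (+ co-assay RNA twins)
            n_atac = max(1, spec.atac_cells_per_type_per_time // len(sexes))
            for sex in sexes:
                u_atac = rng.standard_normal(n_atac)
                acc = atac_binary(k, t, u_atac)
                n_pair = int(round(spec.coassay_frac * n_atac))
                pids = [""] * n_atac
                for j in range(n_pair):
                    pids[j] = f"pair{pair_counter:06d}"
                    pair_counter += 1
                full = np.zeros((n_atac, G + P))
                full[:, G:] = acc
                X_rows.append(full)
                obs_rows.append(pd.DataFrame({
                    "time_days": t, "condition": sex, "batch": f"b{ti % spec.n_batches}",
                    "modality": "ATAC", "cell_type": f"type{k}", "pair_id": pids,
                }, index=range(n_atac)))
                if n_pair:
                    # co-assay twins share the cell state of their ATAC mate
                    twin = rna_counts(k, sex, ti % spec.n_batches, t, u_atac[:n_pair])
                    full = np.zeros((n_pair, G + P))
                    full[:, :G] = twin
                    X_rows.append(full)
                    obs_rows.append(pd.DataFrame({
                        "time_days": t, "condition": sex,
                        "batch": f"b{ti % spec.n_batches}", "modality": "RNA",
                        "cell_type": f"type{k}", "pair_id": pids[:n_pair],
                    }, index=range(n_pair)))

    X = sp.csr_matrix(np.vstack(X_rows))
    obs = pd.concat(obs_rows, ignore_index=True)
    var = pd.DataFrame(index=gene_ids + peak_ids)
    var["feature_type"] = ["gene"] * G + ["peak"] * P
    var["chrom"] = list(truth.genes["chrom"]) + list(truth.peaks["chrom"])
    var["tss"] = list(truth.genes["tss"]) + [np.nan] * P
    var["strand"] = list(truth.genes["strand"]) + [""] * P
    var["start"] = [np.nan] * G + list(truth.peaks["start"])
    var["end"] = [np.nan] * G + list(truth.peaks["end"])
    data = TimeSeriesDataset(counts=X, obs=obs, var=var)
    return data, truth
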