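"""Synthetic cohorts with the statistical structure the pipeline assumes.

Counts follow a negative-binomial model through a Gaussian copula: per sample
a latent normal vector is drawn in which each planted miRNA–ceRNA pair is
bivariate with correlation rho_normal (normal samples and non-metastatic
tumors) or rho_met (metastatic tumors); all other genes are independent.  The
latent normals are pushed through the NB quantile function, which preserves
rank correlation — the signal both MIC and PCC-on-log-CPM respond to — while
attenuating the Pearson value somewhat (tested with loose tolerance rather
than inverted analytically).  Library sizes are drawn log-normally (CV 30%)
so TMM normalization has real composition work to do.  TNM stages are
consistent with the labels (positives N1–3/M0, negatives N0/M0) and survival
is exponential with the hazard multiplied by ``survival_effect`` for
metastatic samples, administratively censored at a fixed horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_labels import ExpressionMatrix, SampleTable, assign_labels


@dataclass
class SimConfig:
    """Cohort-simulation parameters (defaults are desk-scale TCGA-like)."""

    n_normal: int = 100
    n_tumor_pos: int = 80
    n_tumor_neg: int = 80
    n_mirna: int = 50
    n_cerna_per_biotype: int = 200  # for each of mRNA, lncRNA, pseudogene
    n_signal_pairs: int = 40
    rho_normal: float = 0.8  # planted-pair correlation in normals/negatives
    rho_met: float = 0.0  # planted-pair correlation in metastatic tumors
    nb_dispersion: float = 0.3  # var = mu + dispersion * mu^2
    mean_log_expression: float = 4.0  # natural-log mean of gene base means
    sd_log_expression: float = 1.0
    lib_size_cv: float = 0.3
    survival_base_hazard: float = 1.0 / 1500.0  # events per day
    survival_effect: float = 2.5  # hazard multiplier for metastatic samples
    censor_horizon: float = 2000.0  # days of administrative follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_tumor_pos", "n_tumor_neg", "n_mirna",
                     "n_cerna_per_biotype", "n_signal_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (abs(self.rho_normal) < 1 and abs(self.rho_met) < 1):
            raise ValueError("|rho| must be < 1")
        if self.n_signal_pairs > min(self.n_mirna, 3 * self.n_cerna_per_biotype):
            raise ValueError("more signal pairs than available miRNAs or ceRNAs")


@dataclass
class GroundTruth:
    """Planted pairs and per-sample truth emitted alongside a simulation."""

    pairs: pd.DataFrame  # mirna_id, rna_id, rho_normal, rho_met
    sample_truth: pd.DataFrame = field(repr=False)  # sample_id, label, hazard_multiplier

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["mirna_id"], self.pairs["rna_id"]))

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def _nb_quantile(u: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mu)
    return stats.nbinom.ppf(u, size, p)


def _counts_from_latent(z, base_mu, lib_factor, dispersion):
    """Gaussian copula: latent N(0,1) -> uniform -> NB quantile per cell."""
    u = stats.norm.cdf(z)
    mu = base_mu[:, None] * lib_factor[None, :]
    return _nb_quantile(u, mu, dispersion)


def simulate_cohort(cfg: SimConfig):
    """Simulate (miRNA matrix, ceRNA matrix, SampleTable, GroundTruth).

    Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_normal + cfg.n_tumor_pos + cfg.n_tumor_neg
    sample_ids = (
        [f"N{i:04d}" for i in range(cfg.n_normal)]
        + [f"TP{i:04d}" for i in range(cfg.n_tumor_pos)]
        + [f"TN{i:04d}" for i in range(cfg.n_tumor_neg)]
    )
    is_met = np.array([False] * cfg.n_normal + [True] * cfg.n_tumor_pos
                      + [False] * cfg.n_tumor_neg)
    is_tumor = np.array([False] * cfg.n_normal
                        + [True] * (cfg.n_tumor_pos + cfg.n_tumor_neg))

    mir_ids = [f"miR-{i:03d}" for i in range(cfg.n_mirna)]
    biotypes = ["mRNA", "lncRNA", "pseudogene"]
    rna_ids, rna_bt = [], []
    for bt in biotypes:
        for i in range(cfg.n_cerna_per_biotype):
            rna_ids.append(f"{bt}-{i:03d}")
            rna_bt.append(bt)
    n_cerna = len(rna_ids)

    # planted pairs: disjoint miRNA/ceRNA slots, ceRNAs cycled over biotypes
    signal_mir = list(range(cfg.n_signal_pairs))
    signal_rna = [(i % 3) * cfg.n_cerna_per_biotype + i // 3
                  for i in range(cfg.n_signal_pairs)]

    z_mir = rng.standard_normal((cfg.n_mirna, n_samples))
    z_rna = rng.standard_normal((n_cerna, n_samples))
    rho = np.where(is_met, cfg.rho_met, cfg.rho_normal)
    for mi, ri in zip(signal_mir, signal_rna):
        # correlate the ceRNA latent with the miRNA latent, group-wise rho
        z_rna[ri] = rho * z_mir[mi] + np.sqrt(1 - rho ** 2) * z_rna[ri]

    mu_mir = np.exp(rng.normal(cfg.mean_log_expression, cfg.sd_log_expression,
                               cfg.n_mirna))
    mu_rna = np.exp(rng.normal(cfg.mean_log_expression, cfg.sd_log_expression,
                               n_cerna))
    sigma_lib = np.sqrt(np.log(1 + cfg.lib_size_cv ** 2))
    lib_mir = np.exp(rng.normal(0, sigma_lib, n_samples))
    lib_rna = np.exp(rng.normal(0, sigma_lib, n_samples))

    mir_counts = _counts_from_latent(z_mir, mu_mir, lib_mir, cfg.nb_dispersion)
    rna_counts = _counts_from_latent(z_rna, mu_rna, lib_rna, cfg.nb_dispersion)

    mirna = ExpressionMatrix(
        values=pd.DataFrame(mir_counts, index=mir_ids, columns=sample_ids),
        biotype=pd.Series("miRNA", index=mir_ids))
    cerna = ExpressionMatrix(
        values=pd.DataFrame(rna_counts, index=rna_ids, columns=sample_ids),
        biotype=pd.Series(rna_bt, index=rna_ids))

    t_stage = rng.integers(1, 5, n_samples)
    n_stage = np.where(is_met, rng.integers(1, 4, n_samples), 0)
    hazard_mult = np.where(is_met, cfg.survival_effect, 1.0)
    hazard = cfg.survival_base_hazard * hazard_mult
    raw_time = rng.exponential(1.0 / hazard)
    time = np.minimum(raw_time, cfg.censor_horizon)
    event = (raw_time <= cfg.censor_horizon).astype(int)
    # survival fields only meaningful for tumor samples
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "sample_type": np.where(is_tumor, "tumor", "normal"),
        "t_stage": np.where(is_tumor, [f"T{t}" for t in t_stage], ""),
        "n_stage": np.where(is_tumor, [f"N{n}" for n in n_stage], ""),
        "m_stage": np.where(is_tumor, "M0", ""),
        "survival_time": np.where(is_tumor, np.maximum(time, 1.0), np.nan),
        "event": np.where(is_tumor, event, np.nan),
    })
    samples = assign_labels(SampleTable(meta))

    truth = GroundTruth(
        pairs=pd.DataFrame({
            "mirna_id": [mir_ids[i] for i in signal_mir],
            "rna_id": [rna_ids[i] for i in signal_rna],
            "rho_normal": cfg.rho_normal,
            "rho_met": cfg.rho_met,
        }),
        sample_truth=pd.DataFrame({
            "sample_id": sample_ids,
            "label": np.where(is_tumor, np.where(is_met, "positive", "negative"),
                              "not_applicable"),
            "hazard_multiplier": hazard_mult,
        }),
    )
    return mirna, cerna, samples, truth


#: the fixed cohort every end-to-end check runs on
ACCEPTANCE_CONFIG = SimConfig(
    n_normal=100, n_tumor_pos=80, n_tumor_neg=80,
    n_mirna=50, n_cerna_per_biotype=200, n_signal_pairs=40,
    rho_normal=0.8, rho_met=0.0, seed=20220417,
)


def default_acceptance_cohort():
    """The published default cohort: 100 normals, 80+80 tumors, 50 miRNAs,
    600 ceRNAs (200 per biotype), 40 planted pairs with rho 0.8 -> 0.0."""
    return simulate_cohort(ACCEPTANCE_CONFIG)
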