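"""Low-expression filtering and TMM (trimmed mean of M-values) normalization.

TMM corrects between-sample composition bias in RNA-seq counts: for each
sample a scaling factor is computed as a precision-weighted, doubly trimmed
mean of gene-wise log expression ratios (M-values) against a reference
sample, following the canonical definition (30% trimmed from each tail of M,
5% from each tail of A, asymptotic binomial precision weights, factors
centred to geometric mean 1).  Downstream correlation work uses
log2 counts-per-million on the TMM-effective library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_labels import ExpressionMatrix


def filter_low_expression(m: ExpressionMatrix, min_mean: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose mean count across all samples is below ``min_mean``.

    The default threshold of 1 removes genes unexpressed in most samples.
    Gene order is preserved; an empty result is a hard error.
    """
    if m.layer != "raw_counts":
        raise ValueError("filter_low_expression expects raw counts")
    keep = m.values.mean(axis=1) >= min_mean
    if not keep.any():
        raise ValueError("no gene passes the mean-count filter")
    return m.subset_genes(m.values.index[keep])


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and library sizes.

    Factors are dimensionless, positive, and centred so their geometric mean
    is 1; ``lib_size * factor`` is the effective library size.
    """

    factors: pd.Series  # index = sample ids
    lib_sizes: pd.Series

    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": self.factors.index, "lib_size": self.lib_sizes.values,
             "factor": self.factors.values}
        ).to_csv(path, sep="\t", index=False)


def _quantile_ratio(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    # per-sample p-th quantile of count/libsize, used to pick the reference
    return np.array([np.quantile(counts[:, j], p) / lib[j] for j in range(counts.shape[1])])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05,
              a_cutoff: float = -1e10) -> float:
    """TMM factor of one sample against the reference (log2 scale returned as 2**f)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))  # M values
    abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0  # A values
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)  # 1/precision
    keep = abs_e > a_cutoff
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    # ranks are 1-based, average ranks for ties (matches edgeR's rank())
    rank_m = pd.Series(log_r).rank().to_numpy()
    rank_a = pd.Series(abs_e).rank().to_numpy()
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.nansum(log_r[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    if abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(m: ExpressionMatrix, ref_sample: str | None = None) -> NormFactors:
    """Compute TMM scaling factors for every sample of a raw-count matrix.

    The reference sample is the one whose 75th-percentile count/library-size
    ratio is closest to the cohort mean, unless given explicitly.
    """
    if m.layer != "raw_counts":
        raise ValueError("tmm_factors expects raw counts")
    counts = m.values.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        zero = m.values.columns[lib == 0]
        raise ValueError(f"sample(s) with zero total count: {list(zero[:5])}")
    f75 = _quantile_ratio(counts, lib)
    if ref_sample is None:
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = m.sample_ids.index(ref_sample)
    factors = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_j], lib[j], lib[ref_j])
        for j in range(counts.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    cols = m.values.columns
    return NormFactors(factors=pd.Series(factors, index=cols),
                       lib_sizes=pd.Series(lib, index=cols))


def normalize_logcpm(m: ExpressionMatrix, f: NormFactors | None = None,
                     prior: float = 0.5) -> ExpressionMatrix:
    """log2 CPM on TMM-effective library sizes.

    value = log2((count + prior) / (lib_size * factor + 2 * prior) * 1e6)
    """
    if m.layer != "raw_counts":
        raise ValueError("normalize_logcpm expects raw counts")
    if f is None:
        f = tmm_factors(m)
    eff = f.effective_lib_sizes().reindex(m.values.columns).to_numpy()
    vals = np.log2(
        (m.values.to_numpy(dtype=float) + prior) / (eff + 2.0 * prior) * 1e6
    )
    return replace(
        m,
        values=pd.DataFrame(vals, index=m.values.index, columns=m.values.columns),
        layer="tmm_logcpm",
    )
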