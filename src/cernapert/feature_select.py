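"""Differential-correlation feature selection: Wilcoxon rank-sum + PCA.

Pairs whose ΔPCC distributions differ between metastatic (positive) and
non-metastatic (negative) tumors at p < 0.01 (two-sided rank-sum, raw p — no
multiple-testing correction, though a Benjamini–Hochberg column is reported
for information) are retained, then the pairs x samples ΔPCC block is reduced
by centered PCA.  By default both steps are fitted on the training samples
only; ``fit_ids=None`` reproduces the all-sample variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .delta_pcc import DeltaPccMatrix
from .io_labels import LABEL_NEGATIVE, LABEL_POSITIVE, SampleTable

logger = logging.getLogger(__name__)


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration when |a|+|b| <= 12 with no ties; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(q, 0, 1)


@dataclass
class FeatureSet:
    """Wilcoxon-selected pairs plus the fitted PCA reduction of their ΔPCCs."""

    pairs: pd.DataFrame  # mirna_id, rna_id, rna_biotype, p_value, bh_fdr
    alpha: float = 0.01
    n_pc: int | None = None
    pca_components: np.ndarray | None = None  # selected-pairs x n_pc loadings
    pca_center: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None
    scores: pd.DataFrame | None = field(default=None, repr=False)  # samples x PCs

    @property
    def pair_ids(self) -> list[str]:
        return [f"{m}_{r}" for m, r in
                zip(self.pairs["mirna_id"], self.pairs["rna_id"])]

    def transform(self, delta_block: np.ndarray) -> np.ndarray:
        """Project a selected-pairs x samples ΔPCC block onto the fitted PCs."""
        if self.pca_components is None:
            raise ValueError("PCA not fitted; call pca_reduce first")
        return (delta_block - self.pca_center[:, None]).T @ self.pca_components

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def select_pairs(delta: DeltaPccMatrix, labels: SampleTable,
                 alpha: float = 0.01) -> FeatureSet:
    """Keep pairs whose ΔPCC differs between positive and negative tumors.

    p-values compare the ΔPCC of metastatic vs non-metastatic samples per
    pair (two-sided rank-sum).  Zero surviving pairs is a hard error that
    reports the minimum observed p.
    """
    pos = [s for s in labels.ids_with_label(LABEL_POSITIVE) if s in delta.sample_ids]
    neg = [s for s in labels.ids_with_label(LABEL_NEGATIVE) if s in delta.sample_ids]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 samples per class among the ΔPCC columns")
    cols = {s: j for j, s in enumerate(delta.sample_ids)}
    a = delta.delta[:, [cols[s] for s in pos]]
    b = delta.delta[:, [cols[s] for s in neg]]
    if a.shape[1] + b.shape[1] > 12:
        p = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", axis=1).pvalue
    else:
        p = np.array([rank_sum_test(a[i], b[i]) for i in range(a.shape[0])])
    selected = p < alpha
    if not selected.any():
        raise ValueError(
            f"no pair passed the rank-sum filter at alpha={alpha} "
            f"(minimum observed p = {p.min():.3g})")
    pairs = delta.pairs[selected].reset_index(drop=True).copy()
    pairs["p_value"] = p[selected]
    pairs["bh_fdr"] = _bh_fdr(p)[selected]
    logger.info("rank-sum filter kept %d / %d pairs at p < %g",
                int(selected.sum()), p.size, alpha)
    return FeatureSet(pairs=pairs, alpha=alpha)


def pca_reduce(features: FeatureSet, delta: DeltaPccMatrix,
               n_pc: int | None = None, fit_ids=None,
               variance_target: float = 0.9) -> FeatureSet:
    """Fit a centered SVD-based PCA of the selected pairs' ΔPCCs and project
    all samples.

    Components are fitted on ``fit_ids`` only (all samples when None).  When
    ``n_pc`` is None the smallest number of components explaining
    ``variance_target`` of the variance is used.  ΔPCC features are centered
    but not variance-scaled (they share the [−2, 2] scale).
    """
    sel_mask = delta.pairs.merge(
        features.pairs[["mirna_id", "rna_id"]], how="left", indicator=True
    )["_merge"].eq("both").to_numpy()
    block = delta.delta[sel_mask]  # selected pairs x all samples
    fit_ids = list(fit_ids) if fit_ids is not None else list(delta.sample_ids)
    cols = {s: j for j, s in enumerate(delta.sample_ids)}
    fit_block = block[:, [cols[s] for s in fit_ids]]

    max_pc = min(block.shape[0], len(fit_ids))
    if n_pc is not None and n_pc > max_pc:
        raise ValueError(f"n_pc={n_pc} exceeds min(#pairs, #fit samples)={max_pc}")
    center = fit_block.mean(axis=1)
    xc = (fit_block - center[:, None]).T  # fit samples x pairs
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2 / max(len(fit_ids) - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    if n_pc is None:
        n_pc = int(np.searchsorted(np.cumsum(ratio), variance_target) + 1)
        n_pc = min(n_pc, max_pc)
    components = vt[:n_pc].T  # pairs x n_pc, orthonormal columns
    scores = (block - center[:, None]).T @ components
    logger.info("PCA: %d components (%.1f%% variance explained)",
                n_pc, 100 * ratio[:n_pc].sum())
    return FeatureSet(
        pairs=features.pairs, alpha=features.alpha, n_pc=n_pc,
        pca_components=components, pca_center=center,
        explained_variance_ratio=ratio[:n_pc],
        scores=pd.DataFrame(scores, index=delta.sample_ids,
                            columns=[f"PC{i+1}" for i in range(n_pc)]),
    )
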