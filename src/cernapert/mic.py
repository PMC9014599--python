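"""Maximal information coefficient (MIC) screening of miRNA–ceRNA pairs.

MIC measures linear or non-linear association between two variables on a
[0, 1] scale: over all grids with n_X columns and n_Y rows whose size is
bounded by B = n^alpha, the mutual information of the induced discrete joint
distribution is maximized and normalized by log2 min(n_X, n_Y).  Candidate
miRNA–RNA pairs are kept when MIC >= 0.5 in either the normal or the tumor
cohort; weaker pairs are not considered ceRNA interactions.

The default grid bound follows the strict form n_X * n_Y < B (with B clamped
so a 2x2 grid is always admissible); ``inclusive_b=True`` switches to the
n_X * n_Y <= B convention of the original MINE description.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mic_kernels import _mic_kernel
from .io_labels import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class MicConfig:
    """Parameters of the MIC estimator and the pair screen.

    ``alpha`` sets the grid budget B = floor(n^alpha); ``clump_factor`` is the
    superclump multiplier c of ApproxMaxMI; ``threshold`` is the keep cutoff
    applied to max(MIC_normal, MIC_tumor); ``inclusive_b`` switches the grid
    admissibility from n_X*n_Y < B (default) to <= B.
    """

    alpha: float = 0.6
    clump_factor: int = 15
    threshold: float = 0.5
    inclusive_b: bool = False

    def grid_limit(self, n: int) -> int:
        """Largest admissible n_X * n_Y for a sample of size n (>= 4 always)."""
        b = int(np.floor(n ** self.alpha))
        limit = b if self.inclusive_b else b - 1
        return max(limit, 4)


def grid_mutual_information(x, y, x_edges, y_edges) -> float:
    """Mutual information (bits) of the grid partition induced by the edges.

    Cell probabilities are point counts / n; 0·log(0) terms contribute 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two points")
    xb = np.searchsorted(np.asarray(x_edges, dtype=float), x, side="right")
    yb = np.searchsorted(np.asarray(y_edges, dtype=float), y, side="right")
    return _mi_from_bins(xb, yb, n)


def _mi_from_bins(xb, yb, n) -> float:
    nx = int(xb.max()) + 1
    ny = int(yb.max()) + 1
    joint = np.bincount(xb * ny + yb, minlength=nx * ny).reshape(nx, ny) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / np.outer(px, py))
    return float(np.nansum(term))


def mic(x, y, cfg: MicConfig | None = None) -> float:
    """MIC score of two samples via the ApproxMaxMI search.

    Constant input gives 0 with a warning (no informative partition exists).
    """
    cfg = cfg or MicConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input to mic(); returning 0", stacklevel=2)
        return 0.0
    limit = cfg.grid_limit(x.size)
    return float(
        _mic_kernel(x, y, np.argsort(x, kind="mergesort"),
                    np.argsort(y, kind="mergesort"), limit, cfg.clump_factor)
    )


def _cut_positions(sorted_vals) -> np.ndarray:
    """Midpoints between distinct consecutive sorted values (valid cut sites)."""
    distinct = np.flatnonzero(np.diff(sorted_vals) > 0)
    return (sorted_vals[distinct] + sorted_vals[distinct + 1]) / 2.0


def mic_brute_force(x, y, cfg: MicConfig | None = None) -> float:
    """Exhaustive MIC: search every admissible grid shape and every placement
    of cuts between distinct data values.  Exponential; intended as the test
    oracle for n <= ~30.
    """
    cfg = cfg or MicConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    limit = cfg.grid_limit(n)
    xcuts = _cut_positions(np.sort(x))
    ycuts = _cut_positions(np.sort(y))
    best = 0.0
    for nx in range(2, limit // 2 + 1):
        for ny in range(2, limit // nx + 1):
            if len(xcuts) < nx - 1 or len(ycuts) < ny - 1:
                continue
            denom = np.log2(min(nx, ny))
            for xe in itertools.combinations(xcuts, nx - 1):
                xb = np.searchsorted(np.array(xe), x, side="right")
                for ye in itertools.combinations(ycuts, ny - 1):
                    yb = np.searchsorted(np.array(ye), y, side="right")
                    score = _mi_from_bins(xb, yb, n) / denom
                    if score > best:
                        best = score
    return min(best, 1.0)


@dataclass
class PairTable:
    """Candidate miRNA–RNA pairs with per-cohort MIC scores and keep flags."""

    table: pd.DataFrame  # columns: mirna_id, rna_id, rna_biotype, mic_normal, mic_tumor, kept
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.table.duplicated(["mirna_id", "rna_id"]).any():
            raise ValueError("duplicate (mirna_id, rna_id) pair")

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["kept"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, threshold: float = 0.5) -> "PairTable":
        return cls(pd.read_csv(path, sep="\t"), threshold=threshold)


def screen_pairs(mirna: ExpressionMatrix, cerna: ExpressionMatrix,
                 normal_ids, tumor_ids, cfg: MicConfig | None = None,
                 chunk_size: int = 2000) -> PairTable:
    """Score every (miRNA, ceRNA) combination by MIC in the normal and tumor
    cohorts separately and keep pairs with MIC >= threshold in either.

    Rows are ordered deterministically (miRNA id, then RNA id); progress is
    logged per chunk.
    """
    cfg = cfg or MicConfig()
    normal_ids, tumor_ids = list(normal_ids), list(tumor_ids)
    if set(normal_ids) & set(tumor_ids):
        raise ValueError("normal and tumor id sets overlap")
    for ids, name in ((normal_ids, "normal"), (tumor_ids, "tumor")):
        if len(ids) < 11:
            raise ValueError(f"need >= 11 {name} samples for MIC screening")

    mir_ids = sorted(mirna.gene_ids)
    rna_ids = sorted(cerna.gene_ids)
    cohorts = []
    for ids in (normal_ids, tumor_ids):
        xm = mirna.values.loc[mir_ids, ids].to_numpy(dtype=float)
        ym = cerna.values.loc[rna_ids, ids].to_numpy(dtype=float)
        cohorts.append((
            xm, ym,
            np.argsort(xm, axis=1, kind="mergesort"),
            np.argsort(ym, axis=1, kind="mergesort"),
            cfg.grid_limit(len(ids)),
        ))

    n_pairs = len(mir_ids) * len(rna_ids)
    scores = np.zeros((2, n_pairs))
    biotypes = cerna.biotype.loc[rna_ids].to_numpy()
    done = 0
    for mi, mir in enumerate(mir_ids):
        for ci, (xm, ym, xo, yo, limit) in enumerate(cohorts):
            const_x = np.all(xm[mi] == xm[mi, 0])
            for ri in range(len(rna_ids)):
                idx = mi * len(rna_ids) + ri
                if const_x or np.all(ym[ri] == ym[ri, 0]):
                    scores[ci, idx] = 0.0
                else:
                    scores[ci, idx] = _mic_kernel(
                        xm[mi], ym[ri], xo[mi], yo[ri], limit, cfg.clump_factor
                    )
        done += len(rna_ids)
        if done % chunk_size < len(rna_ids):
            logger.info("MIC screen: %d / %d pairs scored", done, n_pairs)

    table = pd.DataFrame({
        "mirna_id": np.repeat(mir_ids, len(rna_ids)),
        "rna_id": np.tile(rna_ids, len(mir_ids)),
        "rna_biotype": np.tile(biotypes, len(mir_ids)),
        "mic_normal": scores[0],
        "mic_tumor": scores[1],
    })
    table["kept"] = (table["mic_normal"] >= cfg.threshold) | \
                    (table["mic_tumor"] >= cfg.threshold)
    if not table["kept"].any():
        warnings.warn("no pair passed the MIC threshold", stacklevel=2)
    logger.info("MIC screen kept %d / %d pairs", int(table["kept"].sum()), n_pairs)
    return PairTable(table, threshold=cfg.threshold)
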