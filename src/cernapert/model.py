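"""Top-level modelling interface.

``CeRNAMetastasisModel`` bundles the whole procedure — TMM-normalized
expression, MIC screening of miRNA–ceRNA pairs, single-sample ΔPCC
perturbation features, Wilcoxon + PCA feature selection and the SVM/LR
stacking classifier — behind a statsmodels-style ``Model.fit() -> Results``
pair.  The Results object carries the fitted stages, the cross-validation
and independent-test metrics, and hangs survival screening and network
construction off the fitted ΔPCC matrix.

Example
-------
>>> from cernapert.synthdata import default_acceptance_cohort
>>> from cernapert.model import CeRNAMetastasisModel
>>> mirna, cerna, samples, _ = default_acceptance_cohort()
>>> res = CeRNAMetastasisModel(mirna, cerna, samples).fit(seed=1)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify
from .delta_pcc import DeltaPccMatrix, perturbation_matrix
from .feature_select import FeatureSet, pca_reduce, select_pairs
from .io_labels import (
    ExpressionMatrix,
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    SampleTable,
    assign_labels,
    load_biotype_map,
    load_expression,
)
from .mic import MicConfig, PairTable, screen_pairs
from .network import build_global, build_patient
from .preprocess import filter_low_expression, normalize_logcpm, tmm_factors
from .survival import SurvivalRecords, survival_screen

logger = logging.getLogger(__name__)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Fan one seed out to independent per-stage seeds (< 2^31)."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


class CeRNAMetastasisModel:
    """Lymph-node-metastasis model over miRNA/ceRNA expression and TNM labels.

    Parameters
    ----------
    mirna, cerna
        Raw-count expression matrices (miRNAs and ceRNA candidates).  A single
        combined matrix can be split with ``ExpressionMatrix.split_by_biotype``.
    samples
        Sample metadata; metastasis labels are derived from TNM stages if not
        already assigned.
    mic_config
        MIC estimator / screen settings.
    wilcox_alpha
        Raw two-sided rank-sum threshold for differentially correlated pairs.
    n_pc
        Number of principal components; None selects the smallest number
        explaining 90% of the ΔPCC variance.
    paper_mode
        When True, the Wilcoxon filter and PCA are fitted on all tumor
        samples (the replication variant); the default fits them on the
        training portion only, giving honest test metrics.
    """

    def __init__(self, mirna: ExpressionMatrix, cerna: ExpressionMatrix,
                 samples: SampleTable, *, mic_config: MicConfig | None = None,
                 wilcox_alpha: float = 0.01, n_pc: int | None = None,
                 split_ratio: float = 0.7, folds: int = 5, grid=None,
                 min_mean_count: float = 1.0, paper_mode: bool = False):
        self.mirna = mirna
        self.cerna = cerna
        self.samples = samples if "label" in samples.table.columns \
            else assign_labels(samples)
        self.mic_config = mic_config or MicConfig()
        self.wilcox_alpha = wilcox_alpha
        self.n_pc = n_pc
        self.split_ratio = split_ratio
        self.folds = folds
        self.grid = grid
        self.min_mean_count = min_mean_count
        self.paper_mode = paper_mode

    @classmethod
    def from_tsv(cls, expression_path, biotype_path, samples_path,
                 mirna_path=None, **kwargs) -> "CeRNAMetastasisModel":
        """Build from TSV files; ``expression_path`` may hold all biotypes
        (split internally) or only ceRNAs with miRNAs in ``mirna_path``."""
        bt = load_biotype_map(biotype_path)
        samples = SampleTable.from_tsv(samples_path)
        if mirna_path is None:
            both = load_expression(expression_path, bt)
            mirna, cerna = both.split_by_biotype()
        else:
            mirna = load_expression(mirna_path, bt)
            cerna = load_expression(expression_path, bt)
        return cls(mirna, cerna, samples, **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self, seed: int = 0) -> "CeRNAMetastasisResults":
        """Run every stage and return the fitted results."""
        split_seed, grid_seed, cv_seed, _ = _stage_seeds(seed)
        samples = self.samples
        normal_ids = samples.normal_ids
        tumor_ids = (samples.ids_with_label(LABEL_POSITIVE)
                     + samples.ids_with_label(LABEL_NEGATIVE))
        label_of = dict(samples.table["label"])

        logger.info("preprocess: mean-count filter + TMM log-CPM")
        mirna_n = self._normalize(self.mirna, normal_ids + tumor_ids)
        cerna_n = self._normalize(self.cerna, normal_ids + tumor_ids)

        pair_table = screen_pairs(mirna_n, cerna_n, normal_ids, tumor_ids,
                                  self.mic_config)
        delta = perturbation_matrix(pair_table, mirna_n, cerna_n,
                                    normal_ids, tumor_ids)

        train_ids, test_ids = classify.split_cohort(
            samples, ratio=self.split_ratio, seed=split_seed)
        fit_ids = None if self.paper_mode else train_ids
        sel_cols = delta.sample_ids if self.paper_mode else train_ids
        sel_delta = DeltaPccMatrix(
            pairs=delta.pairs, sample_ids=list(sel_cols),
            pcc_normal=delta.pcc_normal,
            delta=delta.delta[:, [delta.sample_ids.index(s) for s in sel_cols]])
        features = select_pairs(sel_delta, samples, alpha=self.wilcox_alpha)
        features = pca_reduce(features, delta, n_pc=self.n_pc, fit_ids=fit_ids)

        y_train = np.array([label_of[s] == LABEL_POSITIVE for s in train_ids],
                           dtype=int)
        y_test = np.array([label_of[s] == LABEL_POSITIVE for s in test_ids],
                          dtype=int)
        x_train = features.scores.loc[train_ids].to_numpy()
        x_test = features.scores.loc[test_ids].to_numpy()

        model = classify.fit_stacking(x_train, y_train, grid=self.grid,
                                      seed=grid_seed, inner_folds=self.folds)
        from sklearn.base import clone
        cv_report = classify.cross_validate(
            x_train, y_train, estimator=clone(model.estimator),
            k=self.folds, seed=cv_seed)
        test_report = classify.evaluate(model, x_test, y_test)

        return CeRNAMetastasisResults(
            model=self, seed=seed, mirna_norm=mirna_n, cerna_norm=cerna_n,
            pair_table=pair_table, delta=delta, features=features,
            stacking=model, cv_report=cv_report, test_report=test_report,
            train_ids=list(train_ids), test_ids=list(test_ids),
        )

    def _normalize(self, m: ExpressionMatrix, ids) -> ExpressionMatrix:
        sub = m.subset_samples(ids)
        filt = filter_low_expression(sub, self.min_mean_count)
        return normalize_logcpm(filt, tmm_factors(filt))


@dataclass
class CeRNAMetastasisResults:
    """Fitted pipeline state, metrics and downstream analyses."""

    model: CeRNAMetastasisModel
    seed: int
    mirna_norm: ExpressionMatrix = field(repr=False)
    cerna_norm: ExpressionMatrix = field(repr=False)
    pair_table: PairTable = field(repr=False)
    delta: DeltaPccMatrix = field(repr=False)
    features: FeatureSet = field(repr=False)
    stacking: classify.StackingModel = field(repr=False)
    cv_report: classify.MetricsReport
    test_report: classify.MetricsReport
    train_ids: list[str] = field(repr=False)
    test_ids: list[str] = field(repr=False)

    @property
    def stage_counts(self) -> dict:
        """Feature counts after each filtering stage."""
        return {
            "candidate_pairs": int(len(self.pair_table.table)),
            "after_mic": int(self.pair_table.table["kept"].sum()),
            "after_wilcox": int(len(self.features.pairs)),
            "after_pca": int(self.features.n_pc),
        }

    def survival_screen(self, records: SurvivalRecords | None = None,
                        alpha: float = 0.01) -> pd.DataFrame:
        """Log-rank screen of the selected pairs' ΔPCC median splits."""
        if records is None:
            records = SurvivalRecords.from_sample_table(self.model.samples)
        sel = self._selected_delta()
        return survival_screen(sel, records, alpha=alpha,
                               mirna=self.mirna_norm, cerna=self.cerna_norm)

    def global_network(self):
        return build_global(self.features)

    def patient_network(self, sample_id: str, quantile: float = 0.5):
        return build_patient(self._selected_delta(), sample_id, quantile)

    def _selected_delta(self) -> DeltaPccMatrix:
        mask = self.delta.pairs.merge(
            self.features.pairs[["mirna_id", "rna_id"]], how="left",
            indicator=True)["_merge"].eq("both").to_numpy()
        return self.delta.subset_pairs(mask)

    def summary(self) -> str:
        """Plain-text overview of the fitted pipeline."""
        sc = self.stage_counts
        lines = [
            "ceRNA-perturbation lymph-node-metastasis model",
            "=" * 56,
            f"samples: {len(self.model.samples.normal_ids)} normal, "
            f"{len(self.train_ids)} train / {len(self.test_ids)} test tumor",
            f"pairs: {sc['candidate_pairs']} candidates -> "
            f"{sc['after_mic']} after MIC >= {self.model.mic_config.threshold} -> "
            f"{sc['after_wilcox']} after rank-sum p < {self.model.wilcox_alpha} -> "
            f"{sc['after_pca']} principal components",
            f"stacking hyperparameters: {self.stacking.best_params}",
            "-" * 56,
            f"{'metric':<8}{'CV (train)':>14}{'test':>14}",
        ]
        cv, te = self.cv_report.as_dict(), self.test_report.as_dict()
        for k in ("SN", "SP", "ACC", "PPV", "NPV", "AUC"):
            cvv = "nan" if cv[k] is None else f"{cv[k]:.3f}"
            tev = "nan" if te[k] is None else f"{te[k]:.3f}"
            lines.append(f"{k:<8}{cvv:>14}{tev:>14}")
        return "\n".join(lines)

    def metrics_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "cv": self.cv_report.as_dict(),
            "test": self.test_report.as_dict(),
            "best_params": self.stacking.best_params,
            "seed": self.seed,
        }
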