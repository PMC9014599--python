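"""Composable pipeline stages with a single config file and cached
intermediates.

``run_all`` executes filter -> TMM -> MIC screen -> ΔPCC -> Wilcoxon -> PCA
-> stacking train/CV/test -> survival screen -> networks inside a run
directory.  Each expensive stage writes its output as TSV/JSON and is loaded
from cache on rerun, so deleting one stage's output reruns only that stage
and later ones.  One config seed fans out to per-stage seeds, making every
stage independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify
from .delta_pcc import DeltaPccMatrix, perturbation_matrix
from .feature_select import FeatureSet, pca_reduce, select_pairs
from .io_labels import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    SampleTable,
    assign_labels,
    load_biotype_map,
    load_expression,
)
from .mic import MicConfig, PairTable, screen_pairs
from .model import _stage_seeds
from .network import biotype_counts, build_global, build_patient, export_network, hub_mirnas
from .preprocess import filter_low_expression, normalize_logcpm, tmm_factors
from .survival import SurvivalRecords, survival_screen
from .synthdata import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs: input paths and all module parameters."""

    mirna_path: str = ""
    cerna_path: str = ""
    biotype_path: str = ""
    samples_path: str = ""
    min_mean_count: float = 1.0
    mic_threshold: float = 0.5
    mic_alpha: float = 0.6
    mic_clumps: int = 15
    mic_inclusive_b: bool = False
    wilcox_alpha: float = 0.01
    n_pc: int | None = None
    split_ratio: float = 0.7
    folds: int = 5
    survival_alpha: float = 0.01
    paper_mode: bool = False
    seed: int = 0

    def mic_config(self) -> MicConfig:
        return MicConfig(alpha=self.mic_alpha, clump_factor=self.mic_clumps,
                         threshold=self.mic_threshold,
                         inclusive_b=self.mic_inclusive_b)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _cached(path: Path, loader, compute_and_save):
    if path.exists():
        logger.info("stage cached: %s", path.name)
        return loader(path)
    out = compute_and_save(path)
    return out


class PipelineRun:
    """Stage orchestration inside one run directory."""

    def __init__(self, cfg: PipelineConfig, run_dir):
        self.cfg = cfg
        self.dir = Path(run_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(self.dir / "resolved_config.yaml")
        seeds = _stage_seeds(cfg.seed)
        self.split_seed, self.grid_seed, self.cv_seed, self.sim_seed = seeds
        self._stage = "init"

    def _fail(self, exc: Exception):
        status = {"status": "error", "stage": self._stage, "error": str(exc)}
        (self.dir / "status.json").write_text(json.dumps(status, indent=2))
        raise RuntimeError(f"pipeline stage {self._stage!r} failed: {exc}") from exc

    # -- stages ----------------------------------------------------------

    def load_inputs(self):
        self._stage = "load"
        bt = load_biotype_map(self.cfg.biotype_path)
        self.samples = SampleTable.from_tsv(self.cfg.samples_path)
        if "label" not in self.samples.table.columns:
            self.samples = assign_labels(self.samples)
        mirna = load_expression(self.cfg.mirna_path, bt)
        cerna = load_expression(self.cfg.cerna_path, bt)
        self.normal_ids = self.samples.normal_ids
        self.tumor_ids = (self.samples.ids_with_label(LABEL_POSITIVE)
                          + self.samples.ids_with_label(LABEL_NEGATIVE))
        ids = self.normal_ids + self.tumor_ids
        self.mirna_raw = mirna.subset_samples(ids)
        self.cerna_raw = cerna.subset_samples(ids)
        self.samples.to_tsv(self.dir / "labels.tsv")

    def preprocess(self):
        self._stage = "preprocess"

        def compute(path):
            out = []
            for name, raw in (("mirna", self.mirna_raw), ("cerna", self.cerna_raw)):
                filt = filter_low_expression(raw, self.cfg.min_mean_count)
                nf = tmm_factors(filt)
                nf.to_tsv(self.dir / f"tmm_{name}.tsv")
                norm = normalize_logcpm(filt, nf)
                df = norm.values.copy()
                df.insert(0, "biotype", norm.biotype.values)
                df.to_csv(self.dir / f"{name}_logcpm.tsv", sep="\t",
                          index_label="gene_id")
                out.append(norm)
            return tuple(out)

        def load(path):
            from .io_labels import ExpressionMatrix
            out = []
            for name in ("mirna", "cerna"):
                df = pd.read_csv(self.dir / f"{name}_logcpm.tsv", sep="\t",
                                 index_col=0)
                bt = df.pop("biotype")
                out.append(ExpressionMatrix(values=df, biotype=bt,
                                            layer="tmm_logcpm"))
            return tuple(out)

        self.mirna_n, self.cerna_n = _cached(
            self.dir / "cerna_logcpm.tsv", load, compute)

    def mic_screen(self):
        self._stage = "mic"

        def compute(path):
            pairs = screen_pairs(self.mirna_n, self.cerna_n, self.normal_ids,
                                 self.tumor_ids, self.cfg.mic_config())
            pairs.to_tsv(path)
            return pairs

        self.pairs = _cached(
            self.dir / "pairs.tsv",
            lambda p: PairTable.from_tsv(p, threshold=self.cfg.mic_threshold),
            compute)

    def deltapcc(self):
        self._stage = "deltapcc"

        def compute(path):
            delta = perturbation_matrix(self.pairs, self.mirna_n, self.cerna_n,
                                        self.normal_ids, self.tumor_ids)
            delta.to_long_tsv(path)
            return delta

        self.delta = _cached(self.dir / "delta_pcc.tsv",
                             DeltaPccMatrix.from_long_tsv, compute)

    def select(self):
        self._stage = "select"
        self.train_ids, self.test_ids = classify.split_cohort(
            self.samples, ratio=self.cfg.split_ratio, seed=self.split_seed)
        fit_ids = None if self.cfg.paper_mode else self.train_ids
        cols = self.delta.sample_ids if self.cfg.paper_mode else self.train_ids
        sub = DeltaPccMatrix(
            pairs=self.delta.pairs, sample_ids=list(cols),
            pcc_normal=self.delta.pcc_normal,
            delta=self.delta.delta[:, [self.delta.sample_ids.index(s)
                                       for s in cols]])
        features = select_pairs(sub, self.samples, alpha=self.cfg.wilcox_alpha)
        self.features = pca_reduce(features, self.delta, n_pc=self.cfg.n_pc,
                                   fit_ids=fit_ids)
        self.features.to_tsv(self.dir / "selected_pairs.tsv")

    def train_and_evaluate(self):
        self._stage = "train"
        label_of = dict(self.samples.table["label"])
        y = {s: int(label_of[s] == LABEL_POSITIVE)
             for s in self.train_ids + self.test_ids}

        def compute(path):
            from sklearn.base import clone
            x_tr = self.features.scores.loc[self.train_ids].to_numpy()
            y_tr = np.array([y[s] for s in self.train_ids])
            x_te = self.features.scores.loc[self.test_ids].to_numpy()
            y_te = np.array([y[s] for s in self.test_ids])
            model = classify.fit_stacking(x_tr, y_tr, seed=self.grid_seed,
                                          inner_folds=self.cfg.folds)
            cv = classify.cross_validate(x_tr, y_tr,
                                         estimator=clone(model.estimator),
                                         k=self.cfg.folds, seed=self.cv_seed)
            test = classify.evaluate(model, x_te, y_te)
            metrics = {
                "stage_counts": self.stage_counts(),
                "cv": cv.as_dict(), "test": test.as_dict(),
                "best_params": model.best_params, "seed": self.cfg.seed,
            }
            path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
            return metrics

        self.metrics = _cached(self.dir / "metrics.json",
                               lambda p: json.loads(p.read_text()), compute)

    def survival(self):
        self._stage = "survival"
        if "survival_time" not in self.samples.table.columns:
            logger.info("no survival columns; skipping survival screen")
            self.survival_table = None
            return
        records = SurvivalRecords.from_sample_table(self.samples)
        sel = self._selected_delta()
        self.survival_table = survival_screen(
            sel, records, alpha=self.cfg.survival_alpha,
            mirna=self.mirna_n, cerna=self.cerna_n)
        self.survival_table.to_csv(self.dir / "survival_screen.tsv",
                                   sep="\t", index=False)

    def networks(self):
        self._stage = "network"
        g = build_global(self.features)
        export_network(g, self.dir / "global_network.graphml")
        export_network(g, self.dir / "global_network_edges.tsv", fmt="edge_tsv")
        hub_mirnas(g).to_csv(self.dir / "hub_mirnas.tsv", sep="\t", index=False)
        sel = self._selected_delta()
        rows = [(s, build_patient(sel, s).number_of_edges())
                for s in sel.sample_ids]
        pd.DataFrame(rows, columns=["sample_id", "n_edges"]).to_csv(
            self.dir / "patient_network_summary.tsv", sep="\t", index=False)
        counts = {"nodes": g.number_of_nodes(), "edges": g.number_of_edges(),
                  "biotypes": biotype_counts(g)}
        (self.dir / "network_counts.json").write_text(
            json.dumps(counts, indent=2, sort_keys=True))

    def _selected_delta(self) -> DeltaPccMatrix:
        mask = self.delta.pairs.merge(
            self.features.pairs[["mirna_id", "rna_id"]], how="left",
            indicator=True)["_merge"].eq("both").to_numpy()
        return self.delta.subset_pairs(mask)

    def stage_counts(self) -> dict:
        return {
            "candidate_pairs": int(len(self.pairs.table)),
            "after_mic": int(self.pairs.table["kept"].sum()),
            "after_wilcox": int(len(self.features.pairs)),
            "after_pca": int(self.features.n_pc),
        }


def run_all(cfg: PipelineConfig, run_dir) -> Path:
    """Execute every stage; returns the run directory.

    Any stage error aborts with the stage name and writes a machine-readable
    ``status.json``.
    """
    run = PipelineRun(cfg, run_dir)
    try:
        run.load_inputs()
        run.preprocess()
        run.mic_screen()
        run.deltapcc()
        run.select()
        run.train_and_evaluate()
        run.survival()
        run.networks()
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        run._fail(exc)
    counts = run.stage_counts()
    (run.dir / "stage_counts.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True))
    (run.dir / "status.json").write_text(
        json.dumps({"status": "ok", "stage_counts": counts}, indent=2,
                   sort_keys=True))
    logger.info("run complete: %s", run.dir)
    return run.dir


def simulate_to_dir(sim: SimConfig, out_dir) -> PipelineConfig:
    """Write a simulated cohort as the TSV inputs the pipeline reads and
    return a config pointing at them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirna, cerna, samples, truth = simulate_cohort(sim)
    mirna.values.to_csv(out / "mirna_counts.tsv", sep="\t", index_label="gene_id")
    cerna.values.to_csv(out / "cerna_counts.tsv", sep="\t", index_label="gene_id")
    bt = pd.concat([mirna.biotype, cerna.biotype])
    bt.to_csv(out / "biotypes.tsv", sep="\t", header=False)
    samples.to_tsv(out / "samples.tsv")
    truth.to_tsv(out / "ground_truth_pairs.tsv")
    return PipelineConfig(
        mirna_path=str(out / "mirna_counts.tsv"),
        cerna_path=str(out / "cerna_counts.tsv"),
        biotype_path=str(out / "biotypes.tsv"),
        samples_path=str(out / "samples.tsv"),
        seed=sim.seed,
    )
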