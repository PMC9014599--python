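"""Kaplan–Meier estimation and log-rank screening of ΔPCC-defined groups.

For each miRNA–RNA pair, tumor samples are split into a high and a low ΔPCC
group at the median (ties to the low group) and overall survival is compared
by the log-rank test.  For context, the same median-split test is run on the
pair's miRNA and RNA expression individually, so the pair-vs-single-gene
comparison is part of every screen.  Raw p-values are reported (with a
Benjamini–Hochberg column for information only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .delta_pcc import DeltaPccMatrix
from .feature_select import _bh_fdr
from .io_labels import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecords:
    """Right-censored survival data: time in days (> 0), event 1 = death."""

    table: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self) -> None:
        if (self.table["time"] <= 0).any():
            bad = self.table.loc[self.table["time"] <= 0, "sample_id"]
            raise ValueError(f"non-positive survival time for {list(bad[:5])}")
        self.table = self.table.set_index("sample_id", drop=False)

    @classmethod
    def from_sample_table(cls, samples: SampleTable) -> "SurvivalRecords":
        df = samples.table
        ok = df["survival_time"].notna() & df["event"].notna() & \
            (df["sample_type"] == "tumor")
        return cls(pd.DataFrame({
            "sample_id": df.loc[ok, "sample_id"].values,
            "time": df.loc[ok, "survival_time"].astype(float).values,
            "event": df.loc[ok, "event"].astype(int).values,
        }))

    def subset(self, sample_ids) -> "SurvivalRecords":
        ids = [s for s in sample_ids if s in self.table.index]
        return SurvivalRecords(self.table.loc[ids].reset_index(drop=True))


def km_curve(records: SurvivalRecords) -> pd.DataFrame:
    """Product-limit survival estimate as a right-continuous step function.

    Returns a DataFrame with columns ``time`` and ``survival``; starts at
    S(0) = 1 and is non-increasing.
    """
    if len(records.table) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(records.table["time"], records.table["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(group_a: SurvivalRecords, group_b: SurvivalRecords):
    """Log-rank test (observed − expected with hypergeometric variance).

    Returns (chi2, p); with no events at all the statistic is undefined and
    (nan, nan) is returned.
    """
    if len(group_a.table) == 0 or len(group_b.table) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.table["event"].sum() + group_b.table["event"].sum() == 0:
        return float("nan"), float("nan")
    res = logrank_test(group_a.table["time"], group_b.table["time"],
                       event_observed_A=group_a.table["event"],
                       event_observed_B=group_b.table["event"])
    return float(res.test_statistic), float(res.p_value)


def _median_split_pvalue(values: np.ndarray, records: SurvivalRecords,
                         sample_ids) -> tuple[float, float]:
    """Log-rank p for the median split of ``values`` (ties go low)."""
    med = np.median(values)
    high = [s for s, v in zip(sample_ids, values) if v > med]
    low = [s for s, v in zip(sample_ids, values) if v <= med]
    if not high or not low:
        return float("nan"), float("nan")
    return logrank(records.subset(high), records.subset(low))


def survival_screen(delta: DeltaPccMatrix, records: SurvivalRecords,
                    alpha: float = 0.01,
                    mirna: ExpressionMatrix | None = None,
                    cerna: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Per-pair log-rank test of high- vs low-ΔPCC patients, ranked by p.

    When expression matrices are provided, each pair's individual miRNA and
    RNA (median expression split) are tested too, for the pair-vs-gene
    comparison.  The full ranked table is returned with a ``significant``
    flag at ``alpha``; no multiple-testing correction is applied to the
    ranking (BH values are informational).
    """
    ids = [s for s in delta.sample_ids if s in records.table.index]
    if len(ids) < 10:
        raise ValueError("need >= 10 samples with survival data")
    rec = records.subset(ids)
    cols = [delta.sample_ids.index(s) for s in ids]
    rows = []
    for i in range(delta.delta.shape[0]):
        chi2, p = _median_split_pvalue(delta.delta[i, cols], rec, ids)
        row = {
            "mirna_id": delta.pairs["mirna_id"].iloc[i],
            "rna_id": delta.pairs["rna_id"].iloc[i],
            "rna_biotype": delta.pairs["rna_biotype"].iloc[i],
            "chi2": chi2, "p_pair": p,
        }
        if mirna is not None:
            vals = mirna.values.loc[row["mirna_id"], ids].to_numpy(dtype=float)
            row["p_mirna"] = _median_split_pvalue(vals, rec, ids)[1]
        if cerna is not None:
            vals = cerna.values.loc[row["rna_id"], ids].to_numpy(dtype=float)
            row["p_rna"] = _median_split_pvalue(vals, rec, ids)[1]
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("p_pair", kind="mergesort")
    out = out.reset_index(drop=True)
    finite = out["p_pair"].notna()
    out["bh_fdr"] = np.nan
    out.loc[finite, "bh_fdr"] = _bh_fdr(out.loc[finite, "p_pair"].to_numpy())
    out["significant"] = out["p_pair"] < alpha
    logger.info("survival screen: %d / %d pairs with p < %g",
                int(out["significant"].sum()), len(out), alpha)
    return out


def plot_km_pair(delta: DeltaPccMatrix, records: SurvivalRecords, mirna_id: str,
                 rna_id: str, path=None):
    """Kaplan–Meier curves of the high vs low ΔPCC groups of one pair."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = (delta.pairs["mirna_id"] == mirna_id) & (delta.pairs["rna_id"] == rna_id)
    if not mask.any():
        raise ValueError(f"pair {mirna_id}_{rna_id} not in the ΔPCC matrix")
    i = int(np.flatnonzero(mask)[0])
    ids = [s for s in delta.sample_ids if s in records.table.index]
    cols = [delta.sample_ids.index(s) for s in ids]
    vals = delta.delta[i, cols]
    med = np.median(vals)
    fig, ax = plt.subplots()
    for name, keep in (("high ΔPCC", vals > med), ("low ΔPCC", vals <= med)):
        sub = records.subset([s for s, k in zip(ids, keep) if k])
        kmf = KaplanMeierFitter(label=name)
        kmf.fit(sub.table["time"], sub.table["event"])
        kmf.plot_survival_function(ax=ax)
    chi2, p = _median_split_pvalue(vals, records.subset(ids), ids)
    ax.set_title(f"{mirna_id}_{rna_id}  (log-rank p = {p:.2e})")
    ax.set_xlabel("days")
    ax.set_ylabel("overall survival")
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
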