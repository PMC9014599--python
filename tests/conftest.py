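import numpy as np
import pandas as pd
import pytest

from cernapert.io_labels import ExpressionMatrix, SampleTable, assign_labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expression(values, gene_ids=None, sample_ids=None, biotype="mRNA",
                    layer="raw_counts"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    if isinstance(biotype, str):
        biotype = [biotype] * len(gene_ids)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        biotype=pd.Series(biotype, index=gene_ids), layer=layer)


def make_samples(n_normal, n_pos, n_neg, survival=False, rng=None):
    ids = ([f"N{i}" for i in range(n_normal)] + [f"P{i}" for i in range(n_pos)]
           + [f"G{i}" for i in range(n_neg)])
    stype = ["normal"] * n_normal + ["tumor"] * (n_pos + n_neg)
    tstage = [""] * n_normal + ["T2"] * (n_pos + n_neg)
    nstage = [""] * n_normal + ["N1"] * n_pos + ["N0"] * n_neg
    mstage = [""] * n_normal + ["M0"] * (n_pos + n_neg)
    df = pd.DataFrame({"sample_id": ids, "sample_type": stype,
                       "t_stage": tstage, "n_stage": nstage,
                       "m_stage": mstage})
    if survival:
        rng = rng or np.random.default_rng(0)
        df["survival_time"] = np.where(
            df["sample_type"].eq("tumor"), rng.exponential(500, len(df)) + 1,
            np.nan)
        df["event"] = np.where(df["sample_type"].eq("tumor"),
                               rng.integers(0, 2, len(df)), np.nan)
    return assign_labels(SampleTable(df))
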