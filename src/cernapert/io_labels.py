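"""Expression/metadata I/O and metastasis labelling from TNM stages.

Expression matrices are genes x samples TSV files with a header row of sample
ids and gene ids in the first column.  Sample metadata is a TSV with the
columns ``sample_id``, ``sample_type``, ``t_stage``, ``n_stage``, ``m_stage``
and optionally ``survival_time`` and ``event``.

Lymph-node-metastasis labels are derived from TNM staging: a tumor sample with
T stage 1-4, N stage 1-3 and M stage 0 is ``positive`` (node metastasis);
T 1-4, N 0, M 0 is ``negative``; M stage 1 is ``excluded`` (distant metastasis
confounds the endpoint), as is any tumor sample with a required stage missing.
Normal samples are ``not_applicable``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOTYPES = ("miRNA", "mRNA", "lncRNA", "pseudogene")

#: biotype strings as they appear in Ensembl GTF files, mapped to our four classes
_GTF_BIOTYPE_MAP = {
    "miRNA": "miRNA",
    "protein_coding": "mRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "pseudogene": "pseudogene",
}

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_EXCLUDED = "excluded"
LABEL_NA = "not_applicable"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-gene biotype.

    ``layer`` records what the values are: ``raw_counts`` straight from the
    TSV, or ``tmm_logcpm`` after normalization.
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    biotype: pd.Series  # index = gene ids, values in BIOTYPES
    layer: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene id(s): {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample id(s): {list(dups[:5])}")
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()]
            raise ValueError(f"genes without biotype: {list(missing[:5])}")
        if self.layer == "raw_counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw_counts layer contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return replace(
            self, values=self.values.loc[gene_ids], biotype=self.biotype.loc[gene_ids]
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values[list(sample_ids)])

    def split_by_biotype(self) -> tuple["ExpressionMatrix", "ExpressionMatrix"]:
        """Split into (miRNA matrix, ceRNA matrix) by per-gene biotype."""
        is_mir = self.biotype == "miRNA"
        return (
            self.subset_genes(self.values.index[is_mir]),
            self.subset_genes(self.values.index[~is_mir]),
        )


def load_biotype_map(path) -> pd.Series:
    """Read a two-column TSV (gene_id, biotype) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("biotype map must have two columns: gene_id, biotype")
    # tolerate a header row
    if df.iloc[0, 0].lower() in ("gene_id", "gene", "id"):
        df = df.iloc[1:]
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    bad = set(ser.unique()) - set(BIOTYPES)
    if bad:
        raise ValueError(f"unknown biotype(s) in map: {sorted(bad)}")
    return ser


def biotype_map_from_gtf(path) -> pd.Series:
    """Extract a gene_id -> biotype table from a GTF annotation file.

    Convenience that reduces a GTF to the two-column mapping the pipeline
    needs; only ``gene`` features are used and Ensembl biotype strings are
    collapsed onto {miRNA, mRNA, lncRNA, pseudogene}.  Unmapped biotypes are
    dropped.
    """
    gene_re = re.compile(r'gene_id "([^"]+)"')
    bt_re = re.compile(r'gene_(?:bio)?type "([^"]+)"')
    ids, bts = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            gm, bm = gene_re.search(parts[8]), bt_re.search(parts[8])
            if not gm or not bm:
                continue
            mapped = _GTF_BIOTYPE_MAP.get(bm.group(1))
            if mapped is not None:
                ids.append(gm.group(1))
                bts.append(mapped)
    return pd.Series(bts, index=ids)


def load_expression(path, biotype_map: pd.Series) -> ExpressionMatrix:
    """Read a genes x samples TSV and attach biotypes.

    Genes absent from ``biotype_map`` are dropped (count logged).  Duplicate
    gene ids or non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate gene id(s) in {path}: {list(dups[:5])}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value in column {col!r}, row(s) {list(bad_rows[:3])}"
            )
    annotated = df.index.intersection(biotype_map.index)
    n_dropped = df.shape[0] - len(annotated)
    if len(annotated) == 0:
        raise ValueError("no gene in the expression file is covered by the biotype map")
    if n_dropped:
        logger.info("dropped %d gene(s) without biotype annotation", n_dropped)
    df = df.loc[annotated]
    return ExpressionMatrix(values=df, biotype=biotype_map.loc[annotated].copy())


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


_STAGE_RE = re.compile(r"^[TNM]?\s*(\d+)", re.IGNORECASE)


def parse_stage(value) -> int | None:
    """Parse a TNM stage field to its leading integer, or None if unknown.

    Accepts clinical dialects like ``N1a``, ``T2b``, plain integers, and maps
    ``NX``/``TX``/``MX``/empty to unknown.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "unknown", "na"):
        return None
    m = _STAGE_RE.match(s)
    if m is None:
        return None
    return int(m.group(1))


@dataclass
class SampleTable:
    """Per-sample metadata: cohort group, TNM stages, survival, derived label."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "sample_type", "t_stage", "n_stage", "m_stage")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample table missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        self.table = self.table.set_index("sample_id", drop=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def normal_ids(self) -> list[str]:
        return list(self.table.index[self.table["sample_type"] == "normal"])

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.table.index[self.table["sample_type"] == "tumor"])

    def ids_with_label(self, label: str) -> list[str]:
        if "label" not in self.table.columns:
            raise ValueError("labels not assigned yet; call assign_labels first")
        return list(self.table.index[self.table["label"] == label])


def assign_labels(samples: SampleTable) -> SampleTable:
    """Derive the metastasis label for every sample from its TNM stages.

    Rules (tumor samples): T in 1-4, N in 1-3, M = 0 -> positive;
    T in 1-4, N = 0, M = 0 -> negative; M = 1 -> excluded; any required stage
    unknown -> excluded.  Normal samples -> not_applicable.
    """
    df = samples.table.copy()
    labels = []
    for _, row in df.iterrows():
        if row["sample_type"] == "normal":
            labels.append(LABEL_NA)
            continue
        t = parse_stage(row["t_stage"])
        n = parse_stage(row["n_stage"])
        m = parse_stage(row["m_stage"])
        if m == 1:
            labels.append(LABEL_EXCLUDED)
        elif t is None or n is None or m is None:
            labels.append(LABEL_EXCLUDED)
        elif 1 <= t <= 4 and 1 <= n <= 3 and m == 0:
            labels.append(LABEL_POSITIVE)
        elif 1 <= t <= 4 and n == 0 and m == 0:
            labels.append(LABEL_NEGATIVE)
        else:
            labels.append(LABEL_EXCLUDED)
    df["label"] = labels
    return SampleTable(df.reset_index(drop=True))
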