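"""Global and patient-specific ceRNA networks.

The global network has one edge per Wilcoxon-selected miRNA–RNA pair; nodes
are miRNAs and ceRNAs (mRNA/lncRNA/pseudogene), so the graph is bipartite by
construction.  A patient's network keeps the pairs whose |ΔPCC| in that
patient is strictly larger than the pair's median |ΔPCC| over all tumor
samples of the cohort — the interactions perturbed more in this patient than
in a typical one.  Edge weights carry the signed ΔPCC (the threshold uses the
absolute value), so the direction of the correlation change is preserved.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .delta_pcc import DeltaPccMatrix
from .feature_select import FeatureSet

logger = logging.getLogger(__name__)


def _add_pair_edges(g: nx.Graph, rows, weights=None) -> None:
    for i, (_, row) in enumerate(rows.iterrows()):
        g.add_node(row["mirna_id"], biotype="miRNA")
        g.add_node(row["rna_id"], biotype=row["rna_biotype"])
        w = 1.0 if weights is None else float(weights[i])
        g.add_edge(row["mirna_id"], row["rna_id"], weight=w)


def biotype_counts(g: nx.Graph) -> dict:
    counts: dict[str, int] = {}
    for _, bt in g.nodes(data="biotype"):
        counts[bt] = counts.get(bt, 0) + 1
    return counts


def build_global(selected: FeatureSet) -> nx.Graph:
    """Bipartite miRNA–ceRNA graph with one edge per selected pair."""
    if len(selected.pairs) == 0:
        raise ValueError("empty pair selection")
    g = nx.Graph(scope="global")
    _add_pair_edges(g, selected.pairs)
    logger.info("global network: %d nodes, %d edges, biotypes %s",
                g.number_of_nodes(), g.number_of_edges(), biotype_counts(g))
    return g


def build_patient(delta: DeltaPccMatrix, sample_id: str,
                  quantile: float = 0.5) -> nx.Graph:
    """Patient-specific subnetwork by the strict median-|ΔPCC| rule.

    An edge for pair p is present iff |ΔPCC[p, sample]| is strictly greater
    than the ``quantile`` (default median) of |ΔPCC[p, ·]| over all tumor
    samples.  Edge weight = the signed ΔPCC of this patient.

    The upper empirical quantile is used, so fewer than half of the patients
    can carry any given pair (for an even sample count the interpolated
    median would let exactly half exceed it).
    """
    if sample_id not in delta.sample_ids:
        raise ValueError(f"unknown sample {sample_id!r}")
    absd = np.abs(delta.delta)
    cutoff = np.quantile(absd, quantile, axis=1, method="higher")
    col = delta.column(sample_id)
    keep = np.abs(col) > cutoff
    g = nx.Graph(scope=f"patient:{sample_id}")
    _add_pair_edges(g, delta.pairs[keep], weights=col[keep])
    return g


def hub_mirnas(g: nx.Graph, top_k: int = 10) -> pd.DataFrame:
    """Top-k miRNA nodes by degree (the network's hub report)."""
    rows = [(n, g.degree(n)) for n, bt in g.nodes(data="biotype")
            if bt == "miRNA"]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows[:top_k], columns=["mirna_id", "degree"])


def export_network(g: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a network as GraphML (node biotype + edge weight attributes) or
    as an edge-list TSV (mirna, rna, biotype, weight)."""
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        rows = []
        for u, v, w in g.edges(data="weight"):
            if g.nodes[u].get("biotype") == "miRNA":
                mir, rna = u, v
            else:
                mir, rna = v, u
            rows.append((mir, rna, g.nodes[rna].get("biotype"), w))
        pd.DataFrame(rows, columns=["mirna", "rna", "biotype", "weight"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_node(row["mirna"], biotype="miRNA")
            g.add_node(row["rna"], biotype=row["biotype"])
            g.add_edge(row["mirna"], row["rna"], weight=float(row["weight"]))
        return g
    raise ValueError(f"unknown format {fmt!r}")
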