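"""Anti-correlation refinement of predicted targets and network construction.

Predicted miRNA-target pairs are scored by the Spearman correlation of the
pair's normalized expression across the matched polarized samples; pairs
with SCC strictly below the filter threshold (default -0.5) and BH-adjusted
correlation p strictly below 0.05 form the refined target set, and the
subset with SCC < -0.8 forms the high-confidence network used for hub and
annotation analysis.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

log = logging.getLogger(__name__)


def spearman_edges(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    targets: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation per predicted pair across matched samples.

    Both matrices must carry an identical, ordered sample set (normally the
    polarized M1/M2 samples).  The SCC is the Pearson correlation of
    mid-ranks; its p-value comes from the t approximation
    ``t = scc * sqrt((n-2) / (1-scc^2))``.  Pairs with a constant vector get
    a null SCC and are excluded from BH adjustment (count logged).
    """
    if list(mirna_expr.columns) != list(gene_expr.columns):
        raise ValueError("miRNA and gene matrices must share an identical ordered sample set")
    n = mirna_expr.shape[1]
    rows = []
    n_constant = 0
    for mirna_id, gene_id in targets[["mirna_id", "gene_id"]].itertuples(index=False):
        x = mirna_expr.loc[mirna_id].to_numpy(dtype=float)
        y = gene_expr.loc[gene_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_constant += 1
            rows.append((mirna_id, gene_id, np.nan, np.nan, n))
            continue
        scc, p = sps.spearmanr(x, y)
        rows.append((mirna_id, gene_id, float(scc), float(p), n))
    if n_constant:
        log.info("spearman_edges: %d pairs with a constant vector excluded from testing", n_constant)
    edges = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "scc", "pvalue", "n"])
    edges["adj_pvalue"] = bh_adjust(edges["pvalue"].to_numpy())
    return edges


def filter_targets(
    edges: pd.DataFrame,
    targets: pd.DataFrame | None = None,
    scc_filter: float = -0.5,
    adj_p: float = 0.05,
) -> pd.DataFrame:
    """Refined target pairs: SCC < scc_filter and adjusted p < adj_p (strict).

    When the predicted ``targets`` table is given, its site metadata (best
    site type, site count) is retained on the refined table.
    """
    keep = (edges["scc"] < scc_filter) & (edges["adj_pvalue"] < adj_p)
    refined = edges.loc[keep.fillna(False)].reset_index(drop=True)
    if targets is not None:
        refined = refined.merge(targets, on=["mirna_id", "gene_id"], how="left")
    return refined


def build_network(
    edges: pd.DataFrame,
    network_scc: float = 0.8,
    de_genes: pd.DataFrame | None = None,
    de_mirnas: pd.DataFrame | None = None,
    tf_list=(),
    c2h2_list=(),
) -> nx.Graph:
    """High-confidence bipartite miRNA-target network.

    Keeps edges with SCC strictly below ``-network_scc``.  Gene nodes are
    annotated with is_TF / is_C2H2 / is_DE / direction; miRNA nodes with
    their DE direction, which also splits the edge set into the M1-miRNA
    and M2-miRNA subnetworks.  The graph carries a hub report (genes ranked
    by miRNA in-degree) and summary counts in ``G.graph``.
    """
    kept = edges.loc[edges["scc"] < -abs(network_scc)]
    G = nx.Graph()
    tf_set, c2h2_set = set(tf_list), set(c2h2_list)
    mirna_dir = {}
    if de_mirnas is not None and "direction" in de_mirnas:
        mirna_dir = de_mirnas["direction"].to_dict()
    gene_de, gene_dir = {}, {}
    if de_genes is not None:
        if "de" in de_genes:
            gene_de = de_genes["de"].to_dict()
        if "direction" in de_genes:
            gene_dir = de_genes["direction"].to_dict()
    for row in kept.itertuples(index=False):
        G.add_node(row.mirna_id, bipartite="mirna",
                   direction=mirna_dir.get(row.mirna_id, "unknown"))
        G.add_node(row.gene_id, bipartite="gene",
                   is_TF=row.gene_id in tf_set,
                   is_C2H2=row.gene_id in c2h2_set,
                   is_DE=bool(gene_de.get(row.gene_id, False)),
                   direction=gene_dir.get(row.gene_id, "unknown"))
        G.add_edge(row.mirna_id, row.gene_id, scc=row.scc, adj_pvalue=row.adj_pvalue)
    ignored = (tf_set | c2h2_set) - set(G.nodes)
    if ignored:
        log.info("build_network: %d annotation ids not present in the network", len(ignored))
    genes = [n for n, d in G.nodes(data=True) if d["bipartite"] == "gene"]
    hub = pd.DataFrame(
        {"gene_id": genes, "mirna_degree": [G.degree(g) for g in genes]}
    ).sort_values(["mirna_degree", "gene_id"], ascending=[False, True]).reset_index(drop=True)
    summary = {}
    for cond in ("M1-high", "M2-high"):
        sub_mirnas = [n for n, d in G.nodes(data=True)
                      if d["bipartite"] == "mirna" and d["direction"] == cond]
        sub_genes = sorted({g for m in sub_mirnas for g in G.neighbors(m)})
        down = sum(
            1 for g in sub_genes
            if G.nodes[g]["is_DE"] and G.nodes[g]["direction"] != cond
        )
        summary[cond] = {"n_mirnas": len(sub_mirnas), "n_genes": len(sub_genes),
                         "n_downregulated_targets": down}
    G.graph["hub_report"] = hub
    G.graph["summary"] = summary
    G.graph["n_edges"] = G.number_of_edges()
    return G


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def overlap_with_validated(
    refined: pd.DataFrame,
    validated_pairs,
    universe_size: int,
) -> pd.DataFrame:
    """Per-miRNA Fisher exact test of predicted vs validated target overlap.

    The universe is the number of detected genes.  miRNAs without any
    validated targets are marked not-testable (NaN p).
    """
    validated: dict[str, set] = {}
    for m, g in validated_pairs:
        validated.setdefault(m, set()).add(g)
    rows = []
    for mirna_id, grp in refined.groupby("mirna_id", sort=True):
        pred = set(grp["gene_id"])
        val = validated.get(mirna_id, set())
        a = len(pred & val)
        b = len(pred - val)
        c = len(val - pred)
        d = universe_size - a - b - c
        if d < 0:
            raise ValueError("universe smaller than the union of predicted and validated sets")
        testable = len(val) > 0
        p = fisher_two_sided(a, b, c, d) if testable else np.nan
        rows.append({"mirna_id": mirna_id, "n_predicted": len(pred), "n_validated": len(val),
                     "n_overlap": a, "pvalue": p, "testable": testable})
    return pd.DataFrame(rows)
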