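"""Set-level enrichment statistics.

Three complementary views of the planted / observed regulatory signal:

* GSEA on each miRNA's predicted-target list ranked by the moderated t,
  with leading-edge extraction (the set members before the running-sum
  extremum) and gene-label permutation p-values;
* per-(miRNA, time point) hypergeometric enrichment of targets among the
  genes DE at that time point, BH-adjusted jointly across all cells;
* one-sided hypergeometric over-representation of pathways in each time
  cluster, BH-adjusted within cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .stats import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GseaResult:
    set_id: str
    es: float
    nes: float
    pvalue: float
    leading_edge: list = field(default_factory=list)
    n_hits: int = 0
    n_perm: int = 0
    testable: bool = True


def _order_ranked(ranked: pd.Series) -> pd.Series:
    """Descending by metric; ties broken by gene id (deterministic)."""
    if ranked.index.duplicated().any():
        dup = ranked.index[ranked.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in ranked list: {dup[:5]}")
    frame = ranked.rename("metric").rename_axis("gene").reset_index()
    frame = frame.sort_values(["metric", "gene"], ascending=[False, True])
    return pd.Series(frame["metric"].to_numpy(), index=frame["gene"].to_numpy())


def _es_from_inc(inc: np.ndarray) -> tuple[float, int]:
    run = np.cumsum(inc)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def gsea(
    ranked: pd.Series,
    gene_set,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed=None,
    set_id: str = "",
) -> GseaResult:
    """Weighted Kolmogorov-style enrichment score with permutation p-value.

    The running sum increments by ``|metric|^w / sum_hits |metric|^w`` at
    set hits and decrements by ``1/(N-K)`` at misses; ES is the extremum by
    magnitude.  The null distribution permutes gene labels (random hit
    positions, metric profile fixed); the one-sided p is the +1-smoothed
    frequency of same-sign null scores at least as extreme (conditioning on
    the sign keeps the test calibrated despite the post-hoc sign selection),
    and NES divides ES by the mean magnitude of same-sign null scores.
    Degenerate sets (empty intersection with the list, or covering the
    entire list) return a not-testable result.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ordered = _order_ranked(ranked)
    genes = ordered.index.to_numpy()
    metric = ordered.to_numpy(dtype=float)
    N = len(genes)
    hit = np.isin(genes, list(gene_set))
    K = int(hit.sum())
    if K == 0 or K == N:
        return GseaResult(set_id, np.nan, np.nan, np.nan, [], K, 0, testable=False)

    w = np.abs(metric) ** weight_exponent

    def increments(hit_mask: np.ndarray) -> np.ndarray:
        hw = w * hit_mask
        total = hw.sum(axis=-1, keepdims=True)
        # all-zero metric over hits: fall back to uniform hit increments
        uniform = 1.0 / hit_mask.sum(axis=-1, keepdims=True)
        inc = np.where(total > 0, np.divide(hw, np.where(total > 0, total, 1.0)),
                       uniform * hit_mask)
        inc = inc - (~hit_mask.astype(bool)) / (N - K)
        return inc

    es, i_ext = _es_from_inc(increments(hit.astype(float)))

    rng = np.random.default_rng(seed)
    null_hits = np.zeros((n_perm, N))
    for b in range(n_perm):
        null_hits[b, rng.choice(N, size=K, replace=False)] = 1.0
    runs = np.cumsum(increments(null_hits), axis=1)
    idx = np.argmax(np.abs(runs), axis=1)
    null_es = runs[np.arange(n_perm), idx]

    # the observed ES sign is selected post hoc (extremum by magnitude), so
    # the null comparison conditions on same-sign permutation scores; an
    # unconditional denominator would double the false-positive rate
    same = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
    as_extreme = (same >= es) if es >= 0 else (same <= es)
    p = (1.0 + float(as_extreme.sum())) / (1.0 + len(same))
    nes = es / float(np.abs(same).mean()) if len(same) and np.abs(same).mean() > 0 else np.nan

    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return GseaResult(set_id, es, nes, p, leading, K, n_perm, testable=True)


def mirna_pathway_gsea(
    refined_targets: pd.DataFrame,
    pathways: dict[str, set],
    de_table: pd.DataFrame,
    de_mirnas=None,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    min_targets: int = 10,
    seed=None,
    tf_list=(),
    sig_p: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GSEA of every pathway against each miRNA's ranked target list.

    Ranked list per miRNA = its refined predicted targets ordered by the
    moderated t from the DE table; each pathway is intersected with that
    target list.  Returns the result table (raw and BH-adjusted p within
    miRNA) and the (miRNA, leading-edge gene) network table built from sets
    significant at raw p < ``sig_p``, annotated with gene DE status and TF
    membership.  miRNAs with fewer ranked targets than ``min_targets`` are
    skipped with a log message.
    """
    mirnas = sorted(de_mirnas) if de_mirnas is not None else sorted(refined_targets["mirna_id"].unique())
    tf_set = set(tf_list)
    rng = np.random.default_rng(seed)
    rows, edge_rows = [], []
    for mirna in mirnas:
        target_genes = refined_targets.loc[refined_targets["mirna_id"] == mirna, "gene_id"]
        target_genes = [g for g in target_genes if g in de_table.index]
        if len(target_genes) < min_targets:
            log.info("mirna_pathway_gsea: skipping %s with %d ranked targets (< %d)",
                     mirna, len(target_genes), min_targets)
            continue
        ranked = de_table.loc[target_genes, "t"].astype(float)
        for pw in sorted(pathways):
            members = set(pathways[pw])
            res = gsea(ranked, members, weight_exponent, n_perm,
                       seed=int(rng.integers(2**31)), set_id=pw)
            rows.append({"mirna_id": mirna, "pathway": pw, "es": res.es, "nes": res.nes,
                         "pvalue": res.pvalue, "n_hits": res.n_hits,
                         "testable": res.testable,
                         "leading_edge": ",".join(res.leading_edge)})
    results = pd.DataFrame(rows, columns=["mirna_id", "pathway", "es", "nes", "pvalue",
                                          "n_hits", "testable", "leading_edge"])
    if len(results):
        results["adj_pvalue"] = np.nan
        for mirna, grp in results.groupby("mirna_id"):
            results.loc[grp.index, "adj_pvalue"] = bh_adjust(grp["pvalue"].to_numpy())
        sig = results[(results["testable"]) & (results["pvalue"] < sig_p)]
        for row in sig.itertuples(index=False):
            for gene in row.leading_edge.split(","):
                if not gene:
                    continue
                edge_rows.append({
                    "mirna_id": row.mirna_id, "pathway": row.pathway, "gene_id": gene,
                    "gene_de": bool(de_table.loc[gene, "de"]) if "de" in de_table else False,
                    "is_TF": gene in tf_set,
                })
    else:
        results["adj_pvalue"] = pd.Series(dtype=float)
    edges = pd.DataFrame(edge_rows, columns=["mirna_id", "pathway", "gene_id", "gene_de", "is_TF"])
    return results, edges


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def hypergeom_heatmap(
    targets: pd.DataFrame,
    de_table: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    sig_level: float = 0.05,
) -> pd.DataFrame:
    """Per-(miRNA, time point) enrichment of targets among DE genes.

    The universe is the detected genes (the DE table's index).  A gene is
    DE at time t when ``|log2FC_t| > log2(fc_threshold)`` and its adjusted
    p is below ``p_threshold``.  Cells are BH-adjusted jointly; the output
    carries a significance flag at ``sig_level`` and a display order of
    miRNAs from hierarchical clustering of the flag patterns
    (``result.attrs['mirna_order']``).
    """
    universe = set(de_table.index)
    N = len(universe)
    time_cols = [c for c in de_table.columns if c.startswith("log2fc_")]
    if not time_cols:
        raise ValueError("DE table lacks per-timepoint log2fc columns")
    de_sets = {}
    for col in time_cols:
        mask = (de_table[col].abs() > np.log2(fc_threshold)) & (de_table["adj_pvalue"] < p_threshold)
        de_sets[col] = set(de_table.index[mask])
    rows = []
    for mirna, grp in targets.groupby("mirna_id", sort=True):
        tset = set(grp["gene_id"]) & universe
        K = len(tset)
        for col in time_cols:
            de_genes = de_sets[col]
            n = len(de_genes)
            k = len(tset & de_genes)
            testable = K > 0
            p = hypergeom_pvalue(N, K, n, k) if testable else 1.0
            rows.append({"mirna_id": mirna, "timepoint": col.replace("log2fc_", ""),
                         "N": N, "K": K, "n": n, "k": k, "pvalue": p, "testable": testable})
    cells = pd.DataFrame(rows)
    if len(cells):
        p_for_adj = cells["pvalue"].where(cells["testable"], np.nan).to_numpy()
        cells["adj_pvalue"] = bh_adjust(p_for_adj)
        cells["significant"] = cells["adj_pvalue"] < sig_level
        cells["significant"] = cells["significant"].fillna(False)
        flags = cells.pivot(index="mirna_id", columns="timepoint", values="significant").astype(float)
        if len(flags) > 2:
            link = hierarchy.linkage(flags.to_numpy(), method="average", metric="hamming")
            order = hierarchy.leaves_list(link)
            cells.attrs["mirna_order"] = list(flags.index[order])
        else:
            cells.attrs["mirna_order"] = list(flags.index)
    return cells


def cluster_ora(
    assignments: pd.Series,
    pathways: dict[str, set],
    universe,
    refined_targets: pd.DataFrame | None = None,
    de_mirnas=None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of pathways per cluster.

    ``assignments`` maps gene -> cluster id (negative = unassigned, ignored).
    Pathway members are deduplicated and intersected with the universe;
    pathways absent from the universe are skipped with a log message.  BH
    adjustment is applied within each cluster.  When a refined target table
    is supplied, each row lists the DE miRNAs targeting at least one
    overlapping gene.
    """
    universe = set(universe)
    N = len(universe)
    targeting: dict[str, set] = {}
    if refined_targets is not None:
        keep = refined_targets
        if de_mirnas is not None:
            keep = keep[keep["mirna_id"].isin(set(de_mirnas))]
        for m, g in keep[["mirna_id", "gene_id"]].itertuples(index=False):
            targeting.setdefault(g, set()).add(m)
    rows = []
    clusters = sorted(c for c in assignments.unique() if c >= 0)
    for cluster in clusters:
        genes = set(assignments.index[assignments == cluster]) & universe
        n = len(genes)
        for pw in sorted(pathways):
            members = set(pathways[pw]) & universe
            K = len(members)
            if K == 0:
                log.info("cluster_ora: pathway %s absent from universe, skipped", pw)
                continue
            overlap = sorted(genes & members)
            k = len(overlap)
            p = hypergeom_pvalue(N, K, n, k)
            mirnas = sorted({m for g in overlap for m in targeting.get(g, ())})
            rows.append({"cluster": cluster, "pathway": pw, "N": N, "K": K, "n": n,
                         "k": k, "pvalue": p, "overlap_genes": ",".join(overlap),
                         "de_mirnas": ",".join(mirnas)})
    out = pd.DataFrame(rows, columns=["cluster", "pathway", "N", "K", "n", "k", "pvalue",
                                      "overlap_genes", "de_mirnas"])
    if len(out):
        out["adj_pvalue"] = np.nan
        for cluster, grp in out.groupby("cluster"):
            out.loc[grp.index, "adj_pvalue"] = bh_adjust(grp["pvalue"].to_numpy())
    else:
        out["adj_pvalue"] = pd.Series(dtype=float)
    return out
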