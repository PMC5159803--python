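"""End-to-end orchestration of the integrative analysis.

``run_pipeline`` executes normalization -> DE -> clustering -> target
prediction -> anti-correlation integration -> enrichment -> network on a
bundle directory and writes every result table plus a run log.  Each stage
is also exposed as a file-in / file-out function so that the CLI
subcommands compose to exactly the same outputs as a single ``run``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .clustering import assign_clusters, build_profiles, fuzzy_cmeans
from .de import call_de, fit_two_factor
from .enrichment import cluster_ora, hypergeom_heatmap, mirna_pathway_gsea
from .network import build_network, filter_targets, overlap_with_validated, spearman_edges
from .normalization import detection_filter, normalize_counts
from .targets import predict_targets

log = logging.getLogger(__name__)

STAGES = ("normalize", "de", "cluster", "predict", "integrate", "enrich", "network")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _read_table(path, index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna().unique()) <= {"True", "False"}:
            df[col] = df[col] == "True"
    return df


def _write_matrix(df: pd.DataFrame, path) -> None:
    df.rename_axis("feature_id").to_csv(path, sep="\t", float_format="%.6g")


def _paths(config: PipelineConfig) -> tuple[Path, Path]:
    ind, outd = Path(config.input_dir), Path(config.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    return ind, outd


# ------------------------------------------------------------------ stages ---

def stage_normalize(config: PipelineConfig) -> None:
    ind, outd = _paths(config)
    design = pio.read_design(ind / "design.tsv")
    factors = {}
    for kind, min_count in (("mrna", 0.0), ("mirna", config.mirna_min_count)):
        counts = pio.read_counts(ind / f"{kind}_counts.tsv", design)
        normalized, sf = normalize_counts(counts)
        normalized = detection_filter(normalized, min_count)
        factors[kind] = sf
        _write_matrix(normalized, outd / f"{kind}_normalized.tsv")
    sf_table = pd.concat(
        [factors[k].rename("size_factor").rename_axis("sample_id").reset_index().assign(matrix=k)
         for k in factors]
    )
    pio.write_table(sf_table, outd / "size_factors.tsv")


def stage_de(config: PipelineConfig) -> None:
    ind, outd = _paths(config)
    design = pio.read_design(ind / "design.tsv").polarized()
    for kind, fc in (("mrna", config.gene_fc), ("mirna", config.mirna_fc)):
        normalized = pio.read_counts(outd / f"{kind}_normalized.tsv", design=None)[design.sample_ids]
        log_expr = np.log2(normalized + 1.0)
        fit = fit_two_factor(log_expr, design)
        table = call_de(fit, normalized, design, fc_threshold=fc,
                        p_threshold=config.adj_p, pseudocount=config.pseudocount,
                        average_scale=config.fc_average_scale)
        name = "gene_de.tsv" if kind == "mrna" else "mirna_de.tsv"
        pio.write_table(table.rename_axis("feature_id"), outd / name, index=True)
        log.info("%s: %d/%d DE at fc>%g, adj_p<%g (prior df %.2f)",
                 name, int(table["de"].sum()), len(table), fc, config.adj_p, fit.prior_df_)


def stage_cluster(config: PipelineConfig) -> None:
    ind, outd = _paths(config)
    design = pio.read_design(ind / "design.tsv")
    normalized = pio.read_counts(outd / "mrna_normalized.tsv", design=None)
    gene_de = _read_table(outd / "gene_de.tsv", index_col=0)
    de_genes = list(gene_de.index[gene_de["de"]])
    profiles = build_profiles(normalized, design, de_genes, relative_to_m0=config.relative_to_m0)
    fc = fuzzy_cmeans(profiles, c=config.n_clusters, m=config.fuzzifier, seed=config.seed)
    assignments = assign_clusters(fc, profiles, threshold=config.membership)
    _write_matrix(profiles, outd / "profiles.tsv")
    memb = pd.DataFrame(fc.membership_, index=profiles.index,
                        columns=[f"cluster_{i}" for i in range(config.n_clusters)])
    _write_matrix(memb, outd / "memberships.tsv")
    centers = pd.DataFrame(fc.cluster_centers_, columns=profiles.columns)
    centers.insert(0, "cluster", range(config.n_clusters))
    pio.write_table(centers, outd / "cluster_centers.tsv")
    pio.write_table(assignments.rename_axis("gene_id"), outd / "cluster_assignments.tsv", index=True)
    log.info("clustering: %.1f%% of %d DE genes assigned at membership > %g",
             100 * assignments.attrs["assigned_fraction"], len(profiles), config.membership)


def stage_predict(config: PipelineConfig) -> None:
    ind, outd = _paths(config)
    mirna_seqs = pio.read_fasta(ind / "mirnas.fasta")
    utr_seqs = pio.read_fasta(ind / "utrs.fasta")
    table = predict_targets(mirna_seqs, utr_seqs)
    pio.write_table(table, outd / "predicted_targets.tsv")
    sites = pd.DataFrame([
        {"mirna_id": s.mirna_id, "gene_id": s.gene_id, "site_type": s.site_type,
         "utr_start": s.utr_start, "utr_end": s.utr_end, "matched": s.matched}
        for s in table.attrs["sites"]
    ], columns=["mirna_id", "gene_id", "site_type", "utr_start", "utr_end", "matched"])
    pio.write_table(sites, outd / "sites.tsv")


def stage_integrate(config: PipelineConfig) -> None:
    ind, outd = _paths(config)
    design = pio.read_design(ind / "design.tsv")
    if not config.include_m0_in_scc:
        design = design.polarized()
    mrna = pio.read_counts(outd / "mrna_normalized.tsv", design=None)[design.sample_ids]
    mirna = pio.read_counts(outd / "mirna_normalized.tsv", design=None)[design.sample_ids]
    targets = _read_table(outd / "predicted_targets.tsv")
    targets = targets[targets["mirna_id"].isin(mirna.index) & targets["gene_id"].isin(mrna.index)]
    edges = spearman_edges(mirna, mrna, targets)
    pio.write_table(edges, outd / "correlation_edges.tsv")
    refined = filter_targets(edges, targets, scc_filter=config.scc_filter, adj_p=config.adj_p)
    pio.write_table(refined, outd / "refined_targets.tsv")
    validated_path = ind / "validated_targets.tsv"
    if validated_path.exists():
        gene_de = _read_table(outd / "gene_de.tsv", index_col=0)
        overlap = overlap_with_validated(refined, pio.read_pair_list(validated_path), len(gene_de))
        pio.write_table(overlap, outd / "validated_overlap.tsv")
    log.info("integration: %d/%d pairs pass SCC<%g & adj_p<%g",
             len(refined), len(edges), config.scc_filter, config.adj_p)


def stage_enrich(config: PipelineConfig) -> None:
    ind, outd = _paths(config)
    pathways = pio.read_gmt(ind / "pathways.gmt")
    gene_de = _read_table(outd / "gene_de.tsv", index_col=0)
    mirna_de = _read_table(outd / "mirna_de.tsv", index_col=0)
    refined = _read_table(outd / "refined_targets.tsv")
    de_mirnas = list(mirna_de.index[mirna_de["de"]])
    tf_path = ind / "tf_list.tsv"
    tf_list = pio.read_id_list(tf_path) if tf_path.exists() else set()

    results, gsea_edges = mirna_pathway_gsea(
        refined, pathways, gene_de, de_mirnas=de_mirnas,
        weight_exponent=config.gsea_weight, n_perm=config.gsea_permutations,
        min_targets=config.gsea_min_targets, seed=config.seed, tf_list=tf_list)
    pio.write_table(results, outd / "gsea_results.tsv")
    pio.write_table(gsea_edges, outd / "gsea_edges.tsv")

    cells = hypergeom_heatmap(refined[refined["mirna_id"].isin(de_mirnas)], gene_de,
                              fc_threshold=config.gene_fc, p_threshold=config.adj_p)
    pio.write_table(cells, outd / "hypergeom_cells.tsv")

    assignments = _read_table(outd / "cluster_assignments.tsv", index_col=0)["assigned"]
    ora = cluster_ora(assignments, pathways, universe=gene_de.index,
                      refined_targets=refined, de_mirnas=de_mirnas)
    pio.write_table(ora, outd / "cluster_ora.tsv")


def stage_network(config: PipelineConfig) -> None:
    ind, outd = _paths(config)
    refined = _read_table(outd / "refined_targets.tsv")
    gene_de = _read_table(outd / "gene_de.tsv", index_col=0)
    mirna_de = _read_table(outd / "mirna_de.tsv", index_col=0)
    tf_path, c2h2_path = ind / "tf_list.tsv", ind / "c2h2_list.tsv"
    tf_list = pio.read_id_list(tf_path) if tf_path.exists() else set()
    c2h2_list = pio.read_id_list(c2h2_path) if c2h2_path.exists() else set()
    G = build_network(refined, network_scc=config.network_scc, de_genes=gene_de,
                      de_mirnas=mirna_de, tf_list=tf_list, c2h2_list=c2h2_list)
    pio.write_edge_list(G, outd / "network_edges.tsv")
    pio.write_table(G.graph["hub_report"], outd / "hubs.tsv")
    (outd / "network_summary.json").write_text(
        json.dumps(G.graph["summary"], indent=1, sort_keys=True))
    log.info("network: %d high-confidence edges at SCC<-%g", G.graph["n_edges"], config.network_scc)


_STAGE_FUNCS = {
    "normalize": stage_normalize,
    "de": stage_de,
    "cluster": stage_cluster,
    "predict": stage_predict,
    "integrate": stage_integrate,
    "enrich": stage_enrich,
    "network": stage_network,
}


def run_stage(name: str, config: PipelineConfig) -> None:
    try:
        _STAGE_FUNCS[name](config)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - surfaced with the stage name
        raise PipelineStageError(name, exc) from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory.

    Identical config + inputs reproduce identical outputs.  A failing stage
    raises :class:`PipelineStageError` naming the stage, and the run log
    records the thresholds actually used.
    """
    _, outd = _paths(config)
    handler = logging.FileHandler(outd / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("polarmir")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        from . import __version__
        log.info("polarmir %s", __version__)
        log.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))
        for stage in STAGES:
            log.info("running stage %s", stage)
            run_stage(stage, config)
        log.info("pipeline complete")
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
    return outd
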