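"""Configuration objects for the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic polarization time course.

    The defaults emulate the study design this package targets at desk
    scale: two polarization conditions (M1, M2) sampled at 1, 2, 4 and 8 h
    in duplicate, plus duplicate unstimulated (M0) controls at 1 h;
    negative-binomial counts; four planted differential-expression trend
    archetypes; condition-specific miRNAs split into early- and
    late-response classes; and planted miRNA->target repression realized
    both as canonical 3'UTR seed sites and as anti-correlated expression.

    Parameters
    ----------
    n_genes, n_mirnas : int
        Total simulated features per matrix.
    n_de_genes_per_archetype : int
        Planted differentially expressed genes in each of the four trend
        archetypes.
    n_m1_mirnas, n_m2_mirnas : int
        Planted condition-specific miRNAs (split evenly into early/late
        response classes within each condition).
    n_targets_per_mirna : int
        Exclusive planted targets per differential miRNA.
    n_shared_targets : int
        Genes planted as common targets of 2-3 miRNAs of the same
        condition class (the network hubs).
    timepoints : tuple of float
        Polarization sampling times in hours, strictly increasing.
    n_replicates : int
        Replicates per (condition, time) cell.
    nb_dispersion : float
        Negative-binomial dispersion phi; variance = mu + phi * mu**2.
    library_size_range : (float, float)
        Per-sample library scale factors are drawn uniformly in this range.
    logfc_magnitude : float
        Log2 amplitude of the planted condition trends (0 gives a global
        null).
    repression_slope : float
        Log2 units of target repression per log2 unit of regulator trend.
    utr_length : int
        Simulated 3'UTR length in nt.
    seed : int
        RNG seed; identical configs produce byte-identical bundles.
    """

    n_genes: int = 2500
    n_mirnas: int = 60
    n_de_genes_per_archetype: int = 150
    n_m1_mirnas: int = 8
    n_m2_mirnas: int = 6
    n_targets_per_mirna: int = 12
    n_shared_targets: int = 6
    timepoints: tuple = (1.0, 2.0, 4.0, 8.0)
    n_replicates: int = 2
    nb_dispersion: float = 0.05
    library_size_range: tuple = (0.7, 1.3)
    logfc_magnitude: float = 2.0
    repression_slope: float = 1.5
    utr_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_mirnas",
            "n_de_genes_per_archetype",
            "n_m1_mirnas",
            "n_m2_mirnas",
            "n_targets_per_mirna",
            "n_replicates",
            "utr_length",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        tp = tuple(float(t) for t in self.timepoints)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints = tp
        self.library_size_range = tuple(float(x) for x in self.library_size_range)
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.logfc_magnitude < 0:
            raise ValueError("logfc_magnitude must be >= 0")
        if self.repression_slope < 0:
            raise ValueError("repression_slope must be >= 0")


@dataclass
class PipelineConfig:
    """Thresholds, algorithm settings and file locations for a full run.

    All comparison thresholds are applied as strict inequalities: a gene
    with average fold change exactly 2, a pair with SCC exactly -0.5, a
    membership of exactly 0.5 or a maximum normalized count of exactly 10
    do not pass.
    """

    # DE calling
    gene_fc: float = 2.0
    mirna_fc: float = 1.5
    adj_p: float = 0.05
    mirna_min_count: float = 10.0
    pseudocount: float = 1.0
    fc_average_scale: str = "linear"  # or "log"
    # correlation filtering / network
    scc_filter: float = -0.5
    network_scc: float = 0.8
    include_m0_in_scc: bool = False
    # clustering
    n_clusters: int = 4
    fuzzifier: float = 2.0
    membership: float = 0.5
    relative_to_m0: bool = False
    # enrichment
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    gsea_min_targets: int = 10
    # misc
    seed: int = 0
    # file paths (a simulated bundle directory provides defaults)
    input_dir: str = ""
    output_dir: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.adj_p < 1:
            raise ValueError("adj_p must be in (0, 1)")
        if self.gene_fc <= 1 or self.mirna_fc <= 1:
            raise ValueError("fold-change thresholds must be > 1")
        if not -1 < self.scc_filter < 0:
            raise ValueError("scc_filter must be in (-1, 0)")
        if not 0 < self.network_scc < 1:
            raise ValueError("network_scc must be in (0, 1)")
        if not 0 < self.membership < 1:
            raise ValueError("membership must be in (0, 1)")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")
        if self.fc_average_scale not in ("linear", "log"):
            raise ValueError("fc_average_scale must be 'linear' or 'log'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML key-value config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
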