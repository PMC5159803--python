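"""Synthetic polarization time course with planted ground truth.

The generator emulates the study design every downstream stage expects: M1
and M2 conditions sampled at 1, 2, 4 and 8 h in duplicate plus duplicate M0
controls at 1 h; negative-binomial counts over a log-normal baseline with
per-sample library factors; four DE-gene trend archetypes (M1-high
decreasing, M1-high increasing, M2-high stable, M2-high increasing);
condition-specific miRNAs in early- and late-response classes; and planted
miRNA->target repression realized both as canonical seed sites in the
target's 3'UTR and as anti-correlated expression (the target's log2 mean is
shifted by ``-repression_slope`` times its regulator's log2 trend).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .design import SampleDesign
from .targets import seed_patterns, scan_utr, DEFAULT_TYPES

ARCHETYPES = (1, 2, 3, 4)
_PLANTABLE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_REJECTION_CAP = 200


@dataclass
class GroundTruth:
    """Planted structure of a simulated bundle."""

    de_genes_by_archetype: dict = field(default_factory=dict)  # archetype -> [gene ids]
    de_mirnas: dict = field(default_factory=dict)  # condition -> {"early": [...], "late": [...]}
    target_pairs: list = field(default_factory=list)  # (mirna_id, gene_id)
    strong_target_pairs: list = field(default_factory=list)  # doubled-slope subset
    pathways: dict = field(default_factory=dict)  # name -> [gene ids]
    gsea_pathway: str = ""
    gsea_mirna: str = ""
    tf_genes: list = field(default_factory=list)
    c2h2_genes: list = field(default_factory=list)
    validated_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for arch, genes in self.de_genes_by_archetype.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"archetype sets overlap at {sorted(overlap)[:5]}")
            seen |= set(genes)

    @property
    def all_de_mirnas(self) -> list:
        return [m for cond in sorted(self.de_mirnas)
                for cls in ("early", "late")
                for m in self.de_mirnas[cond].get(cls, [])]

    @property
    def all_archetype_genes(self) -> list:
        return [g for a in sorted(self.de_genes_by_archetype)
                for g in self.de_genes_by_archetype[a]]

    @property
    def target_genes(self) -> list:
        return sorted({g for _, g in self.target_pairs})

    @property
    def affected_genes(self) -> set:
        """Genes with a real planted condition effect (archetypes + targets)."""
        return set(self.all_archetype_genes) | set(self.target_genes)

    @property
    def multi_mirna_targets(self) -> set:
        counts: dict[str, int] = {}
        for _, g in self.target_pairs:
            counts[g] = counts.get(g, 0) + 1
        return {g for g, c in counts.items() if c >= 2}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        data["de_genes_by_archetype"] = {int(k): v for k, v in data["de_genes_by_archetype"].items()}
        data["target_pairs"] = [tuple(p) for p in data["target_pairs"]]
        data["strong_target_pairs"] = [tuple(p) for p in data["strong_target_pairs"]]
        data["validated_pairs"] = [tuple(p) for p in data["validated_pairs"]]
        return cls(**data)


def _trend_shapes(n_timepoints: int) -> dict[str, np.ndarray]:
    return {
        "decreasing": np.linspace(1.7, 0.3, n_timepoints),
        "increasing": np.linspace(0.3, 1.7, n_timepoints),
        "stable": np.ones(n_timepoints),
    }


# archetype -> (condition that is high, shape name); mirrors the four
# observed cluster trends: M1-high early/decreasing, M1-high late/increasing,
# M2-high stable, M2-high increasing.
_ARCHETYPE_TREND = {
    1: ("M1", "decreasing"),
    2: ("M1", "increasing"),
    3: ("M2", "stable"),
    4: ("M2", "increasing"),
}


def make_design(config: SimulationConfig) -> SampleDesign:
    """Sample design: M1/M2 x timepoints x replicates, plus M0 duplicates at
    the first time point."""
    rows = []
    for cond in ("M1", "M2"):
        for tp in config.timepoints:
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{cond}_{tp:g}h_r{rep}", cond, tp, rep))
    for rep in range(1, 3):
        rows.append((f"M0_{config.timepoints[0]:g}h_r{rep}", "M0", config.timepoints[0], rep))
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "condition", "time_h", "replicate"]))


def _plant_structure(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    gene_ids = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    mirna_ids = [f"mir-{i:03d}" for i in range(1, config.n_mirnas + 1)]
    n_arch = config.n_de_genes_per_archetype
    if 4 * n_arch > config.n_genes:
        raise ValueError("n_de_genes_per_archetype too large for n_genes")
    if config.n_m1_mirnas + config.n_m2_mirnas > config.n_mirnas:
        raise ValueError("condition-specific miRNAs exceed n_mirnas")

    perm = rng.permutation(config.n_genes)
    arch_genes = {a: sorted(gene_ids[j] for j in perm[(a - 1) * n_arch: a * n_arch])
                  for a in ARCHETYPES}

    m1 = mirna_ids[: config.n_m1_mirnas]
    m2 = mirna_ids[config.n_m1_mirnas: config.n_m1_mirnas + config.n_m2_mirnas]
    de_mirnas = {
        "M1": {"early": m1[: len(m1) // 2 + len(m1) % 2], "late": m1[len(m1) // 2 + len(m1) % 2:]},
        "M2": {"early": m2[: len(m2) // 2 + len(m2) % 2], "late": m2[len(m2) // 2 + len(m2) % 2:]},
    }
    all_de_mirnas = m1 + m2

    # Targets are drawn from the DE genes that are high in the opposite
    # condition: an M1-specific miRNA represses genes whose expression is
    # relatively M2-high, so target status is orthogonal to the four trend
    # families, as observed for real polarization targetomes.
    target_pairs, strong_pairs = [], []
    pools = {
        "M1": [g for a in (3, 4) for g in arch_genes[a]],
        "M2": [g for a in (1, 2) for g in arch_genes[a]],
    }
    n_shared = {"M1": config.n_shared_targets // 2 + config.n_shared_targets % 2,
                "M2": config.n_shared_targets // 2}
    for cond, mirnas in (("M1", m1), ("M2", m2)):
        pool = list(rng.permutation(pools[cond]))
        need = config.n_targets_per_mirna * len(mirnas) + n_shared[cond]
        if need > len(pool):
            raise ValueError(
                "n_targets_per_mirna too large: need "
                f"{need} opposite-condition DE genes for {cond} miRNAs, have {len(pool)}"
            )
        pos = 0
        for mirna in mirnas:
            own = pool[pos: pos + config.n_targets_per_mirna]
            pos += config.n_targets_per_mirna
            target_pairs += [(mirna, g) for g in own]
            strong_pairs += [(mirna, g) for g in own[: config.n_targets_per_mirna // 2]]
        for i in range(n_shared[cond]):
            gene = pool[pos]
            pos += 1
            k = min(3 + i % 3, len(mirnas))
            regulators = list(rng.choice(mirnas, size=k, replace=False))
            target_pairs += [(m, gene) for m in regulators]

    gsea_mirna = m1[0]
    gsea_genes = [g for m, g in strong_pairs if m == gsea_mirna]
    pathways = {f"PW_ARCH{a}": list(arch_genes[a]) for a in ARCHETYPES}
    pathways["PW_REPRESSED"] = sorted(gsea_genes)
    all_targets = sorted({g for _, g in target_pairs})
    for i in range(5):
        mix = list(rng.choice(all_targets, size=min(10, len(all_targets)), replace=False))
        filler = list(rng.choice(gene_ids, size=20, replace=False))
        pathways[f"PW_MIX{i + 1}"] = sorted(set(mix + filler))
    for i in range(10):
        pathways[f"PW_RANDOM{i + 1}"] = sorted(rng.choice(gene_ids, size=30, replace=False))

    tf_genes = sorted(rng.choice(all_targets, size=max(1, len(all_targets) // 3), replace=False))
    c2h2_genes = sorted(rng.choice(tf_genes, size=max(1, len(tf_genes) // 2), replace=False))
    validated = [p for i, p in enumerate(sorted(target_pairs)) if i % 2 == 0]

    return GroundTruth(
        de_genes_by_archetype=arch_genes,
        de_mirnas=de_mirnas,
        target_pairs=sorted(target_pairs),
        strong_target_pairs=sorted(strong_pairs),
        pathways=pathways,
        gsea_pathway="PW_REPRESSED",
        gsea_mirna=gsea_mirna,
        tf_genes=list(tf_genes),
        c2h2_genes=list(c2h2_genes),
        validated_pairs=validated,
    )


def _mirna_trends(config: SimulationConfig, truth: GroundTruth,
                  rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Per-miRNA log2 offset vectors by condition over the time points.

    Early-response miRNAs peak at the first time points and decay; late
    responders rise toward the last.  Each miRNA gets its own decay/rise
    endpoint and amplitude (drawn once, seeded), emulating heterogeneous
    kinetics within a response class.  Amplitudes are half the gene trend
    amplitude: miRNA induction during early polarization is more modest
    than the downstream transcriptional response, and the repression each
    miRNA exerts on its targets (``repression_slope`` times its trend)
    stays a perturbation of, rather than a replacement for, the target's
    own condition trend.
    """
    T = len(config.timepoints)
    zero = np.zeros(T)
    trends: dict[str, dict[str, np.ndarray]] = {}
    for cond in ("M1", "M2"):
        for cls in ("early", "late"):
            for mirna in truth.de_mirnas[cond][cls]:
                endpoint = rng.uniform(0.5, 0.9)
                amplitude = rng.uniform(0.85, 1.15) * 0.5 * config.logfc_magnitude
                shape = (np.linspace(1.4, endpoint, T) if cls == "early"
                         else np.linspace(endpoint, 1.4, T))
                trends[mirna] = {cond: amplitude * shape,
                                 ("M2" if cond == "M1" else "M1"): zero}
    return trends


def _gene_offsets(config: SimulationConfig, truth: GroundTruth,
                  trends: dict) -> dict[str, dict[str, np.ndarray]]:
    T = len(config.timepoints)
    shapes = _trend_shapes(T)
    zero = np.zeros(T)
    offsets: dict[str, dict[str, np.ndarray]] = {}
    for arch, genes in truth.de_genes_by_archetype.items():
        cond, shape_name = _ARCHETYPE_TREND[arch]
        offs = config.logfc_magnitude * shapes[shape_name]
        for g in genes:
            offsets[g] = {cond: offs.copy(), ("M2" if cond == "M1" else "M1"): zero.copy()}
    strong = set(truth.strong_target_pairs)
    for mirna, gene in truth.target_pairs:
        slope = config.repression_slope * (2.0 if (mirna, gene) in strong else 1.0)
        entry = offsets.setdefault(gene, {"M1": zero.copy(), "M2": zero.copy()})
        for cond in ("M1", "M2"):
            entry[cond] = entry[cond] - slope * trends[mirna][cond]
    return offsets


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _simulate_matrix(rng, feature_ids, baselines, offsets, design, config) -> pd.DataFrame:
    T = list(config.timepoints)
    lib = rng.uniform(*config.library_size_range, size=len(design))
    means = np.empty((len(feature_ids), len(design)))
    zero = np.zeros(len(T))
    for j, row in enumerate(design.table.itertuples(index=False)):
        if row.condition == "M0":
            log2_off = np.zeros(len(feature_ids))
        else:
            ti = T.index(row.time_h)
            log2_off = np.array([
                offsets.get(f, {}).get(row.condition, zero)[ti] for f in feature_ids
            ])
        means[:, j] = baselines * lib[j] * 2.0**log2_off
    counts = _nb_draw(rng, means, config.nb_dispersion)
    return pd.DataFrame(counts, index=feature_ids, columns=design.sample_ids, dtype=int)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SampleDesign, GroundTruth]:
    """Simulate paired mRNA / miRNA count matrices with planted structure.

    Returns ``(mrna_counts, mirna_counts, design, truth)``.  Counts are
    negative-binomial with mean = baseline x library factor x 2^trend;
    planted targets are additionally shifted by ``-repression_slope`` times
    their regulators' log2 trends; M0 controls carry baseline only.  The
    same config (including seed) reproduces bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    design = make_design(config)
    truth = _plant_structure(config, rng)
    trends = _mirna_trends(config, truth, rng)
    gene_offsets = _gene_offsets(config, truth, trends)

    gene_ids = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    mirna_ids = [f"mir-{i:03d}" for i in range(1, config.n_mirnas + 1)]
    gene_base = np.exp(rng.normal(np.log(150.0), 0.8, size=config.n_genes))
    mirna_base = np.exp(rng.normal(np.log(400.0), 0.8, size=config.n_mirnas))

    mrna = _simulate_matrix(rng, gene_ids, gene_base, gene_offsets, design, config)
    mirna = _simulate_matrix(rng, mirna_ids, mirna_base, trends, design, config)
    return mrna, mirna, design, truth


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def simulate_sequences(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, str], dict[str, str]]:
    """Random mature miRNA sequences and 3'UTRs with planted seed sites.

    Every miRNA is a random 22-nt RNA sequence with a unique seed.  Each
    true-target UTR contains one planted canonical site (8mer, 7mer-m8 or
    7mer-A1, chosen at random) per regulator and no other canonical site for
    any simulated miRNA; non-target UTRs contain no canonical site at all
    (rejection sampling with a retry cap).
    """
    rng = np.random.default_rng(config.seed + 1)
    n_genes = config.n_genes
    gene_ids = [f"GENE{i:05d}" for i in range(1, n_genes + 1)]
    mirna_ids = [f"mir-{i:03d}" for i in range(1, config.n_mirnas + 1)]

    mirna_seqs: dict[str, str] = {}
    seeds_seen = set()
    for mid in mirna_ids:
        for _ in range(_REJECTION_CAP):
            seq = _random_seq(rng, 22, "ACGU")
            if seq[1:8] not in seeds_seen:
                seeds_seen.add(seq[1:8])
                mirna_seqs[mid] = seq
                break
        else:
            raise RuntimeError("could not draw miRNAs with unique seeds; reduce n_mirnas")

    patterns = {mid: seed_patterns(seq) for mid, seq in mirna_seqs.items()}
    regulators: dict[str, list[str]] = {}
    for mirna, gene in truth.target_pairs:
        regulators.setdefault(gene, []).append(mirna)

    utr_seqs: dict[str, str] = {}
    for gene in gene_ids:
        regs = sorted(regulators.get(gene, []))
        min_len = 10 * len(regs) + 20
        if config.utr_length < min_len:
            raise ValueError(
                f"utr_length {config.utr_length} too short to plant {len(regs)} sites; "
                "increase utr_length"
            )
        for attempt in range(_REJECTION_CAP):
            utr = _random_seq(rng, config.utr_length)
            planted: list[tuple[str, str, int]] = []
            ok = True
            used: list[tuple[int, int]] = []
            for mirna in regs:
                stype = str(rng.choice(_PLANTABLE_TYPES))
                pat = patterns[mirna][stype]
                for _ in range(40):
                    off = int(rng.integers(0, config.utr_length - len(pat)))
                    if all(off + len(pat) <= a or off >= b for a, b in used):
                        break
                else:
                    ok = False
                    break
                utr = utr[:off] + pat + utr[off + len(pat):]
                used.append((off, off + len(pat)))
                planted.append((mirna, stype, off))
            if not ok:
                continue
            # accept iff the scanner finds exactly the planted regulators
            found_pairs = set()
            clean = True
            for mid in mirna_ids:
                hits = scan_utr(utr, patterns[mid], DEFAULT_TYPES, mirna_id=mid, gene_id=gene)
                if hits:
                    if mid not in regs:
                        clean = False
                        break
                    found_pairs.add(mid)
            if clean and found_pairs == set(regs):
                utr_seqs[gene] = utr
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed for {gene} after {_REJECTION_CAP} tries; "
                "try longer UTRs or fewer miRNAs"
            )
    return mirna_seqs, utr_seqs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(directory, config: SimulationConfig) -> dict:
    """Simulate and write a complete fixture bundle; returns the manifest.

    Writes the count TSVs, design TSV, miRNA/UTR FASTAs, pathway GMT,
    TF / C2H2 / validated-target lists, the ground-truth JSON and a manifest
    with sha256 checksums of every written file.  The same config writes a
    byte-identical bundle.
    """
    from . import io as pio  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mrna, mirna, design, truth = simulate_counts(config)
    mirna_seqs, utr_seqs = simulate_sequences(config, truth)

    files = {}

    def _write(name: str, writer) -> None:
        path = directory / name
        writer(path)
        files[name] = _sha256(path)

    _write("mrna_counts.tsv", lambda p: pio.write_counts(mrna, p))
    _write("mirna_counts.tsv", lambda p: pio.write_counts(mirna, p))
    _write("design.tsv", lambda p: design.table.to_csv(p, sep="\t", index=False))
    _write("mirnas.fasta", lambda p: pio.write_fasta(mirna_seqs, p))
    _write("utrs.fasta", lambda p: pio.write_fasta(utr_seqs, p))
    _write("pathways.gmt", lambda p: pio.write_gmt(truth.pathways, p))
    _write("tf_list.tsv", lambda p: pio.write_id_list(truth.tf_genes, p))
    _write("c2h2_list.tsv", lambda p: pio.write_id_list(truth.c2h2_genes, p))
    _write("validated_targets.tsv", lambda p: pio.write_pair_list(truth.validated_pairs, p))
    _write("ground_truth.json", lambda p: p.write_text(truth.to_json()))

    manifest = {"config": asdict(config), "files": files}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
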