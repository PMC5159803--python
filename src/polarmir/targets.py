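"""TargetScan-style canonical seed-site prediction in 3'UTR sequences.

A miRNA's seed is nucleotides 2-8 (1-based, from the 5' end).  Canonical
sites on the UTR sense strand (conventionally DNA alphabet) are

* ``7mer-m8``: reverse complement of miRNA positions 2-8;
* ``8mer``: the 7mer-m8 followed by an A (opposite miRNA position 1);
* ``7mer-A1``: reverse complement of positions 2-7 followed by an A;
* ``6mer``: reverse complement of positions 2-7 (off by default).

The scanner reports all exact occurrences; 7mer matches nested inside an
8mer occurrence are suppressed in favor of the 8mer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
DEFAULT_TYPES = ("8mer", "7mer-m8", "7mer-A1")
# ranking for "best site": lower is better
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}
_SITE_LEN = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


@dataclass(frozen=True)
class SeedSite:
    """One canonical site occurrence (0-based, half-open UTR coordinates)."""

    mirna_id: str
    gene_id: str
    site_type: str
    utr_start: int
    utr_end: int
    matched: str


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """UTR sense-strand patterns for each canonical site type.

    Accepts a mature miRNA sequence 5'->3' in RNA or DNA alphabet and
    returns DNA-alphabet patterns keyed by site type.
    """
    seq = mirna_seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(f"miRNA sequence must be at least 8 nt, got {len(seq)}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in miRNA sequence: {sorted(bad)}")
    rc_2_8 = str(Seq(seq[1:8]).reverse_complement())
    rc_2_7 = str(Seq(seq[1:7]).reverse_complement())
    return {
        "8mer": rc_2_8 + "A",
        "7mer-m8": rc_2_8,
        "7mer-A1": rc_2_7 + "A",
        "6mer": rc_2_7,
    }


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def scan_utr(
    utr_seq: str,
    patterns: dict[str, str],
    enabled_types=DEFAULT_TYPES,
    mirna_id: str = "",
    gene_id: str = "",
) -> list[SeedSite]:
    """All canonical site occurrences of one miRNA in one UTR.

    Occurrences may overlap; N never matches; 7mer matches that sit inside
    an 8mer occurrence (the 7mer-m8 sharing its start, the 7mer-A1 sharing
    its end) are reported once, as the 8mer.
    """
    if not utr_seq:
        raise ValueError("empty UTR sequence")
    utr = utr_seq.upper().replace("U", "T")
    bad = set(utr) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in UTR sequence: {sorted(bad)}")
    unknown = set(enabled_types) - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types: {sorted(unknown)}")
    eightmer_starts = set(_find_all(utr, patterns["8mer"])) if "8mer" in enabled_types else set()
    sites = []
    for stype in SITE_TYPES:
        if stype not in enabled_types:
            continue
        for pos in _find_all(utr, patterns[stype]):
            if stype == "7mer-m8" and pos in eightmer_starts:
                continue
            if stype == "7mer-A1" and (pos - 1) in eightmer_starts:
                continue
            end = pos + _SITE_LEN[stype]
            sites.append(SeedSite(mirna_id, gene_id, stype, pos, end, utr[pos:end]))
    sites.sort(key=lambda s: (s.utr_start, _SITE_RANK[s.site_type]))
    return sites


def predict_targets(
    mirna_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    enabled_types=DEFAULT_TYPES,
    gene_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Scan every (miRNA, UTR) pair and aggregate to unique target pairs.

    ``gene_map`` optionally maps UTR record ids to gene ids so that sites
    on UTR isoforms of the same gene are unioned at the gene level.
    Returns a DataFrame sorted by (mirna_id, gene_id) with the best site
    type (8mer > 7mer-m8 > 7mer-A1 > 6mer), the site count and the site
    list; the per-site records are in ``result.attrs['sites']``.
    """
    if not mirna_seqs or not utr_seqs:
        raise ValueError("miRNA and UTR sequence sets must be non-empty")
    patterns = {mid: seed_patterns(seq) for mid, seq in mirna_seqs.items()}
    all_sites: dict[tuple[str, str], list[SeedSite]] = {}
    for utr_id, utr in utr_seqs.items():
        gene = gene_map.get(utr_id, utr_id) if gene_map else utr_id
        for mid in mirna_seqs:
            found = scan_utr(utr, patterns[mid], enabled_types, mirna_id=mid, gene_id=gene)
            if found:
                all_sites.setdefault((mid, gene), []).extend(found)
    rows = []
    for (mid, gene) in sorted(all_sites):
        sites = all_sites[(mid, gene)]
        best = min(sites, key=lambda s: _SITE_RANK[s.site_type]).site_type
        rows.append({"mirna_id": mid, "gene_id": gene, "best_site_type": best,
                     "n_sites": len(sites)})
    table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "best_site_type", "n_sites"])
    table.attrs["sites"] = [s for key in sorted(all_sites) for s in all_sites[key]]
    return table
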