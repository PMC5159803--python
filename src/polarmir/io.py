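"""Readers and writers for all interchange formats.

All tables are TSV with headers.  Floating-point values are written with 6
significant digits except p-values, which use 4-digit scientific notation,
so that outputs are diff-able and reruns are byte-comparable.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import SampleDesign


# ---------------------------------------------------------------- counts ---

def read_counts(path, design: SampleDesign | None = None) -> pd.DataFrame:
    """Read a feature x sample count TSV (first column = feature id).

    Feature order follows the file; columns are reordered to the design
    order when a design is given.  Duplicate feature ids, non-numeric cells
    and design/header mismatches raise with the offending name.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate feature ids in {path}: {dup}")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(f"non-numeric cell in {path} at row {row!r}, column {col!r}") from None
        raise
    if (values.to_numpy() == values.to_numpy().astype(int)).all():
        values = values.astype(int)
    if design is not None:
        extra = [c for c in values.columns if c not in set(design.sample_ids)]
        missing = [s for s in design.sample_ids if s not in set(values.columns)]
        if extra or missing:
            raise ValueError(
                f"sample mismatch between {path} and design: "
                f"extra in file {extra}, missing from file {missing}"
            )
        values = values[design.sample_ids]
    return values


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_design(path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return SampleDesign(table)


# ------------------------------------------------------------- sequences ---

def read_fasta(path) -> dict[str, str]:
    """FASTA records as an id -> sequence dict (id = header up to whitespace)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------- gene sets ---

def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: set name, description, tab-separated members."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    for i, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {i} in {path}: fewer than 3 fields")
        sets[fields[0]] = set(filter(None, fields[2:]))
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = sorted(set(sets[name]))
            fh.write("\t".join([name, "synthetic"] + members) + "\n")


def read_id_list(path) -> set:
    with open(path) as fh:
        ids = {line.strip() for line in fh if line.strip()}
    if not ids:
        raise ValueError(f"empty id list: {path}")
    return ids


def write_id_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_pair_list(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df[["mirna_id", "gene_id"]].itertuples(index=False)]


def write_pair_list(pairs, path) -> None:
    pd.DataFrame(sorted(pairs), columns=["mirna_id", "gene_id"]).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- edge list ---

def write_edge_list(G, path) -> None:
    """Cytoscape-importable edge list: source, target, scc, adjusted_p, edge_sign."""
    rows = [
        (u if G.nodes[u]["bipartite"] == "mirna" else v,
         v if G.nodes[u]["bipartite"] == "mirna" else u,
         d["scc"], d["adj_pvalue"], "repression" if d["scc"] < 0 else "activation")
        for u, v, d in G.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "scc", "adjusted_p", "edge_sign"])
    df = df.sort_values(["source", "target"]).reset_index(drop=True)
    write_table(df, path)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty and len(df.columns) == 0:
        raise ValueError(f"empty edge list: {path}")
    return df


# ------------------------------------------------------------ formatting ---

def _format_value(x, is_p: bool) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return f"{x:.4e}" if is_p else f"{x:.6g}"
    return str(x)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """TSV writer with the package-wide float conventions.

    Floats use 6 significant digits; columns whose names contain
    ``pvalue``/``adjusted_p`` use 4-digit scientific notation.
    """
    out = df.copy()
    if index:
        out = out.reset_index()
    for col in out.columns:
        is_p = "pvalue" in str(col) or "adjusted_p" in str(col)
        if out[col].dtype.kind in "fb" or is_p:
            out[col] = out[col].map(lambda x, p=is_p: _format_value(x, p))
    out.to_csv(path, sep="\t", index=False)
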