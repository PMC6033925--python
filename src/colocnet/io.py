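"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices are genes/probes × samples TSV (first column = feature
id, header row = sample ids, missing values empty or "NA").  Annotation is a
two-column probe→gene TSV.  Networks are written both as edge-list TSV and
GraphML.  FISH signal tables are CSV with one row per fluorescent signal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .fish import NucleusRecord, Signal

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature × sample expression matrix from TSV."""
    m = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    m.index = m.index.astype(str)
    if m.index.duplicated().any():
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in expression matrix: {dups}")
    if m.columns.duplicated().any():
        dups = m.columns[m.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in expression matrix: {dups}")
    return m.astype(float)


def write_expression_tsv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", na_rep="NA")


def read_annotation_tsv(path: str | Path) -> dict[str, str]:
    """Read the probe_id → gene_symbol mapping (many probes to one gene)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if ann.shape[1] < 2:
        raise ValueError("annotation TSV needs two columns: probe_id, gene_symbol")
    probe_col, gene_col = ann.columns[:2]
    ann = ann.dropna(subset=[probe_col, gene_col])
    if ann[probe_col].duplicated().any():
        dups = ann.loc[ann[probe_col].duplicated(), probe_col].tolist()
        raise ValueError(f"probes annotated more than once: {dups}")
    return dict(zip(ann[probe_col], ann[gene_col]))


def write_annotation_tsv(ann: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(ann.items()), columns=["probe_id", "gene_symbol"]
    ).to_csv(path, sep="\t", index=False)


def network_to_frame(network: nx.Graph) -> pd.DataFrame:
    rows = [
        (a, b, data.get("weight", float("nan")))
        for a, b, data in sorted(
            network.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
        )
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "partial_correlation"])


def write_network_tsv(network: nx.Graph, path: str | Path) -> None:
    network_to_frame(network).to_csv(path, sep="\t", index=False)


def read_network_tsv(path: str | Path, nodes=None) -> nx.Graph:
    frame = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for _, row in frame.iterrows():
        g.add_edge(
            str(row["gene_a"]),
            str(row["gene_b"]),
            weight=float(row.get("partial_correlation", float("nan"))),
        )
    return g


def write_network_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, path)


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_clustering_tsv(assignment: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["gene", "cluster_id"]
    ).to_csv(path, sep="\t", index=False)


def read_signals_csv(path: str | Path) -> list[NucleusRecord]:
    """Read FISH signal coordinates: nucleus_id, gene, allele, x, y, z, unit."""
    frame = pd.read_csv(path)
    required = {"nucleus_id", "gene", "x", "y", "z"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"signals CSV missing columns: {sorted(missing)}")
    if "unit" not in frame.columns:
        frame["unit"] = "um"
    records = []
    for nucleus_id, group in frame.groupby("nucleus_id", sort=True):
        signals = [
            Signal(
                gene=str(row.gene),
                x=float(row.x),
                y=float(row.y),
                z=float(row.z),
                unit=str(row.unit),
            )
            for row in group.itertuples()
        ]
        records.append(NucleusRecord(nucleus_id=nucleus_id, signals=signals))
    return records


def write_signals_csv(nuclei: list[NucleusRecord], path: str | Path) -> None:
    rows = []
    for nuc in nuclei:
        for i, s in enumerate(nuc.signals):
            rows.append((nuc.nucleus_id, s.gene, i, s.x, s.y, s.z, s.unit))
    pd.DataFrame(
        rows, columns=["nucleus_id", "gene", "allele", "x", "y", "z", "unit"]
    ).to_csv(path, index=False)
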