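"""Readers and writers for the pipeline's plain-text formats.

Counts/design/lengths/GO maps travel as TSV, sequences as FASTA, networks as
SIF and GraphML (Cytoscape-compatible, with node-class attributes), run
metadata as JSON manifests.  Every reader validates its input and reports
the first offending line; every writer/reader pair round-trips exactly.
All coordinates in emitted files are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import ExpressionMatrix
from .network import ClusterSet
from .simulate import SampleDesign, TruthTable

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; the message carries the 1-based line number."""


def read_counts_tsv(
    path, lengths_path=None, unit: str = "count"
) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dup)[-1]) + 2
        raise FormatError(f"{path}:{line}: duplicated transcript id {dup!r}")
    neg = df.lt(0).any(axis=1)
    if neg.any():
        tid = df.index[neg][0]
        line = int(np.flatnonzero(df.index == tid)[0]) + 2
        raise FormatError(f"{path}:{line}: negative value for transcript {tid!r}")
    lengths = None
    if lengths_path is not None:
        lengths = read_lengths_tsv(lengths_path)
    return ExpressionMatrix(df, lengths, unit)


def write_counts_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript")


def read_lengths_tsv(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = df.columns[0]
    s = df[col]
    if (s <= 0).any():
        tid = s.index[s <= 0][0]
        line = int(np.flatnonzero(s.index == tid)[0]) + 2
        raise FormatError(f"{path}:{line}: non-positive length for {tid!r}")
    return s.rename("length")


def write_lengths_tsv(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="transcript")


def read_design_tsv(path) -> SampleDesign:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        return SampleDesign(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_design_tsv(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample")


def read_go_map_tsv(path) -> Dict[str, Set[str]]:
    """transcript_id <tab> GO:NNNNNNN, one pair per line."""
    path = Path(path)
    ann: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            tid, term = parts
            ann.setdefault(tid, set()).add(term)
    return ann


def write_go_map_tsv(ann: Dict[str, Set[str]], path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(ann):
            for term in sorted(ann[tid]):
                fh.write(f"{tid}\t{term}\n")


def read_fasta(path) -> List[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: Set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicated sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def write_truth(truth: TruthTable, tsv_path, json_path) -> None:
    truth.table.to_csv(tsv_path, sep="\t", index_label="transcript")
    with open(json_path, "w") as fh:
        json.dump({"go_enrichment": truth.go_enrichment}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(tsv_path, json_path=None) -> TruthTable:
    table = pd.read_csv(tsv_path, sep="\t", index_col=0)
    go: Dict[str, int] = {}
    if json_path is not None and Path(json_path).exists():
        with open(json_path) as fh:
            go = {k: int(v) for k, v in json.load(fh).get("go_enrichment", {}).items()}
    return TruthTable(table, go)


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_sif(graph: nx.Graph, path, interaction: str = "co") -> None:
    with open(path, "w") as fh:
        isolated = [n for n in sorted(graph.nodes) if graph.degree(n) == 0]
        for i, j in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{i}\t{interaction}\t{j}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_clusters_tsv(clusters: ClusterSet, path) -> None:
    rows = []
    for cid in sorted(clusters.clusters):
        for node in sorted(clusters.clusters[cid]):
            rows.append((node, cid))
    for node in sorted(clusters.unassigned):
        rows.append((node, -1))
    pd.DataFrame(rows, columns=["transcript", "cluster"]).to_csv(
        path, sep="\t", index=False
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, seed: Optional[int], thresholds: Dict, inputs: Sequence) -> None:
    """Deterministic JSON manifest: seed, thresholds and input hashes."""
    manifest = {
        "seed": seed,
        "thresholds": thresholds,
        "inputs": {str(Path(p).name): file_sha256(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
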