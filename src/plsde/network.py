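"""miRNA-target network construction from multi-method prediction lists.

Target predictions from several algorithms (e.g. microT, miRanda, mircode,
TargetScan output lists — consumed as input files, never recomputed) are
merged, and only (miRNA, gene) pairs supported by at least ``min_methods``
distinct methods are kept.  Targets are then restricted to genes that are
themselves differentially expressed, and the surviving pairs form a
bipartite regulatory network whose node degrees identify hubs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import DataError, ParameterError
from .io import read_tsv, write_tsv

DEFAULT_MIN_METHODS = 2


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Load a (mirna, gene, method) prediction table, validating uniqueness."""
    df = read_tsv(path, dtype=str)
    missing = {"mirna", "gene", "method"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: prediction table lacks columns {sorted(missing)}")
    df = df[["mirna", "gene", "method"]].apply(lambda s: s.str.strip())
    if df.duplicated().any():
        raise DataError(f"{path}: duplicate (mirna, gene, method) triples")
    return df


def filter_by_support(predictions: pd.DataFrame,
                      min_methods: int = DEFAULT_MIN_METHODS) -> pd.DataFrame:
    """Keep (mirna, gene) pairs predicted by >= ``min_methods`` distinct methods.

    Returns one row per kept pair with its ``support`` count and the sorted
    method list.  Monotone: raising ``min_methods`` never adds a pair.
    """
    if min_methods < 1:
        raise ParameterError("min_methods must be >= 1")
    grouped = (predictions.drop_duplicates()
               .groupby(["mirna", "gene"], sort=True)["method"]
               .agg(lambda m: sorted(set(m))))
    out = grouped.reset_index()
    out["support"] = out["method"].map(len)
    out["methods"] = out["method"].map(";".join)
    out = out[out["support"] >= min_methods]
    return out[["mirna", "gene", "support", "methods"]].reset_index(drop=True)


def filter_de_targets(targets: pd.DataFrame, de_genes: Iterable[str]) -> pd.DataFrame:
    """Restrict target pairs to differentially expressed genes.

    Matching is exact string after case normalization; no alias resolution.
    """
    de = {str(g).strip().casefold() for g in de_genes}
    if not de:
        import warnings
        warnings.warn("empty differential-expression gene set: no targets retained",
                      UserWarning, stacklevel=2)
        return targets.iloc[0:0].copy()
    keep = targets["gene"].str.strip().str.casefold().isin(de)
    return targets[keep].reset_index(drop=True)


def build_network(targets: pd.DataFrame, mirna_directions: Mapping[str, str],
                  gene_directions: Mapping[str, str],
                  gene_interactions: pd.DataFrame | None = None) -> nx.Graph:
    """Assemble the bipartite miRNA-gene graph with direction attributes.

    Every node carries ``kind`` ('mirna' or 'gene'), ``direction`` ('up' or
    'down' in the grade-IV-like class) and ``degree`` (count of incident
    regulatory edges).  Optional gene-gene interaction edges are admitted
    with ``relation='interacts'`` and excluded from the bipartite degree
    bookkeeping.
    """
    G = nx.Graph()
    for _, row in targets.iterrows():
        m, g = row["mirna"], row["gene"]
        for node, kind, directions in ((m, "mirna", mirna_directions),
                                       (g, "gene", gene_directions)):
            if node not in G:
                if node not in directions:
                    raise DataError(f"no regulation direction for {kind} node {node!r}")
                G.add_node(node, kind=kind, direction=directions[node])
        G.add_edge(m, g, relation="targets",
                   support=int(row["support"]) if "support" in row else None)
    for node in G.nodes:
        G.nodes[node]["degree"] = sum(
            1 for _, _, d in G.edges(node, data=True) if d["relation"] == "targets")
    if gene_interactions is not None:
        for _, row in gene_interactions.iterrows():
            a, b = row["gene_a"], row["gene_b"]
            if a in G and b in G:
                G.add_edge(a, b, relation="interacts", support=None)
    return G


def shared_targets(G: nx.Graph, mirna_a: str, mirna_b: str) -> set[str]:
    """Genes targeted by both miRNAs (regulatory edges only)."""
    def targets_of(m: str) -> set[str]:
        return {v for _, v, d in G.edges(m, data=True) if d["relation"] == "targets"}
    return targets_of(mirna_a) & targets_of(mirna_b)


def write_network(G: nx.Graph, outdir: str | Path, prefix: str = "network") -> dict[str, Path]:
    """Emit edge-list TSV, SIF, and a nodes table with direction and degree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        [{"source": u, "target": v, "relation": d["relation"],
          "support": d.get("support")} for u, v, d in sorted(G.edges(data=True))],
        columns=["source", "target", "relation", "support"])
    nodes = pd.DataFrame(
        [{"node": n, "kind": d["kind"], "direction": d["direction"],
          "degree": d["degree"]} for n, d in sorted(G.nodes(data=True))],
        columns=["node", "kind", "direction", "degree"])
    paths = {
        "edges": write_tsv(edges, outdir / f"{prefix}_edges.tsv"),
        "nodes": write_tsv(nodes, outdir / f"{prefix}_nodes.tsv"),
    }
    sif = outdir / f"{prefix}.sif"
    with open(sif, "w", encoding="utf-8") as fh:
        for u, v, d in sorted(G.edges(data=True)):
            fh.write(f"{u}\t{d['relation']}\t{v}\n")
    paths["sif"] = sif
    return paths
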