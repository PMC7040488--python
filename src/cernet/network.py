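"""ceRNA network (ceRNET) assembly, export and recovery scoring.

An mRNA and a lncRNA compete for a miRNA when both carry that miRNA's
recognition element and both are negatively co-expressed with it.  The
network is the union of kept miRNA-mRNA and miRNA-lncRNA edges; a
competing triplet exists wherever both edge types share a miRNA.  The
"shared MRE" is operationalized as consensus target evidence for the
same miRNA on both partners; site-coordinate identity across partners
is not required.  The development-annotation gate applies to mRNAs
only; lncRNAs are gated by DE status and target evidence upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .coexpr import CoexprPair
from .targets import TargetPair

logger = logging.getLogger(__name__)

NODE_TYPES = ("miRNA", "mRNA", "lncRNA")
EXPORT_FORMATS = ("SIF", "edge_table", "node_table", "GraphML")


@dataclass
class CeRNATriplet:
    mirna_id: str
    mrna_id: str
    lncrna_id: str
    mrna_edge: CoexprPair
    lncrna_edge: CoexprPair

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mirna_id, self.mrna_id, self.lncrna_id)


def build_cernet(
    mrna_pairs: list[CoexprPair],
    lncrna_pairs: list[CoexprPair],
    consensus_targets: list[TargetPair],
    dev_genes: set[str],
    comparison: str = "",
) -> tuple[nx.DiGraph, list[CeRNATriplet]]:
    """Assemble the typed graph and enumerate competing triplets.

    mRNA edges are kept when the mRNA is development-annotated and the
    (miRNA, mRNA) pair has consensus target evidence; lncRNA edges need
    target evidence only.  Edges lacking evidence are dropped with a
    warning rather than raising.  The graph keeps edges without a
    completing partner; triplets pair every kept mRNA edge with every
    kept lncRNA edge of the same miRNA.
    """
    evidence = {(p.mirna_id, p.transcript_id) for p in consensus_targets}

    def keep(pairs: list[CoexprPair], need_dev: bool) -> list[CoexprPair]:
        kept = []
        for pair in pairs:
            if need_dev and pair.target_id not in dev_genes:
                continue
            if (pair.mirna_id, pair.target_id) not in evidence:
                logger.warning(
                    "dropping %s-%s: no target evidence", pair.mirna_id, pair.target_id
                )
                continue
            kept.append(pair)
        return kept

    kept_mrna = keep(mrna_pairs, need_dev=True)
    kept_lnc = keep(lncrna_pairs, need_dev=False)

    graph = nx.DiGraph(comparison=comparison)
    for pair, edge_type, node_type in [
        *((p, "miRNA-mRNA", "mRNA") for p in kept_mrna),
        *((p, "miRNA-lncRNA", "lncRNA") for p in kept_lnc),
    ]:
        if pair.mirna_id == pair.target_id:
            continue  # no self-edges
        graph.add_node(pair.mirna_id, node_type="miRNA")
        graph.add_node(pair.target_id, node_type=node_type)
        graph.add_edge(
            pair.mirna_id, pair.target_id, edge_type=edge_type, r=pair.r, p=pair.p
        )

    by_mirna_mrna: dict[str, list[CoexprPair]] = {}
    for p in kept_mrna:
        by_mirna_mrna.setdefault(p.mirna_id, []).append(p)
    triplets = [
        CeRNATriplet(lp.mirna_id, gp.target_id, lp.target_id, gp, lp)
        for lp in kept_lnc
        for gp in by_mirna_mrna.get(lp.mirna_id, [])
    ]
    triplets.sort(key=lambda t: t.key)
    return graph, triplets


# ---------------------------------------------------------------------------
# Cytoscape-compatible export


def export_network(
    graph: nx.DiGraph, out_dir: str | Path, formats: tuple[str, ...] = EXPORT_FORMATS
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = [f for f in formats if f not in EXPORT_FORMATS]
    if unknown:
        raise ValueError(f"unknown export format(s): {unknown}")
    written: dict[str, Path] = {}
    if "SIF" in formats:
        path = out_dir / "network.sif"
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges):
                fh.write(f"{u}\tinteracts\t{v}\n")
        written["SIF"] = path
    if "edge_table" in formats:
        path = out_dir / "edges.tsv"
        rows = [
            {"source": u, "target": v, "edge_type": d["edge_type"], "r": d["r"], "p": d["p"]}
            for u, v, d in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "edge_type", "r", "p"]).to_csv(
            path, sep="\t", index=False
        )
        written["edge_table"] = path
    if "node_table" in formats:
        path = out_dir / "nodes.tsv"
        rows = [
            {"id": n, "node_type": d.get("node_type", "")}
            for n, d in sorted(graph.nodes(data=True))
        ]
        pd.DataFrame(rows, columns=["id", "node_type"]).to_csv(path, sep="\t", index=False)
        written["node_table"] = path
    if "GraphML" in formats:
        path = out_dir / "network.graphml"
        nx.write_graphml(graph, path)
        written["GraphML"] = path
    return written


def import_network(edge_table: str | Path, node_table: str | Path) -> nx.DiGraph:
    """Rebuild a graph from the exported edge + node tables."""
    graph = nx.DiGraph()
    nodes = pd.read_csv(node_table, sep="\t")
    for row in nodes.itertuples(index=False):
        graph.add_node(row.id, node_type=row.node_type)
    edges = pd.read_csv(edge_table, sep="\t")
    for row in edges.itertuples(index=False):
        graph.add_edge(row.source, row.target, edge_type=row.edge_type, r=row.r, p=row.p)
    return graph


def evaluate_recovery(
    predicted: list[CeRNATriplet] | list[tuple[str, str, str]],
    planted: list[tuple[str, str, str]],
) -> dict[str, float]:
    """Precision/recall/F1 of predicted triplets against the planted truth.

    Matching is exact (miRNA, mRNA, lncRNA) identity.  Empty prediction
    gives precision = recall = 0; F1 is 0 whenever undefined.
    """
    pred_keys = {t.key if isinstance(t, CeRNATriplet) else tuple(t) for t in predicted}
    true_keys = {tuple(t) for t in planted}
    tp = len(pred_keys & true_keys)
    precision = tp / len(pred_keys) if pred_keys else 0.0
    recall = tp / len(true_keys) if true_keys else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": float(tp)}
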