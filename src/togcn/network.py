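"""Concentration-ordered gene co-expression network (TO-GCN) construction.

Edges connect TF / non-TF gene pairs whose Pearson correlation across all
samples reaches a threshold (default 0.9, inclusive).  Bait genes — genes
peaking at 0 mM NaCl and declining along the gradient — seed a breadth-first
level assignment: baits are level 1, every other reachable node gets
1 + its unweighted shortest-path distance to the nearest bait.  Hub
statistics rank nodes by degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConstantProfileError, ParameterError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

PAIR_SCOPES = ("tf_vs_nontf", "tf_vs_all")
EXPORT_FORMATS = ("edgelist", "sif", "graphml")


@dataclass(frozen=True)
class BaitCriterion:
    """Monotone-decline tolerance, as a fraction of the profile range."""

    rel_tol: float = 0.1

    def __post_init__(self):
        if self.rel_tol < 0:
            raise ParameterError("rel_tol must be nonnegative")


def pcc(x, y) -> float:
    """Pearson product-moment correlation of two equal-length sample vectors."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ParameterError("vectors must be 1-D and of equal length")
    if xv.size < 3:
        raise ParameterError("need at least 3 samples")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ConstantProfileError("correlation undefined for a constant vector")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return max(-1.0, min(1.0, r))


def build_edges(
    matrix: ExpressionMatrix,
    tf_ids: set[str],
    pcc_min: float = 0.9,
    pair_scope: str = "tf_vs_nontf",
) -> nx.Graph:
    """Build the co-expression graph at an inclusive PCC cutoff.

    Correlations are computed on per-sample TPM values across all samples.
    ``tf_vs_nontf`` pairs every TF with every non-TF gene; ``tf_vs_all``
    additionally includes TF–TF pairs.  Constant-profile genes cannot carry
    a defined correlation and are skipped with a log message.
    """
    if pair_scope not in PAIR_SCOPES:
        raise ParameterError(f"pair_scope must be one of {PAIR_SCOPES}")
    tfs = [g for g in matrix.gene_ids if g in tf_ids]
    if not tfs:
        raise ParameterError("no TF ids present in the matrix")

    values = matrix.values
    sd = values.std(axis=1, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        log.warning(
            "skipping %d constant-profile gene(s): correlation undefined", len(constant)
        )
    usable = values.drop(index=constant)
    tfs = [g for g in tfs if g in usable.index]

    if pair_scope == "tf_vs_nontf":
        partners = [g for g in usable.index if g not in tf_ids]
    else:
        partners = list(usable.index)

    graph = nx.Graph()
    for g in usable.index:
        graph.add_node(g, is_tf=g in tf_ids)

    if tfs and partners:
        # row-standardise once; corr = standardized dot product / n
        arr = usable.to_numpy(dtype=float)
        arr = arr - arr.mean(axis=1, keepdims=True)
        arr = arr / np.sqrt((arr ** 2).sum(axis=1, keepdims=True))
        idx = {g: i for i, g in enumerate(usable.index)}
        tf_rows = arr[[idx[g] for g in tfs]]
        partner_rows = arr[[idx[g] for g in partners]]
        corr = tf_rows @ partner_rows.T
        np.clip(corr, -1.0, 1.0, out=corr)
        ti, pi = np.nonzero(corr >= pcc_min)
        for a, b in zip(ti, pi):
            u, v = tfs[a], partners[b]
            if u == v:
                continue
            graph.add_edge(u, v, weight=float(corr[a, b]))
    return graph


def select_bait_genes(means: pd.DataFrame, criterion: BaitCriterion = BaitCriterion()) -> set[str]:
    """Genes whose mean profile peaks at T0 and declines along the gradient.

    Selected iff the T0 mean is the strict maximum, every successive step
    decreases or rises by at most tau = rel_tol * (max - min), and the final
    mean is below the T0 mean by more than tau.
    """
    selected = set()
    for gene in means.index:
        p = means.loc[gene].to_numpy(dtype=float)
        rng = p.max() - p.min()
        if rng == 0:
            continue
        tau = criterion.rel_tol * rng
        if p[0] <= p[1:].max():
            continue
        if (np.diff(p) > tau).any():
            continue
        if not p[-1] < p[0] - tau:
            continue
        selected.add(gene)
    return selected


def assign_levels_bfs(graph: nx.Graph, baits: set[str]) -> list[str]:
    """Multi-source BFS level assignment from the bait set.

    Baits get level 1; each reachable node gets 1 + shortest-path distance
    to the nearest bait (stored as node attribute ``level``).  Unreachable
    nodes are left unassigned and returned.
    """
    if not baits:
        raise ParameterError("bait set is empty")
    missing = baits - set(graph.nodes)
    if missing:
        raise ParameterError(f"bait(s) not in network: {sorted(missing)}")
    dist = nx.multi_source_dijkstra_path_length(graph, baits, weight=None)
    unassigned = []
    for node in graph.nodes:
        if node in dist:
            graph.nodes[node]["level"] = int(dist[node]) + 1
        else:
            graph.nodes[node].pop("level", None)
            unassigned.append(node)
    if unassigned:
        log.info("%d node(s) unreachable from baits, left unassigned", len(unassigned))
    return unassigned


def hub_statistics(graph: nx.Graph, focus_ids: set[str] | None = None) -> pd.DataFrame:
    """Degree table (gene, degree, level) sorted by degree desc, then gene id."""
    nodes = graph.nodes if focus_ids is None else [n for n in graph.nodes if n in focus_ids]
    rows = [
        {
            "gene_id": n,
            "degree": graph.degree(n),
            "level": graph.nodes[n].get("level", pd.NA),
        }
        for n in nodes
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "degree", "level"])
    return df.sort_values(
        ["degree", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "edgelist") -> None:
    """Write the network as edge-list TSV, SIF or GraphML.

    The edge-list format carries a companion node-attribute table at
    ``<path>.nodes.tsv`` so levels and TF flags round-trip.
    """
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("gene1\tgene2\tpcc\n")
            for u, v, d in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.17g}\n")
        with open(path.with_suffix(path.suffix + ".nodes.tsv"), "w") as fh:
            fh.write("gene_id\tis_tf\tlevel\n")
            for n in sorted(graph.nodes):
                lvl = graph.nodes[n].get("level", "")
                fh.write(f"{n}\t{int(graph.nodes[n].get('is_tf', False))}\t{lvl}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\tco\t{v}\n")
    elif fmt == "graphml":
        g = graph.copy()
        for n in g.nodes:  # GraphML needs uniform attribute types
            g.nodes[n]["is_tf"] = bool(g.nodes[n].get("is_tf", False))
        nx.write_graphml(g, path)
    else:
        raise ParameterError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")


def read_network(path: str | Path, fmt: str = "edgelist") -> nx.Graph:
    """Read a network written by :func:`export_network` (edgelist or graphml)."""
    path = Path(path)
    if fmt == "edgelist":
        graph = nx.Graph()
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        ndf = pd.read_csv(nodes_path, sep="\t", dtype={"gene_id": str})
        for _, row in ndf.iterrows():
            attrs = {"is_tf": bool(row["is_tf"])}
            if pd.notna(row["level"]):
                attrs["level"] = int(row["level"])
            graph.add_node(row["gene_id"], **attrs)
        edf = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
        for _, row in edf.iterrows():
            graph.add_edge(row["gene1"], row["gene2"], weight=float(row["pcc"]))
        return graph
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ParameterError(f"cannot read format {fmt!r}")
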