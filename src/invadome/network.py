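"""Confidence-weighted interaction networks and Markov clustering.

Edges carry a confidence in [0, 1] (STRING exports on the 0-1000 integer
scale are auto-rescaled) and are binned into the conventional tiers:
medium (>= 0.4), high (>= 0.7), highest (>= 0.9).  After filtering to the
minimum confidence, proteins left without any interaction are removed.

The Markov Cluster Algorithm (MCL) is implemented from scratch on the
column-stochastic transition matrix of the weighted graph: alternate
expansion (matrix squaring — random-walk flow spreading) and inflation
(elementwise power followed by column renormalization — flow sharpening)
with pruning of negligible entries, until the matrix stops changing.
Clusters are read off the limit matrix as attractor systems; every node is
assigned to exactly one cluster (overlap resolved to the attractor
receiving the most flow, ties to the lexicographically smallest seed).
Self-loops are added with weight equal to each node's maximum incident
confidence, the standard regularization that damps parity oscillations.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


class EdgeListError(ValueError):
    """Malformed interaction edge list."""


def confidence_tier(confidence: float) -> str:
    """STRING-style tier name for an edge confidence."""
    if confidence >= 0.9:
        return "highest"
    if confidence >= 0.7:
        return "high"
    if confidence >= 0.4:
        return "medium"
    return "low"


def read_edges(path: str | Path) -> nx.Graph:
    """Read a STRING-style TSV edge list into an undirected weighted graph.

    Columns: nodeA, nodeB, score.  Scores above 1 are interpreted as the
    0-1000 integer scale and divided by 1000; scores outside both scales
    are an error.  Duplicate edges keep the maximum confidence; self-loops
    are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise EdgeListError("edge list needs three columns: nodeA, nodeB, score")
    # tolerate a header row
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:]
    g = nx.Graph()
    for a, b, raw in df.iloc[:, :3].itertuples(index=False):
        score = float(raw)
        if score < 0 or score > 1000:
            raise EdgeListError(f"score {score} outside both [0,1] and [0,1000] scales")
        conf = score / 1000.0 if score > 1 else score
        if a == b:
            warnings.warn(f"self-loop on {a!r} dropped")
            continue
        if g.has_edge(a, b):
            conf = max(conf, g.edges[a, b]["confidence"])
        g.add_edge(a, b, confidence=conf, tier=confidence_tier(conf))
    return g


def filter_graph(g: nx.Graph, min_confidence: float = 0.4) -> nx.Graph:
    """Drop edges below the confidence floor, then disconnected nodes."""
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    for a, b, data in g.edges(data=True):
        if data["confidence"] >= min_confidence:
            out.add_edge(a, b, **data)
    out.remove_nodes_from([n for n, d in dict(out.degree()).items() if d == 0])
    return out


def _transition_matrix(g: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Column-stochastic matrix from confidences, with max-incident self-loops."""
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in g.edges(data=True):
        i, j = index[a], index[b]
        m[i, j] = m[j, i] = data["confidence"]
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    return m / m.sum(axis=0, keepdims=True)


def _inflate(m: np.ndarray, inflation: float, prune: float) -> np.ndarray:
    m = np.power(m, inflation)
    m[m < prune] = 0.0
    colsum = m.sum(axis=0, keepdims=True)
    dead = colsum == 0
    if dead.any():  # a fully pruned column: park the walker on the diagonal
        idx = np.where(dead[0])[0]
        m[idx, idx] = 1.0
        colsum = m.sum(axis=0, keepdims=True)
    return m / colsum


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    prune: float = 1e-5,
    tol: float = 1e-8,
) -> tuple[pd.Series, pd.DataFrame]:
    """Markov clustering of a confidence-weighted graph.

    Returns per-node cluster labels (``c1``, ``c2``, ... ordered by
    cluster seed) and an edge table flagging intra- vs inter-cluster
    edges.  On non-convergence within ``max_iter`` a warning is issued and
    clusters are read from the current state.
    """
    nodes = sorted(g.nodes())
    if not nodes:
        return pd.Series(dtype=object), pd.DataFrame(
            columns=["nodeA", "nodeB", "confidence", "tier", "intra_cluster"]
        )
    m = _transition_matrix(g, nodes)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = _inflate(prev @ prev, inflation, prune)
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    # attractors: nodes with positive flow onto themselves in the limit
    attractors = np.where(np.diag(m) > tol)[0]
    # attractor systems: attractors linked by mutual flow form one cluster core
    core = nx.Graph()
    core.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > tol or m[j, i] > tol):
                core.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(core)]
    systems.sort(key=lambda s: nodes[s[0]])
    attractor_system = {}
    for sys_id, members in enumerate(systems):
        for i in members:
            attractor_system[i] = sys_id

    labels: dict[str, int] = {}
    for j, node in enumerate(nodes):
        # flow mass from column j into each attractor system
        mass: dict[int, float] = {}
        for i in attractors:
            if m[i, j] > 0:
                sid = attractor_system[i]
                mass[sid] = mass.get(sid, 0.0) + m[i, j]
        if mass:
            best = max(mass.items(), key=lambda kv: (kv[1], -kv[0]))
            labels[node] = best[0]
        else:  # isolated numerical orphan: own cluster
            systems.append([j])
            labels[node] = len(systems) - 1

    # relabel clusters deterministically by smallest member node
    cluster_members: dict[int, list[str]] = {}
    for node, sid in labels.items():
        cluster_members.setdefault(sid, []).append(node)
    order = sorted(cluster_members, key=lambda sid: min(cluster_members[sid]))
    rename = {sid: f"c{k + 1}" for k, sid in enumerate(order)}
    assignment = pd.Series(
        {node: rename[sid] for node, sid in labels.items()}, name="cluster"
    ).sort_index()

    edge_rows = []
    for a, b, data in sorted(g.edges(data=True)):
        edge_rows.append(
            (
                a,
                b,
                data["confidence"],
                data.get("tier", confidence_tier(data["confidence"])),
                assignment[a] == assignment[b],
            )
        )
    edges = pd.DataFrame(
        edge_rows, columns=["nodeA", "nodeB", "confidence", "tier", "intra_cluster"]
    )
    return assignment, edges
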