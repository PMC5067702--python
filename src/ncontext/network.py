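"""Target-driven interaction networks and over-representation analysis.

Networks are undirected :class:`networkx.Graph` objects whose edges carry a
``type`` (``interaction`` for database edges, ``association`` for ncRNA →
target links drawn as dotted lines in network figures) and, for interaction
edges, a ``confidence`` in [0, 1].  Node identity is the upper-cased gene
symbol — database exports mix symbol casing across species.

Connectivity (components, shortest paths) is computed over interaction edges
only; association edges represent a different relation and are exempt from
both the confidence filter and connectivity, though this is configurable.

Pathway annotation is a generic hypergeometric over-representation test
against user-supplied gene sets (GMT), with BH correction across sets.
"""

from __future__ import annotations

import warnings
from collections import deque
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .context import TargetAssociation
from .diffexpr import bh_adjust

__all__ = [
    "read_edge_table",
    "read_gmt",
    "filter_confidence",
    "induce_target_network",
    "components_and_paths",
    "shortest_path",
    "overrepresentation",
    "write_edge_list",
]


def read_edge_table(path: str | Path) -> nx.Graph:
    """Read a STRING-style edge table (protein1, protein2, combined_score).

    Scores on the 0–999 integer scale are divided by 1000; files whose scores
    never exceed 1 are taken as already being confidences.  Duplicate pairs
    collapse to a single edge keeping the maximum confidence (warned);
    self-loops are dropped with a warning.
    """
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        sep = "\t" if "\t" in header else None
        cols = header.split(sep)
        try:
            i1, i2, isc = (
                cols.index("protein1"),
                cols.index("protein2"),
                cols.index("combined_score"),
            )
        except ValueError as exc:
            raise ValueError(
                f"{path}:1: header must contain protein1, protein2, "
                "combined_score"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) < max(i1, i2, isc) + 1:
                raise ValueError(f"{path}:{lineno}: too few columns")
            try:
                score = float(fields[isc])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric combined_score "
                    f"{fields[isc]!r}"
                ) from exc
            raw.append((fields[i1].upper(), fields[i2].upper(), score))

    max_score = max((s for _, _, s in raw), default=0.0)
    scale = 1000.0 if max_score > 1 else 1.0

    net = nx.Graph()
    n_dup = n_self = 0
    for u, v, s in raw:
        conf = s / scale
        if u == v:
            n_self += 1
            continue
        if net.has_edge(u, v):
            n_dup += 1
            conf = max(conf, net[u][v]["confidence"])
        net.add_edge(u, v, confidence=conf, type="interaction")
    if n_dup:
        warnings.warn(f"{path}: {n_dup} duplicate pair(s), max confidence kept")
    if n_self:
        warnings.warn(f"{path}: {n_self} self-loop(s) dropped")
    return net


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    "at least one member"
                )
            sets[fields[0]] = {g.upper() for g in fields[2:] if g}
    return sets


def filter_confidence(net: nx.Graph, min_conf: float) -> nx.Graph:
    """Keep interaction edges with confidence >= min_conf (inclusive).

    Association edges are exempt from the filter; isolated nodes survive.
    Idempotent for a fixed threshold.
    """
    if not 0 <= min_conf <= 1:
        raise ValueError("min_conf must lie in [0, 1]")
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    for u, v, data in net.edges(data=True):
        if data.get("type") == "association" or data["confidence"] >= min_conf:
            out.add_edge(u, v, **data)
    return out


def induce_target_network(
    net: nx.Graph,
    targets: Iterable[str],
    assoc: Sequence[TargetAssociation] = (),
) -> nx.Graph:
    """Subgraph on the target genes plus their ncRNAs as association edges.

    Target nodes absent from the edge table still appear (degree 0 or linked
    only by association edges), mirroring networks where pseudogenes are
    superimposed despite not being database-annotated.
    """
    tset = {t.upper() for t in targets}
    out = nx.Graph()
    out.add_nodes_from(sorted(tset))
    for u, v, data in net.edges(data=True):
        if u in tset and v in tset:
            out.add_edge(u, v, **data)
    for a in assoc:
        nc, tg = a.ncrna_id.upper(), a.target_id.upper()
        if nc == tg:
            continue
        out.add_node(nc)
        out.add_node(tg)
        if not out.has_edge(nc, tg):
            out.add_edge(nc, tg, type="association", relation=a.relation)
    return out


def _interaction_subgraph(net: nx.Graph, include_association: bool) -> nx.Graph:
    sub = nx.Graph()
    sub.add_nodes_from(net.nodes)
    for u, v, data in net.edges(data=True):
        if include_association or data.get("type", "interaction") == "interaction":
            sub.add_edge(u, v)
    return sub


def components_and_paths(
    net: nx.Graph,
    endpoints: tuple[str, str] | None = None,
    include_association: bool = False,
) -> tuple[list[list[str]], list[str] | None]:
    """Connected components (interaction edges only) and an optional path.

    Components are sorted lists, largest first (ties by first node).  When
    ``endpoints`` is given, the fewest-edge path between them is returned
    with lexicographic tie-breaking; ``None`` when the endpoints are in
    different components (not an error).  Unknown endpoints raise KeyError.
    """
    sub = _interaction_subgraph(net, include_association)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: (-len(c), c))
    path = None
    if endpoints is not None:
        path = shortest_path(net, *endpoints, include_association=include_association)
    return comps, path


def shortest_path(
    net: nx.Graph,
    source: str,
    target: str,
    include_association: bool = False,
) -> list[str] | None:
    """Fewest-edge path, deterministic lexicographic tie-break; None if none."""
    sub = _interaction_subgraph(net, include_association)
    for node in (source, target):
        if node not in sub:
            raise KeyError(f"endpoint {node!r} not in network")
    # BFS expanding neighbours in sorted order makes the predecessor chain,
    # and hence the reported path, lexicographically smallest among shortest
    pred: dict[str, str | None] = {source: None}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if u == target:
            break
        for v in sorted(sub.neighbors(u)):
            if v not in pred:
                pred[v] = u
                queue.append(v)
    if target not in pred:
        return None
    path = [target]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])  # type: ignore[arg-type]
    return path[::-1]


def overrepresentation(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against named gene sets.

    For each set, p = P(X >= overlap) under sampling |query| genes without
    replacement from the background; BH across sets.  Rows sorted by (q, p,
    set name).  Sets are intersected with the background; the query must be a
    subset of it.
    """
    bg = {g.upper() for g in background}
    if not bg:
        raise ValueError("background gene set is empty")
    q = {g.upper() for g in query}
    stray = q - bg
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    names = sorted(gene_sets)
    rows = []
    for name in names:
        members = {g.upper() for g in gene_sets[name]} & bg
        k = len(members & q)
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(members), len(q)))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": len(q),
                "background_size": len(bg),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "query_size", "background_size", "p"],
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["q", "p", "set"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write the network as a sorted edge-list TSV."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\ttype\tconfidence\n")
        for u, v, data in sorted(
            net.edges(data=True), key=lambda e: (e[0], e[1])
        ):
            conf = data.get("confidence")
            fh.write(
                f"{u}\t{v}\t{data.get('type', 'interaction')}\t"
                f"{'' if conf is None else f'{conf:.3f}'}\n"
            )
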