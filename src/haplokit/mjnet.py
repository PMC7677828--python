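"""Median-joining networks over haplotype bit-vectors.

Builds the minimum-spanning network under Hamming distance (with an
epsilon relaxation), iteratively inserts sitewise-majority median (Steiner)
vectors for connected triplets, prunes obsolete medians, and annotates
nodes with case/control composition.  GraphML and DOT export.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["MjConfig", "build_mj_network", "annotate_nodes", "write_graphml", "write_dot"]


@dataclass
class MjConfig:
    epsilon: int = 0
    max_iterations: int = 50
    exhaustive_triplets: bool = False

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _hamming(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return sum(x != y for x, y in zip(a, b))


def _differing_sites(a: tuple[int, ...], b: tuple[int, ...], site_ids) -> list[str]:
    return [site_ids[i] for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _spanning_network(nodes: list[tuple[int, ...]], epsilon: int) -> nx.Graph:
    """All links of cost <= (max MST edge cost) + epsilon.

    This is the epsilon-relaxed minimum-spanning network: the smallest
    distance threshold that connects all nodes, widened by epsilon.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if len(nodes) == 1:
        return g
    complete = nx.Graph()
    for a, b in itertools.combinations(nodes, 2):
        complete.add_edge(a, b, weight=_hamming(a, b))
    mst = nx.minimum_spanning_tree(complete, algorithm="kruskal")
    threshold = max(d["weight"] for _, _, d in mst.edges(data=True)) + epsilon
    for a, b, d in complete.edges(data=True):
        if d["weight"] <= threshold:
            g.add_edge(a, b, weight=d["weight"])
    return g


def _median(a, b, c) -> tuple[int, ...]:
    """Sitewise majority of three vectors; ties resolve to reference (0)."""
    out = []
    for x, y, z in zip(a, b, c):
        s = x + y + z
        out.append(1 if s >= 2 else 0)
    return tuple(out)


def build_mj_network(
    haplotypes: dict[str, tuple],
    counts: dict[str, tuple[int, int]] | None = None,
    config: MjConfig | None = None,
) -> nx.Graph:
    """Median-joining network from labeled haplotype bit-vectors.

    ``haplotypes`` maps label -> 0/1 vector; ``counts`` maps label ->
    (case_count, control_count).  Median nodes are inserted with zero
    observed frequency and labeled ``MV<n>``; medians not lying on any
    shortest path between observed nodes are deleted.  Node iteration is
    canonicalized by sorting on the bit-vector, so the result is independent
    of input ordering.
    """
    config = config or MjConfig()
    vectors = {lab: tuple(int(x) for x in vec) for lab, vec in haplotypes.items()}
    if len(vectors) < 2:
        raise ValueError("need at least 2 distinct haplotypes")
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError("haplotype vectors have unequal lengths")
    if len(set(vectors.values())) != len(vectors):
        raise ValueError("duplicate haplotype vectors")

    observed = sorted(vectors.values())
    label_of = {v: lab for lab, v in vectors.items()}

    nodes = list(observed)
    for _ in range(config.max_iterations):
        net = _spanning_network(sorted(nodes), config.epsilon)
        new_medians = set()
        if config.exhaustive_triplets:
            triplets = itertools.combinations(sorted(nodes), 3)
        else:
            triplets = _connected_triplets(net)
        for a, b, c in triplets:
            m = _median(a, b, c)
            if m not in net:
                new_medians.add(m)
        if not new_medians:
            break
        nodes.extend(sorted(new_medians))

    net = _spanning_network(sorted(nodes), config.epsilon)
    net = _prune_medians(net, observed)

    site_ids = [f"site{i + 1}" for i in range(len(observed[0]))]
    out = nx.Graph()
    mv = 0
    names = {}
    for v in sorted(net.nodes):
        if v in label_of:
            names[v] = label_of[v]
            is_median = False
        else:
            mv += 1
            names[v] = f"MV{mv}"
            is_median = True
        case = control = 0
        if counts is not None and not is_median:
            case, control = counts.get(label_of[v], (0, 0))
        out.add_node(
            names[v],
            vector="".join(map(str, v)),
            is_median=is_median,
            case_count=case,
            control_count=control,
            total=case + control,
        )
    for a, b, d in net.edges(data=True):
        diff = _differing_sites(a, b, site_ids)
        out.add_edge(names[a], names[b], sites=",".join(diff), weight=d["weight"])
    return out


def _connected_triplets(net: nx.Graph):
    """Triplets forming a path or triangle in the current network."""
    seen = set()
    for v in sorted(net.nodes):
        nbrs = sorted(net.neighbors(v))
        for a, b in itertools.combinations(nbrs, 2):
            key = tuple(sorted((v, a, b)))
            if key not in seen:
                seen.add(key)
                yield key


def _prune_medians(net: nx.Graph, observed: list) -> nx.Graph:
    """Drop median nodes absent from every shortest path between observed
    nodes (weighted by Hamming edge costs)."""
    keep = set(observed)
    obs = [v for v in observed if v in net]
    for a, b in itertools.combinations(obs, 2):
        try:
            for path in nx.all_shortest_paths(net, a, b, weight="weight"):
                keep.update(path)
        except nx.NetworkXNoPath:  # pragma: no cover - MSN is connected
            continue
    pruned = net.subgraph(keep).copy()
    # removing medians can disconnect relaxed edges; re-span if needed
    if not nx.is_connected(pruned):
        return _spanning_network(sorted(keep), 0)
    return pruned


def annotate_nodes(
    graph: nx.Graph, counts: dict[str, tuple[int, int]]
) -> nx.Graph:
    """Attach case/control composition and display size to each node."""
    total_case = sum(c for c, _ in counts.values())
    total_all = sum(c + h for c, h in counts.values())
    for node, data in graph.nodes(data=True):
        case, control = counts.get(node, (0, 0))
        if case < 0 or control < 0:
            raise ValueError("counts must be non-negative")
        data["case_count"] = case
        data["control_count"] = control
        data["total"] = case + control
        data["case_fraction"] = (
            case / (case + control) if case + control > 0 else float("nan")
        )
        data["size"] = (case + control) / total_all if total_all else 0.0
    graph.graph["cohort_case_fraction"] = (
        total_case / total_all if total_all else float("nan")
    )
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    g = graph.copy()
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, float) and np.isnan(v):
                data[k] = -1.0
    nx.write_graphml(g, path)


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export (no pydot dependency)."""
    lines = ["graph mj {"]
    for node, data in sorted(graph.nodes(data=True)):
        shape = "point" if data.get("is_median") else "circle"
        label = f'{node}\\n{data.get("total", 0)}'
        lines.append(f'  "{node}" [shape={shape}, label="{label}"];')
    for a, b, data in sorted(graph.edges(data=True)):
        lines.append(f'  "{a}" -- "{b}" [label="{data.get("sites", "")}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
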