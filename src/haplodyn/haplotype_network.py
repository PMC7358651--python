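"""Statistical-parsimony haplotype networks.

Builds the 95%-connection-limit network among coded haplotypes: pairs are
joined in increasing mutational distance while the probability that the
observed differences reflect exactly that many substitutions (no hidden or
superimposed changes) stays at or above the confidence level.  Paths longer
than one step are filled with inferred, unsampled intermediate haplotypes;
equally parsimonious alternative connections are all retained, so the graph
may contain loops.  A minimum-spanning network (all tied MST edges, no
inferred intermediates) is available as an alternative view.

The connection probability is derived under a finite-sites Jukes-Cantor
model: for two haplotypes differing at ``j`` of ``L`` sites, with the
per-site expected substitution count ``t`` estimated by Jukes-Cantor
inversion of ``j/L``, the parsimony probability is the conditional
probability that every differing site was hit exactly once and every
identical site was hit zero times, given the observed pattern:

    P_j = (t e^{-t} / p_diff)^j * (e^{-t} / (1 - p_diff))^(L-j)

with ``p_diff = (3/4)(1 - e^{-4t/3})``.  P_0 = 1 and P_j is
non-increasing in j; the computed probabilities are exposed on the model
for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .structure_stats import DistanceMatrix

__all__ = [
    "NetworkModel",
    "parsimony_probability",
    "connection_limit",
    "build_network",
    "minimum_spanning_network",
    "export_network",
    "import_network",
    "write_edge_list",
]


def parsimony_probability(j: int, L: int) -> float:
    """Probability that j observed differences over L sites are parsimonious."""
    if L < 1:
        raise ValueError("need L >= 1")
    if j < 0:
        raise ValueError("j must be non-negative")
    if j == 0:
        return 1.0
    p = j / L
    if p >= 0.75:
        return 0.0
    t = -0.75 * np.log1p(-4.0 * p / 3.0)  # Jukes-Cantor expected hits per site
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    log_p = j * (np.log(t) - t - np.log(p_diff)) + (L - j) * (
        -t - np.log1p(-p_diff)
    )
    return float(np.exp(log_p))


def connection_limit(L: int, alpha: float = 0.95) -> tuple[int, dict[int, float]]:
    """Largest step count j_max with parsimony probability >= alpha.

    Returns ``(j_max, probabilities)`` where probabilities cover
    ``j = 0 .. j_max + 1`` so the first sub-threshold value is visible.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    probs: dict[int, float] = {0: 1.0}
    j = 0
    while True:
        nxt = parsimony_probability(j + 1, L)
        probs[j + 1] = nxt
        if nxt < alpha:
            break
        j += 1
        if j > L:
            break
    return j, probs


@dataclass
class NetworkModel:
    """A haplotype network: observed nodes, inferred intermediates, edges."""

    graph: nx.Graph
    j_max: int | None
    probabilities: dict[int, float] = field(default_factory=dict)
    method: str = "statistical_parsimony"

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("inferred")]

    @property
    def inferred(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("inferred")]

    def total_count(self) -> int:
        return sum(
            d.get("count", 0) for _, d in self.graph.nodes(data=True)
        )


def _node_attrs(label, counts, breakdown):
    return {
        "count": int(counts.get(label, 0)) if counts else 0,
        "inferred": False,
        "populations": json.dumps(breakdown.get(label, {}) if breakdown else {}),
    }


def build_network(
    dist: DistanceMatrix,
    counts: dict[str, int] | None = None,
    population_breakdown: dict[str, dict[str, int]] | None = None,
    j_max: int | None = None,
    L: int | None = None,
    alpha: float = 0.95,
) -> NetworkModel:
    """Statistical-parsimony network over observed haplotypes.

    Haplotype pairs are processed in increasing mutational distance up to
    ``j_max`` (computed from ``L`` and ``alpha`` when not given).  A pair
    whose endpoints lie in different components at the start of its
    distance level is connected by a path inserting ``distance - 1``
    inferred intermediates; all pairs at the same level that span the same
    components are connected (equally parsimonious ties, producing loops).
    Observed pairs farther than ``j_max`` stay in separate components
    unless linked through other connections.
    """
    if not dist.labels:
        raise ValueError("empty haplotype set")
    probs: dict[int, float] = {}
    if j_max is None:
        if L is None:
            raise ValueError("either j_max or L must be given")
        j_max, probs = connection_limit(L, alpha)
    graph = nx.Graph()
    for label in dist.labels:
        graph.add_node(label, **_node_attrs(label, counts, population_breakdown))

    pairs: dict[int, list[tuple[str, str]]] = {}
    n = len(dist.labels)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(round(dist.matrix[i, j]))
            if 1 <= d <= j_max:
                pairs.setdefault(d, []).append((dist.labels[i], dist.labels[j]))

    intermediate_counter = 0
    for level in sorted(pairs):
        components = list(nx.connected_components(graph))
        comp_of = {node: ci for ci, comp in enumerate(components) for node in comp}
        for a, b in pairs[level]:
            if comp_of[a] == comp_of[b]:
                continue
            prev = a
            for _ in range(level - 1):
                intermediate_counter += 1
                mid = f"i{intermediate_counter}"
                graph.add_node(
                    mid, count=0, inferred=True, populations=json.dumps({})
                )
                graph.add_edge(prev, mid, steps=1)
                prev = mid
            graph.add_edge(prev, b, steps=1)
    return NetworkModel(graph, j_max, probs, "statistical_parsimony")


def minimum_spanning_network(
    dist: DistanceMatrix,
    counts: dict[str, int] | None = None,
    population_breakdown: dict[str, dict[str, int]] | None = None,
) -> NetworkModel:
    """All tied minimum-spanning edges; no inferred intermediates.

    Kruskal by distance level: every pair at the current level whose
    endpoints lie in different components (at the start of the level) is
    connected directly, keeping all equally short alternatives.
    """
    if not dist.labels:
        raise ValueError("empty haplotype set")
    graph = nx.Graph()
    for label in dist.labels:
        graph.add_node(label, **_node_attrs(label, counts, population_breakdown))
    n = len(dist.labels)
    levels: dict[int, list[tuple[str, str]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = int(round(dist.matrix[i, j]))
            if d >= 1:
                levels.setdefault(d, []).append((dist.labels[i], dist.labels[j]))
    for level in sorted(levels):
        if nx.is_connected(graph):
            break
        comp_of = {
            node: ci
            for ci, comp in enumerate(nx.connected_components(graph))
            for node in comp
        }
        for a, b in levels[level]:
            if comp_of[a] != comp_of[b]:
                graph.add_edge(a, b, steps=level)
    return NetworkModel(graph, None, {}, "minimum_spanning")


def export_network(model: NetworkModel, path: str | Path) -> None:
    """Write GraphML (.graphml/.xml) or DOT (.dot/.gv)."""
    path = Path(path)
    if path.suffix in {".graphml", ".xml"}:
        graph = model.graph.copy()
        graph.graph["method"] = model.method
        graph.graph["j_max"] = -1 if model.j_max is None else model.j_max
        graph.graph["probabilities"] = json.dumps(model.probabilities)
        nx.write_graphml(graph, path)
    elif path.suffix in {".dot", ".gv"}:
        with open(path, "w") as fh:
            fh.write("graph haplotypes {\n")
            for node, data in model.graph.nodes(data=True):
                shape = "circle" if not data.get("inferred") else "point"
                fh.write(
                    f'  "{node}" [label="{node} ({data.get("count", 0)})", '
                    f"shape={shape}];\n"
                )
            for a, b, data in model.graph.edges(data=True):
                fh.write(f'  "{a}" -- "{b}" [label="{data.get("steps", 1)}"];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unsupported network format: {path.suffix}")


def import_network(path: str | Path) -> NetworkModel:
    """Read a GraphML network written by :func:`export_network`."""
    path = Path(path)
    graph = nx.read_graphml(path)
    graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    j_max = graph.graph.get("j_max", -1)
    probs_raw = json.loads(graph.graph.get("probabilities", "{}"))
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        out.add_node(
            node,
            count=int(data.get("count", 0)),
            inferred=bool(data.get("inferred", False)),
            populations=data.get("populations", "{}"),
        )
    for a, b, data in graph.edges(data=True):
        out.add_edge(a, b, steps=int(data.get("steps", 1)))
    return NetworkModel(
        out,
        None if j_max in (-1, None) else int(j_max),
        {int(k): float(v) for k, v in probs_raw.items()},
        graph.graph.get("method", "statistical_parsimony"),
    )


def write_edge_list(model: NetworkModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("from\tto\tsteps\n")
        for a, b, data in model.graph.edges(data=True):
            fh.write(f"{a}\t{b}\t{data.get('steps', 1)}\n")
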