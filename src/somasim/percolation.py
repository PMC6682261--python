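"""Markov blankets as directed graphs: transparency, opacity, percolation.

A protective layer of somatic cells around a reproductive cell can be
abstracted as a Markov blanket: a directed graph whose input nodes face
the environment, whose output nodes face the protected cell, and whose
edges carry prediction-violating information (variational free energy)
inward. An edge is either present or absent — conditional dependencies
below threshold transmit nothing, so the weighted matrix can be
binarized without loss.

The blanket is *transparent* when a directed path connects some input to
some output (the environment can reach the cell) and *opaque* when no
such path exists (full protection, effective exposure beta = 0). A
strict variant of transparency — every input reaches some output —
corresponds to full exposure, beta = 1. As edges are added at random the
blanket undergoes a percolation transition from opacity to transparency;
the more long-range shortcuts the topology allows, the lower the edge
density at which this happens, and hence the more links must be severed
to regain opacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BlanketGraph",
    "PercolationCurve",
    "is_transparent",
    "path_count",
    "min_links_to_opacity",
    "random_blanket",
    "percolation_curve",
    "threshold_estimate",
    "binarize_weights",
    "read_blanket",
    "write_blanket",
]

_SOURCE = "__source__"
_SINK = "__sink__"


@dataclass
class BlanketGraph:
    """Directed binary graph with disjoint input and output node sets."""

    graph: nx.DiGraph
    inputs: frozenset = field(default_factory=frozenset)
    outputs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.inputs = frozenset(self.inputs)
        self.outputs = frozenset(self.outputs)
        if self.inputs & self.outputs:
            raise ValueError("input and output node sets must be disjoint")
        missing = (self.inputs | self.outputs) - set(self.graph.nodes)
        if missing:
            raise ValueError(f"role nodes absent from graph: {sorted(missing)}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        inputs: Iterable,
        outputs: Iterable,
        nodes: Iterable | None = None,
    ) -> "BlanketGraph":
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_nodes_from(inputs)
        g.add_nodes_from(outputs)
        g.add_edges_from(edges)
        return cls(g, frozenset(inputs), frozenset(outputs))

    def _validated(self) -> None:
        if not self.inputs or not self.outputs:
            raise ValueError("blanket must declare at least one input and one output node")


def binarize_weights(matrix: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Threshold a weighted dependency matrix to a binary adjacency matrix.

    Transmission through the blanket is effective only above a coupling
    threshold, so weights are reduced to present/absent at ``cutoff``.
    """
    m = np.asarray(matrix, dtype=float)
    return (m >= cutoff).astype(np.int8)


def is_transparent(g: BlanketGraph, strict: bool = False) -> bool:
    """Whether environmental information can traverse the blanket.

    Default (existential) reading: transparent iff a directed path exists
    from at least one input node to at least one output node; opacity —
    no input-to-output path at all — is what full protection requires.
    With ``strict=True`` every input must reach some output (full
    exposure, beta = 1).
    """
    g._validated()
    reach_any = []
    for src in g.inputs:
        reached = nx.descendants(g.graph, src) | {src}
        hits = bool(reached & g.outputs)
        if hits and not strict:
            return True
        reach_any.append(hits)
    return all(reach_any) if strict else False


def path_count(g: BlanketGraph, cap: int = 1_000_000) -> int:
    """Number of distinct simple directed input-to-output paths, capped.

    Exact for small graphs; enumeration stops at ``cap`` paths so the
    call stays bounded on dense graphs.
    """
    g._validated()
    total = 0
    for src in g.inputs:
        for dst in g.outputs:
            remaining = cap - total
            if remaining <= 0:
                return cap
            total += sum(
                1 for _ in islice(nx.all_simple_paths(g.graph, src, dst), remaining)
            )
    return total


def min_links_to_opacity(g: BlanketGraph) -> int:
    """Minimal number of edge removals that sever every input-to-output path.

    Computed as the minimum edge cut between a virtual super-source
    (feeding all inputs) and super-sink (fed by all outputs), with unit
    capacity on real edges and infinite capacity on the virtual ones.
    Zero iff the blanket is already opaque.
    """
    g._validated()
    if not is_transparent(g):
        return 0
    h = nx.DiGraph()
    for u, v in g.graph.edges:
        h.add_edge(u, v, capacity=1)
    h.add_nodes_from(g.graph.nodes)
    for src in g.inputs:
        h.add_edge(_SOURCE, src, capacity=float("inf"))
    for dst in g.outputs:
        h.add_edge(dst, _SINK, capacity=float("inf"))
    value = nx.maximum_flow_value(h, _SOURCE, _SINK)
    return int(value)


def random_blanket(
    n_inputs: int,
    n_outputs: int,
    n_intermediate: int,
    edge_prob: float,
    topology: str = "layered",
    seed: int | np.random.Generator | None = None,
) -> BlanketGraph:
    """Sample a random blanket graph of the requested topology.

    Topologies
    ----------
    ``one-to-one``
        Bipartite with no intermediates: input ``i`` may link only to
        output ``i`` (each such edge present with ``edge_prob``). This is
        the specialist blanket — one dedicated protector per threat.
    ``layered``
        Edges only between adjacent layers: inputs -> intermediates and
        intermediates -> outputs, each candidate edge present with
        ``edge_prob``.
    ``long-range``
        The layered candidate set plus direct input -> output shortcuts,
        all with ``edge_prob``; the extra shortcuts model long-range
        (small-world) connectivity.
    """
    if min(n_inputs, n_outputs) < 1:
        raise ValueError("need at least one input and one output node")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must lie in [0, 1], got {edge_prob!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    inputs = [f"in{i}" for i in range(n_inputs)]
    outputs = [f"out{i}" for i in range(n_outputs)]
    mids = [f"mid{i}" for i in range(n_intermediate)]

    candidates: list[tuple[str, str]] = []
    if topology == "one-to-one":
        candidates = [
            (inputs[i], outputs[i]) for i in range(min(n_inputs, n_outputs))
        ]
        nodes = inputs + outputs
    elif topology == "layered":
        candidates = [(i, m) for i in inputs for m in mids] + [
            (m, o) for m in mids for o in outputs
        ]
        nodes = inputs + mids + outputs
    elif topology == "long-range":
        candidates = (
            [(i, m) for i in inputs for m in mids]
            + [(m, o) for m in mids for o in outputs]
            + [(i, o) for i in inputs for o in outputs]
        )
        nodes = inputs + mids + outputs
    else:
        raise ValueError(
            "topology must be 'one-to-one', 'layered' or 'long-range', "
            f"got {topology!r}"
        )

    keep = rng.uniform(size=len(candidates)) < edge_prob
    edges = [e for e, k in zip(candidates, keep) if k]
    return BlanketGraph.from_edges(edges, inputs, outputs, nodes=nodes)


@dataclass
class PercolationCurve:
    """Monte-Carlo transparency fraction as a function of edge probability."""

    edge_probs: np.ndarray
    fractions: np.ndarray
    replicates: int
    seed: int | None = None
    topology: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_prob": self.edge_probs,
                "transparent_fraction": self.fractions,
                "replicates": self.replicates,
            }
        )


def percolation_curve(
    n_inputs: int,
    n_outputs: int,
    n_intermediate: int,
    topology: str,
    edge_probs: Sequence[float],
    replicates: int = 200,
    seed: int | None = None,
    strict: bool = False,
) -> PercolationCurve:
    """Estimate the transparency fraction across an edge-probability grid."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    probs = np.asarray(edge_probs, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fractions = np.empty(len(probs))
    for idx, p in enumerate(probs):
        hits = 0
        for _ in range(replicates):
            g = random_blanket(
                n_inputs, n_outputs, n_intermediate, float(p), topology, seed=rng
            )
            hits += is_transparent(g, strict=strict)
        fractions[idx] = hits / replicates
    return PercolationCurve(probs, fractions, replicates, seed, topology)


def threshold_estimate(curve: PercolationCurve, level: float = 0.5) -> float | None:
    """Edge probability at which the transparency fraction crosses ``level``.

    Linear interpolation between the bracketing grid points of the first
    upward crossing; ``None`` if the curve never crosses (not bracketed).
    """
    p, f = curve.edge_probs, curve.fractions
    for i in range(len(p) - 1):
        lo, hi = f[i], f[i + 1]
        if lo < level <= hi:
            if hi == lo:
                return float(p[i + 1])
            return float(p[i] + (level - lo) * (p[i + 1] - p[i]) / (hi - lo))
    if len(f) and f[0] >= level:
        return float(p[0])
    return None


def write_blanket(g: BlanketGraph, edge_path, roles_path) -> None:
    """Write a blanket as a tab-separated edge list plus a JSON role sidecar.

    A ``.graphml`` extension on ``edge_path`` switches to GraphML output;
    node roles always go to the JSON sidecar ``{"inputs": [...],
    "outputs": [...], "nodes": [...]}`` so isolated nodes survive the
    round trip.
    """
    import json
    from pathlib import Path

    edge_path = Path(edge_path)
    if edge_path.suffix == ".graphml":
        nx.write_graphml(g.graph, edge_path)
    else:
        with open(edge_path, "w") as fh:
            for u, v in g.graph.edges:
                fh.write(f"{u}\t{v}\n")
    roles = {
        "inputs": sorted(g.inputs),
        "outputs": sorted(g.outputs),
        "nodes": sorted(g.graph.nodes),
    }
    Path(roles_path).write_text(json.dumps(roles, indent=1))


def read_blanket(edge_path, roles_path) -> BlanketGraph:
    """Read a blanket written by :func:`write_blanket`."""
    import json
    from pathlib import Path

    edge_path = Path(edge_path)
    roles = json.loads(Path(roles_path).read_text())
    if edge_path.suffix == ".graphml":
        graph = nx.DiGraph(nx.read_graphml(edge_path))
    else:
        graph = nx.DiGraph()
        for line in edge_path.read_text().splitlines():
            line = line.strip()
            if line:
                u, v = line.split("\t")
                graph.add_edge(u, v)
    graph.add_nodes_from(roles.get("nodes", []))
    return BlanketGraph(graph, frozenset(roles["inputs"]), frozenset(roles["outputs"]))
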