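"""Causal diagram over community features and backdoor adjustment sets.

The diagram is a DAG relating the community features to downstream
stability through two intermediate stability metrics: richness drives the
interaction totals and degrees; within-patch totals drive resistance to
invasion in their patch; trans totals, rho and mu drive both structural
persistence and downstream resistance to invasion; the two metrics compose
stability.  Degrees and mean strengths have no outgoing edges into the
stability metrics.  Resistance to invasion upstream is an unobserved
(latent) node, and the intermediate metrics are not available as adjustment
covariates either.

Adjustment sets satisfy the backdoor criterion: a set of observed
non-descendants of the exposure that d-separates exposure and outcome in
the graph with the exposure's outgoing edges removed.  The search returns
the smallest valid set (lexicographic tie-break), found by subset
enumeration in increasing size — the graph is small enough that this doubles
as its own certificate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx

__all__ = ["CausalDiagram", "default_diagram", "adjustment_set", "is_valid_adjustment_set"]


@dataclass
class CausalDiagram:
    """A DAG plus the set of nodes unavailable for adjustment."""

    graph: nx.DiGraph
    latent: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("causal diagram must be acyclic")
        self.latent = frozenset(self.latent)

    @property
    def observed(self) -> set:
        return set(self.graph.nodes) - self.latent

    @classmethod
    def from_edge_list(cls, text: str) -> "CausalDiagram":
        """Parse a plain-text encoding: ``a -> b`` per line, ``latent: x``
        lines mark unobserved nodes, ``#`` starts a comment."""
        g = nx.DiGraph()
        latent = set()
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("latent:"):
                latent.add(line.split(":", 1)[1].strip())
            elif "->" in line:
                a, b = (s.strip() for s in line.split("->", 1))
                g.add_edge(a, b)
            else:
                raise ValueError(f"unparseable diagram line: {line!r}")
        unknown = latent - set(g.nodes)
        if unknown:
            raise ValueError(f"latent nodes not in graph: {sorted(unknown)}")
        return cls(graph=g, latent=frozenset(latent))


def default_diagram() -> CausalDiagram:
    """The diagram shipped with the package (see ``data/causal_diagram.txt``)."""
    text = resources.files("chainstab").joinpath("data/causal_diagram.txt").read_text()
    return CausalDiagram.from_edge_list(text)


def is_valid_adjustment_set(
    diagram: CausalDiagram, exposure: str, outcome: str, zset
) -> bool:
    """Backdoor criterion check for a candidate set."""
    g = diagram.graph
    zset = set(zset)
    if exposure in zset or outcome in zset:
        return False
    desc = nx.descendants(g, exposure)
    if zset & desc:
        return False
    backdoor = g.copy()
    backdoor.remove_edges_from(list(g.out_edges(exposure)))
    return nx.is_d_separator(backdoor, {exposure}, {outcome}, zset)


def adjustment_set(diagram: CausalDiagram, exposure: str, outcome: str) -> set:
    """Smallest valid backdoor adjustment set (lexicographic tie-break).

    Raises ``ValueError`` if exposure or outcome is not a node or they
    coincide, and ``RuntimeError`` if no observed set is valid.
    """
    g = diagram.graph
    for node in (exposure, outcome):
        if node not in g:
            raise ValueError(f"{node!r} is not a node of the diagram")
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    candidates = sorted(
        diagram.observed - {exposure, outcome} - nx.descendants(g, exposure)
    )
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            if is_valid_adjustment_set(diagram, exposure, outcome, combo):
                return set(combo)
    raise RuntimeError(
        f"no valid observed adjustment set for {exposure!r} -> {outcome!r}"
    )
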