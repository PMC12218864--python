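"""Back-door covariate selection on a causal DAG with latent nodes.

The study's causal assumptions are encoded as a directed acyclic graph in
which some nodes (here, human use of the landscape) are declared latent:
they may never enter an adjustment set. Covariates for the habitat-use models
are chosen to satisfy the back-door criterion for the *total* effect of the
exposure — adjustment sets must block every back-door path while leaving all
directed exposure→outcome paths (including those through the native plant
community) unblocked.

The bundled graph file ``data/habitat_use.dag`` is an editable edge list, so
the assumed arrows can be revised without touching code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "CausalDAG",
    "load_dag",
    "bundled_habitat_dag",
    "d_separated",
    "is_valid_backdoor",
    "total_effect_sets",
]


@dataclass
class CausalDAG:
    """A DAG with an observability flag per node.

    ``graph`` is a :class:`networkx.DiGraph`; ``latent`` nodes can never be
    conditioned on. ``exposure`` and ``outcome`` are optional designations
    carried along from the graph file.
    """

    graph: nx.DiGraph
    latent: frozenset[str] = frozenset()
    exposure: str | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"graph is cyclic: {cycle}")
        unknown = self.latent - set(self.graph.nodes)
        if unknown:
            raise ValueError(f"latent declaration names unknown nodes: {sorted(unknown)}")
        if self.exposure is not None and self.exposure == self.outcome:
            raise ValueError("exposure and outcome must differ")

    @property
    def observed(self) -> frozenset[str]:
        return frozenset(self.graph.nodes) - self.latent

    def _check_nodes(self, nodes: Iterable[str]) -> None:
        unknown = set(nodes) - set(self.graph.nodes)
        if unknown:
            raise KeyError(f"unknown node names: {sorted(unknown)}")


def load_dag(path: str | Path) -> CausalDAG:
    """Parse the edge-list graph format.

    Lines are either ``A -> B`` edges, ``latent: NODE`` / ``exposure: NODE`` /
    ``outcome: NODE`` headers, blank, or ``#`` comments.
    """
    g = nx.DiGraph()
    latent: set[str] = set()
    exposure = outcome = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("latent:"):
            latent.add(line.split(":", 1)[1].strip())
        elif line.startswith("exposure:"):
            exposure = line.split(":", 1)[1].strip()
        elif line.startswith("outcome:"):
            outcome = line.split(":", 1)[1].strip()
        elif "->" in line:
            a, b = (s.strip() for s in line.split("->", 1))
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: malformed edge {raw!r}")
            g.add_edge(a, b)
        else:
            raise ValueError(f"{path}:{lineno}: unparseable line {raw!r}")
    return CausalDAG(g, frozenset(latent), exposure, outcome)


def bundled_habitat_dag() -> CausalDAG:
    """The package's transcription of the study's habitat-use DAG."""
    ref = resources.files("invade.data").joinpath("habitat_use.dag")
    with resources.as_file(ref) as p:
        return load_dag(p)


def d_separated(dag: CausalDAG, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff every path between x and y is blocked given z.

    Standard d-separation: chains and forks are blocked by conditioning on
    the middle node; colliders are unblocked by conditioning on the collider
    or any of its descendants.
    """
    zset = set(z)
    dag._check_nodes([x, y, *zset])
    if x in zset or y in zset:
        raise ValueError("x and y must not be members of z")
    return nx.is_d_separator(dag.graph, {x}, {y}, zset)


def is_valid_backdoor(dag: CausalDAG, exposure: str, outcome: str, z: Iterable[str]) -> bool:
    """Back-door criterion: does z identify the causal effect of exposure?

    True iff (i) no member of z is a descendant of the exposure, and (ii) z
    blocks every path from exposure to outcome that begins with an edge into
    the exposure.

    A latent node in z raises ``ValueError`` — a design error, distinct from
    an ordinary invalid set.
    """
    zset = set(z)
    dag._check_nodes([exposure, outcome, *zset])
    bad = zset & dag.latent
    if bad:
        raise ValueError(
            f"adjustment set contains latent node(s) {sorted(bad)}; "
            "latent variables cannot be conditioned on"
        )
    if exposure in zset or outcome in zset:
        return False
    if zset & nx.descendants(dag.graph, exposure):
        return False
    # condition (ii) == d-separation in the graph with exposure's outgoing
    # edges removed: only back-door paths remain at the exposure.
    g = dag.graph.copy()
    g.remove_edges_from(list(g.out_edges(exposure)))
    return nx.is_d_separator(g, {exposure}, {outcome}, zset)


def _causal_path_nodes(dag: CausalDAG, exposure: str, outcome: str) -> set[str]:
    """Interior nodes lying on any directed exposure→outcome path."""
    nodes: set[str] = set()
    for path in nx.all_simple_paths(dag.graph, exposure, outcome):
        nodes.update(path[1:-1])
    return nodes


def total_effect_sets(dag: CausalDAG, exposure: str, outcome: str) -> list[frozenset[str]]:
    """All minimal observed back-door sets preserving the total effect.

    Enumerates observed subsets that satisfy the back-door criterion and
    contain no node on any directed exposure→outcome path (so mediated
    pathways stay open). Only subset-minimal sets are returned, ordered
    lexicographically. An empty result means latent confounding cannot be
    resolved with the observed variables.
    """
    dag._check_nodes([exposure, outcome])
    mediators = _causal_path_nodes(dag, exposure, outcome)
    candidates = sorted(
        dag.observed - {exposure, outcome}
        - mediators
        - nx.descendants(dag.graph, exposure)
    )
    valid: list[frozenset[str]] = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            zset = frozenset(combo)
            if any(v <= zset for v in valid):
                continue  # a subset already works: not minimal
            if is_valid_backdoor(dag, exposure, outcome, zset):
                valid.append(zset)
    return sorted(valid, key=lambda s: sorted(s))
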