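"""Causal diagram of stroke risk and its identification machinery.

The default DAG encodes the clinical structure of a high-risk stroke cohort:
age, sex and BMI are exogenous; diabetes (DM) and dyslipidemia (DLP) precede
hypertension (HT); HT precedes chronic kidney disease (CKD) and atrial
fibrillation (AF); antiplatelet treatment (T) is prescribed on the basis of
HT, DM, DLP and age; every comorbidity and the treatment feed into the
stroke indicator Y.  Backdoor adjustment sets are derived by exhaustive
search over subsets of non-descendants, validated with d-separation.

d-separation is implemented directly as reachability ("Bayes-ball") so that
it can be tested exhaustively against path enumeration and against
networkx's implementation on small random DAGs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "CausalDAG",
    "Estimand",
    "build_default_dag",
    "d_separated",
    "backdoor_adjustment_set",
    "default_estimands",
    "mediators",
]

#: Edges of the default stroke DAG. ``sex`` is an isolated covariate: the
#: diagram gives it no causal arrows, but it is recorded in the cohort.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("age", "dm"), ("age", "dlp"), ("age", "ht"), ("age", "ckd"),
    ("age", "af"), ("age", "y"),
    ("bmi", "dm"), ("bmi", "y"),
    ("dm", "ht"), ("dm", "ckd"), ("dm", "y"),
    ("dlp", "ht"), ("dlp", "y"),
    ("ht", "ckd"), ("ht", "af"), ("ht", "y"),
    ("ckd", "y"),
    ("af", "y"),
    ("ht", "t"), ("dm", "t"), ("dlp", "t"), ("age", "t"),
    ("t", "y"),
)

DEFAULT_NODES: tuple[str, ...] = (
    "age", "sex", "bmi", "dm", "dlp", "ht", "ckd", "af", "t", "y",
)

DEFAULT_ROLES: dict[str, str] = {
    "age": "covariate", "sex": "covariate", "bmi": "covariate",
    "dm": "exposure-candidate", "dlp": "exposure-candidate",
    "ht": "exposure-candidate", "af": "exposure-candidate",
    "ckd": "mediator", "t": "exposure-candidate", "y": "outcome",
}


@dataclass(frozen=True)
class CausalDAG:
    """A directed acyclic graph with node roles.

    Attributes
    ----------
    graph
        ``networkx.DiGraph`` holding nodes and directed edges.
    roles
        Map from node name to one of ``exposure-candidate``, ``outcome``,
        ``mediator``, ``covariate``.
    """

    graph: nx.DiGraph
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("causal graph must be acyclic")
        outcome = [n for n, r in self.roles.items() if r == "outcome"]
        for node in outcome:
            if self.graph.out_degree(node):
                raise ValueError(f"outcome node {node!r} has outgoing edges")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges)

    def parents(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node))

    def descendants(self, node: str) -> set[str]:
        return nx.descendants(self.graph, node)

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.graph))

    def to_edgelist(self) -> str:
        """Edge-list serialization: one ``parent -> child`` per line."""
        return "\n".join(f"{u} -> {v}" for u, v in sorted(self.graph.edges))

    def to_dot(self) -> str:
        lines = ["digraph stroke_dag {"]
        lines += [f'  "{n}";' for n in sorted(self.graph.nodes)]
        lines += [f'  "{u}" -> "{v}";' for u, v in sorted(self.graph.edges)]
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class Estimand:
    """An exposure/outcome pair with its backdoor adjustment set."""

    exposure: str
    outcome: str
    adjustment_set: frozenset[str]

    @property
    def expression(self) -> str:
        cond = ", ".join([self.exposure, *sorted(self.adjustment_set)])
        return f"P({self.outcome} | {cond})"


def build_default_dag() -> CausalDAG:
    """Return the fixed stroke DAG (age/sex/BMI exogenous, Y terminal)."""
    g = nx.DiGraph()
    g.add_nodes_from(DEFAULT_NODES)
    g.add_edges_from(DEFAULT_EDGES)
    return CausalDAG(graph=g, roles=dict(DEFAULT_ROLES))


def d_separated(dag: CausalDAG | nx.DiGraph, x: str, y: str,
                z: set[str] | frozenset[str]) -> bool:
    """Bayes-ball d-separation test: is ``x`` d-separated from ``y`` given ``z``?

    Implements the classic reachability algorithm: a "ball" travels along
    edges and bounces according to whether the current node is in the
    conditioning set and whether the meeting is head-to-head (collider).
    """
    g = dag.graph if isinstance(dag, CausalDAG) else dag
    z = set(z)
    if x == y:
        raise ValueError("x and y must differ")
    # ancestors of z (needed for collider openness)
    anc_z: set[str] = set(z)
    for node in z:
        anc_z |= nx.ancestors(g, node)

    # state: (node, direction) with direction "up" = arrived from a child
    # (travelling against edge arrows), "down" = arrived from a parent.
    visited: set[tuple[str, str]] = set()
    frontier: list[tuple[str, str]] = [(x, "up")]
    while frontier:
        node, direction = frontier.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node == y and node not in z:
            return False
        if direction == "up" and node not in z:
            # pass through to parents (chain) and children (fork at source)
            frontier.extend((p, "up") for p in g.predecessors(node))
            frontier.extend((c, "down") for c in g.successors(node))
        elif direction == "down":
            if node not in z:
                # chain: continue to children
                frontier.extend((c, "down") for c in g.successors(node))
            if node in anc_z:
                # collider open when node (or a descendant) is conditioned on
                frontier.extend((p, "up") for p in g.predecessors(node))
    return True


def _is_valid_backdoor(g: nx.DiGraph, exposure: str, outcome: str,
                       z: frozenset[str], descendants: set[str]) -> bool:
    if z & descendants or exposure in z or outcome in z:
        return False
    # blocking all backdoor paths == d-separation in the graph with the
    # exposure's outgoing edges removed
    g_back = g.copy()
    g_back.remove_edges_from(list(g.out_edges(exposure)))
    return d_separated(g_back, exposure, outcome, z)


def backdoor_adjustment_set(dag: CausalDAG, exposure: str,
                            outcome: str = "y") -> frozenset[str]:
    """Minimal covariate set blocking every backdoor path into ``exposure``.

    Searches subsets of non-descendants in order of increasing size, breaking
    ties lexicographically, and returns the first set that d-separates the
    exposure from the outcome in the back-door graph.

    Raises
    ------
    ValueError
        If exposure equals outcome, either is missing from the DAG, or no
        valid adjustment set exists.
    """
    g = dag.graph
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    if exposure not in g or outcome not in g:
        raise ValueError("exposure and outcome must be nodes of the DAG")
    descendants = nx.descendants(g, exposure)
    candidates = sorted(set(g.nodes) - descendants - {exposure, outcome})
    if len(candidates) > 20:
        raise ValueError("too many candidate adjustment nodes for exhaustive search")
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            z = frozenset(combo)
            if _is_valid_backdoor(g, exposure, outcome, z, descendants):
                return z
    raise ValueError(f"no valid backdoor adjustment set for {exposure!r}")


def default_estimands() -> list[Estimand]:
    """Backdoor estimands for the four stroke risk factors on the default DAG."""
    dag = build_default_dag()
    return [
        Estimand(exposure=x, outcome="y",
                 adjustment_set=backdoor_adjustment_set(dag, x, "y"))
        for x in ("af", "ht", "dm", "dlp")
    ]


def mediators(dag: CausalDAG, exposure: str, outcome: str = "y") -> set[str]:
    """Nodes lying on directed paths from ``exposure`` to ``outcome``."""
    g = dag.graph
    desc = nx.descendants(g, exposure)
    anc = nx.ancestors(g, outcome)
    return desc & anc


def disease_mediators(dag: CausalDAG, exposure: str,
                      outcome: str = "y") -> set[str]:
    """Comorbidity mediators of a risk factor, excluding the treatment node.

    Antiplatelet treatment sits on directed risk-factor -> T -> stroke paths,
    but clinically the mediating mechanisms of interest are the downstream
    comorbidities (e.g. HT acts on stroke through CKD and AF), so the
    treatment node is excluded from default mediator sets.
    """
    return mediators(dag, exposure, outcome) - {"t"}
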