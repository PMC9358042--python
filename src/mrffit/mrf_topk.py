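"""Pairwise Markov random field over candidate poses and top-K MAP extraction.

Each subunit is a single node whose states are its retained candidate poses;
every unordered pair of subunits is connected through a pairwise node holding
a table of interaction energies.  The assembly score is log-linear:

    E(X_1..X_N) = sum_i [ w_cc * f_cc(X_i) + w_ov * f_ov(X_i) ]
                + sum_{(i,j)} [ w_ph * f_ph(X_i, X_j) + w_cl * f_cl(X_i, X_j) ]

with f_cc = -CCC, f_ov = -OV, f_ph the physics interaction energy and f_cl
the clash count, so every term is an energy and the optimal conformation is
the global *minimizer*.  The model probability is proportional to exp(-E);
the partition function is never computed because only MAP-style inference is
needed.

Inference runs in two phases of max-sum (min-sum on energies) message
passing: single nodes send their per-pose beliefs to pairwise nodes, and each
pairwise node (i, j) returns to node i, for every pose of i, the best
achievable sum of the edge energy and j's belief.  On loopy graphs these
single-pass beliefs are approximate, so the top-K conformations are extracted
by a best-first heap search over partial assignments whose priority combines
the exact energy of the assigned part with an admissible lower bound on the
rest; every emitted model therefore carries its exact energy and the output
is the true top-K.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Weights",
    "MRFGraph",
    "BeliefState",
    "AssemblyModel",
    "NoValidModelsError",
    "node_energy",
    "edge_energy",
    "total_energy",
    "build_graph",
    "run_max_sum",
    "extract_top_k",
    "enumerate_all",
    "DEFAULT_TOP_K",
]

DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class Weights:
    """Log-linear score weights; the defaults are used throughout the study."""

    w_cc: float = 0.5
    w_ov: float = 0.9
    w_ph: float = 1.0
    w_cl: float = 0.8

    def __post_init__(self) -> None:
        for name in ("w_cc", "w_ov", "w_ph", "w_cl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class NoValidModelsError(RuntimeError):
    """Every complete assignment was rejected by the clash check."""


def node_energy(pose, w: Weights) -> float:
    """Goodness-of-fit energy of one pose: w_cc * (-cc) + w_ov * (-ov)."""
    return w.w_cc * (-pose.cc) + w.w_ov * (-pose.ov)


def edge_energy(score, w: Weights) -> float:
    """Interaction energy of a pose pair: w_ph * f_ph + w_cl * f_cl."""
    return w.w_ph * score.f_ph + w.w_cl * score.f_cl


@dataclass
class MRFGraph:
    """Single nodes (per-pose energies) plus pairwise energy tables.

    ``node_energies[i]`` is a 1D array over poses of subunit i;
    ``edges[(i, j)]`` (i < j) is a |poses_i| x |poses_j| energy table.
    ``clash_tables`` optionally stores the raw clash counts per pose pair
    for the final significant-clash check.
    """

    node_ids: list
    node_energies: list
    edges: dict
    weights: Weights = field(default_factory=Weights)
    clash_tables: dict = field(default_factory=dict)
    pose_sets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_energies = [np.asarray(e, dtype=float) for e in self.node_energies]
        for (i, j), table in list(self.edges.items()):
            if i >= j:
                raise ValueError("edge keys must be ordered pairs (i, j) with i < j")
            table = np.asarray(table, dtype=float)
            expect = (len(self.node_energies[i]), len(self.node_energies[j]))
            if table.shape != expect:
                raise ValueError(f"edge table {(i, j)} has shape {table.shape}, expected {expect}")
            if not np.all(np.isfinite(table)):
                raise ValueError(f"edge table {(i, j)} contains non-finite potentials")
            self.edges[(i, j)] = table

    @property
    def n_nodes(self) -> int:
        return len(self.node_energies)

    def n_states(self, i: int) -> int:
        return len(self.node_energies[i])


@dataclass
class BeliefState:
    """Per-node per-pose beliefs before and after message passing."""

    initial: list
    final: list


def build_graph(pose_sets, subunits, weights: Weights | None = None,
                interaction_cutoff: float = 10.0) -> MRFGraph:
    """Assemble the MRF from per-subunit pose sets.

    Node energies come from the fit scores; edge tables are filled by scoring
    the physical interaction of every cross-subunit pose pair (pairs whose
    bounding spheres are farther than the cutoff get the exact zero score).
    """
    from .pair_scoring import edge_tables_for_pair

    w = weights or Weights()
    node_ids = [ps.subunit_id for ps in pose_sets]
    node_energies = [
        np.array([node_energy(p, w) for p in ps]) for ps in pose_sets
    ]
    edges: dict = {}
    clash_tables: dict = {}
    by_id = {s.id: s for s in subunits}
    for i in range(len(pose_sets)):
        for j in range(i + 1, len(pose_sets)):
            si, sj = by_id[node_ids[i]], by_id[node_ids[j]]
            e_table, c_table = edge_tables_for_pair(
                si, sj, pose_sets[i], pose_sets[j], w, interaction_cutoff
            )
            edges[(i, j)] = e_table
            clash_tables[(i, j)] = c_table
    return MRFGraph(node_ids, node_energies, edges, w, clash_tables, list(pose_sets))


def total_energy(assignment, graph: MRFGraph) -> float:
    """Exact log-linear energy of a complete assignment."""
    assignment = tuple(assignment)
    if len(assignment) != graph.n_nodes:
        raise ValueError("assignment must give one pose index per subunit")
    e = sum(graph.node_energies[i][x] for i, x in enumerate(assignment))
    for (i, j), table in graph.edges.items():
        e += table[assignment[i], assignment[j]]
    return float(e)


def run_max_sum(graph: MRFGraph) -> BeliefState:
    """Two-phase max-sum (min-sum on energies) belief propagation, one pass.

    Phase 1: each single node sends its per-pose beliefs to every incident
    pairwise node.  Phase 2: pairwise node (i, j) sends back to node i, for
    each pose x_i, min over x_j of (edge energy + belief of x_j).  Final
    beliefs are initial beliefs plus all incoming messages.
    """
    for i, e in enumerate(graph.node_energies):
        if len(e) == 0:
            raise RuntimeError(f"subunit {graph.node_ids[i]!r} has an empty pose set")
    initial = [e.copy() for e in graph.node_energies]
    final = [e.copy() for e in graph.node_energies]
    for (i, j), table in graph.edges.items():
        # message to i: best partner pose of j per pose of i (and vice versa)
        final[i] += np.min(table + initial[j][None, :], axis=1)
        final[j] += np.min(table.T + initial[i][None, :], axis=1)
    return BeliefState(initial=initial, final=final)


def _remaining_bound(graph: MRFGraph, assignment: tuple, edge_mins: dict) -> float:
    """Admissible lower bound on the energy of the unassigned remainder."""
    n = graph.n_nodes
    m = len(assignment)
    if m == n:
        return 0.0
    bound = 0.0
    for i in range(m, n):
        per_pose = graph.node_energies[i].copy()
        for j in range(m):
            key = (j, i) if j < i else (i, j)
            table = graph.edges.get(key)
            if table is None:
                continue
            per_pose = per_pose + (table[assignment[j], :] if j < i else table[:, assignment[j]])
        bound += float(per_pose.min())
    for (i, j), mn in edge_mins.items():
        if i >= m and j >= m:
            bound += mn
    return bound


def extract_top_k(
    graph: MRFGraph,
    beliefs: BeliefState | None = None,
    k: int = DEFAULT_TOP_K,
    is_valid=None,
) -> list:
    """Best-first heap search for the exact top-K lowest-energy assemblies.

    Partial assignments (poses fixed for the first m subunits) live on a
    min-heap keyed by exact-assigned-energy + admissible remainder bound, so
    complete assignments pop in exact energy order.  ``is_valid`` (e.g. the
    significant-clash check) filters complete assignments; the search
    continues until K survivors or exhaustion.  Ties in energy are broken by
    lexicographic pose-index order.
    """
    n = graph.n_nodes
    for i in range(n):
        if graph.n_states(i) == 0:
            raise RuntimeError(f"subunit {graph.node_ids[i]!r} has an empty pose set")
    if beliefs is None:
        beliefs = run_max_sum(graph)
    edge_mins = {key: float(t.min()) for key, t in graph.edges.items()}

    def partial_energy(assignment: tuple) -> float:
        e = sum(graph.node_energies[i][x] for i, x in enumerate(assignment))
        for (i, j), table in graph.edges.items():
            if i < len(assignment) and j < len(assignment):
                e += table[assignment[i], assignment[j]]
        return float(e)

    root = ()
    heap = [(_remaining_bound(graph, root, edge_mins), root, 0.0)]
    models: list[AssemblyModel] = []
    while heap and len(models) < k:
        bound, assignment, exact_part = heapq.heappop(heap)
        if len(assignment) == n:
            if is_valid is None or is_valid(assignment):
                models.append(
                    AssemblyModel(assignment=assignment, energy=exact_part,
                                  rank=len(models) + 1)
                )
            continue
        m = len(assignment)
        for x in range(graph.n_states(m)):
            child = assignment + (x,)
            e_child = partial_energy(child)
            b_child = e_child + _remaining_bound(graph, child, edge_mins)
            heapq.heappush(heap, (b_child, child, e_child))
    if not models:
        raise NoValidModelsError(
            "no clash-free assembly model exists for these pose sets"
        )
    return models


@dataclass
class AssemblyModel:
    """A complete pose assignment with its exact log-linear energy."""

    assignment: tuple
    energy: float
    rank: int


def enumerate_all(graph: MRFGraph) -> list:
    """Exhaustive enumeration of all assignments sorted by (energy, indices).

    Independent oracle for the heap search; exponential, test-scale only.
    """
    ranges = [range(graph.n_states(i)) for i in range(graph.n_nodes)]
    scored = [
        (total_energy(a, graph), a) for a in itertools.product(*ranges)
    ]
    scored.sort(key=lambda t: (t[0], t[1]))
    return [
        AssemblyModel(assignment=a, energy=e, rank=r + 1)
        for r, (e, a) in enumerate(scored)
    ]
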